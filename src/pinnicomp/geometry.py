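"""Truncated-cones body geometry for pinnipeds.

A seal hauled out on land is approximated as a stack of conical frusta
whose cross-sections are ellipses (width > height under gravity) or, in
the traditional variant, circles derived from girth.  Landmark
measurements at eight sites along the body define the frusta; ultrasound
sculp-depth readings at the six interior sites define inner surfaces
that partition the body into skin, blubber, and core shells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "SITES",
    "INTERIOR_SITES",
    "Shape",
    "Extent",
    "DepthSource",
    "MorphometricProfile",
    "VolumePartition",
    "UltrasoundCalibration",
    "DegenerateSegmentError",
    "DegenerateBodyError",
    "straight_length",
    "frustum_volume",
    "end_cone_volume",
    "body_volume",
    "partition_volumes",
    "convert_ultrasound_depth",
    "DORSAL_CALIBRATION",
    "LATERAL_CALIBRATION",
]

#: Landmark sites in anatomical order, posterior (tail end) to anterior.
SITES = ("ankles", "pelvis", "umbilicus", "mid", "sternum", "axilla", "neck", "ears")

#: Sites where ultrasound sculp depth is measured (all but the extremities).
INTERIOR_SITES = SITES[1:-1]

_SITE_INDEX = {s: i for i, s in enumerate(SITES)}
N_SITES = len(SITES)


class Shape(str, Enum):
    CIRCULAR = "circular"
    ELLIPTICAL = "elliptical"


class Extent(str, Enum):
    NECK_TO_PELVIS = "neck_to_pelvis"
    FULL_BODY = "full_body"


class DepthSource(str, Enum):
    """How sculp depth is subtracted to form the inner (muscle) surface.

    PER_AXIS subtracts the lateral reading from the horizontal semi-axis
    and the dorsal reading from the vertical semi-axis, matching probe
    placement.  MEAN subtracts the mean of the dorsal and lateral
    readings from both semi-axes (the traditional single-depth usage).
    """

    PER_AXIS = "per_axis"
    MEAN = "mean"


class DegenerateSegmentError(ValueError):
    """Curvilinear length shorter than the radial offset it must span."""


class DegenerateBodyError(ValueError):
    """A subtracted layer is thicker than the body it is subtracted from."""


# ---------------------------------------------------------------------------
# Elementary volumes


def straight_length(l_c, r1, r2):
    """Straight segment length from curvilinear length and end radii.

    The tape follows the body surface, so the measured curvilinear
    length ``l_c`` is the hypotenuse of the straight axial length and
    the difference in radii at the two ends:
    ``L_s = sqrt(L_c^2 - (r1 - r2)^2)``.

    Raises
    ------
    DegenerateSegmentError
        If ``l_c <= |r1 - r2|`` — inconsistent measurements.
    """
    l_c = np.asarray(l_c, dtype=float)
    dr = np.asarray(r1, dtype=float) - np.asarray(r2, dtype=float)
    if np.any(l_c <= np.abs(dr)):
        raise DegenerateSegmentError(
            f"curvilinear length {l_c} does not exceed radial offset {np.abs(dr)}"
        )
    out = np.sqrt(l_c**2 - dr**2)
    return float(out) if out.ndim == 0 else out


def frustum_volume(a1, b1, a2, b2, l_s):
    """Volume of an elliptical conical frustum.

    Semi-axes ``(a1, b1)`` and ``(a2, b2)`` at the two ends vary
    linearly along the axis of length ``l_s``:
    ``V = (pi * L_s / 6) * (2*a1*b1 + a2*b1 + b2*a1 + 2*a2*b2)``.
    The circular case is ``a == b == r`` at each end.
    """
    args = [np.asarray(v, dtype=float) for v in (a1, b1, a2, b2, l_s)]
    if any(np.any(v < 0) for v in args):
        raise ValueError("semi-axes and segment length must be non-negative")
    a1, b1, a2, b2, l_s = args
    out = (np.pi * l_s / 6.0) * (2 * a1 * b1 + a2 * b1 + b2 * a1 + 2 * a2 * b2)
    return float(out) if out.ndim == 0 else out


def end_cone_volume(a, b, l_s):
    """Volume of an elliptical cone: ``V = pi * L_s * a * b / 3``."""
    args = [np.asarray(v, dtype=float) for v in (a, b, l_s)]
    if any(np.any(v < 0) for v in args):
        raise ValueError("semi-axes and length must be non-negative")
    a, b, l_s = args
    out = np.pi * l_s * a * b / 3.0
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Profiles


@dataclass
class MorphometricProfile:
    """One animal's landmark measurements, possibly replicated.

    All per-site arrays have shape ``(n_replicates, 8)`` ordered by
    :data:`SITES` (posterior to anterior).  Ultrasound depths are NaN at
    the ears and ankles, where no image is taken.  Units: cm for all
    lengths and depths, kg for mass.
    """

    animal_id: str
    girth: np.ndarray
    height: np.ndarray
    width: np.ndarray
    curvilinear: np.ndarray
    total_length: np.ndarray  # (n_replicates,) tail to nose tip
    mass: float
    us_dorsal: np.ndarray | None = None
    us_lateral: np.ndarray | None = None

    def __post_init__(self):
        for name in ("girth", "height", "width", "curvilinear"):
            arr = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if arr.shape[1] != N_SITES:
                raise ValueError(f"{name} must have {N_SITES} site columns")
            setattr(self, name, arr)
        self.total_length = np.atleast_1d(np.asarray(self.total_length, dtype=float))
        for name in ("us_dorsal", "us_lateral"):
            arr = getattr(self, name)
            if arr is not None:
                setattr(self, name, np.atleast_2d(np.asarray(arr, dtype=float)))
        self.validate()

    @property
    def n_replicates(self) -> int:
        return self.girth.shape[0]

    def validate(self):
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if np.any(self.girth <= 0) or np.any(self.curvilinear <= 0):
            raise ValueError("girths and curvilinear lengths must be positive")
        lc = self.site_means()["curvilinear"]
        if np.any(np.diff(lc) <= 0):
            raise ValueError("curvilinear length must increase strictly with site order")
        if np.mean(self.total_length) < lc[-1]:
            raise ValueError("total length must reach at least the ears")

    def site_means(self) -> dict[str, np.ndarray]:
        """Replicates reduced to per-site means (geometry operates on these)."""
        out = {
            "girth": self.girth.mean(axis=0),
            "height": self.height.mean(axis=0),
            "width": self.width.mean(axis=0),
            "curvilinear": self.curvilinear.mean(axis=0),
            "total_length": float(self.total_length.mean()),
        }
        for name in ("us_dorsal", "us_lateral"):
            arr = getattr(self, name)
            if arr is not None:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    out[name] = np.nanmean(arr, axis=0)
        return out

    def semi_axes(self, shape: Shape) -> tuple[np.ndarray, np.ndarray]:
        """Per-site semi-axes (a horizontal, b vertical) under a shape model.

        Circular: ``a = b = G / (2 pi)`` from girth.  Elliptical:
        ``a = W/2``, ``b = H/2`` from the direct width/height poles.
        """
        m = self.site_means()
        if Shape(shape) is Shape.CIRCULAR:
            r = m["girth"] / (2 * np.pi)
            return r, r.copy()
        if np.any(~np.isfinite(m["height"])) or np.any(~np.isfinite(m["width"])):
            raise ValueError("elliptical shape requires height and width at every site")
        return m["width"] / 2.0, m["height"] / 2.0


@dataclass
class VolumePartition:
    """Total/skin/blubber/core volumes [cm^3] for one body."""

    v_total: float
    v_skin: float
    v_blubber: float
    v_core: float
    extent: Extent
    shape: Shape
    segments: dict = field(default_factory=dict)
    clamped: bool = False

    def __post_init__(self):
        self.extent = Extent(self.extent)
        self.shape = Shape(self.shape)

    def as_dict(self):
        return {
            "v_total_cm3": self.v_total,
            "v_skin_cm3": self.v_skin,
            "v_blubber_cm3": self.v_blubber,
            "v_core_cm3": self.v_core,
            "extent": self.extent.value,
            "shape": self.shape.value,
        }


# ---------------------------------------------------------------------------
# Whole-body volume


def _straight_lengths(l_c, b, first, last):
    """Axial segment lengths from the outer surface's curvilinear tape.

    The tape follows the outer surface, so the radius correction uses
    the outer vertical semi-axes; the same axial lengths apply to every
    nested (skin, muscle) surface.
    """
    return np.array([
        straight_length(l_c[i + 1] - l_c[i], b[i], b[i + 1])
        for i in range(first, last)
    ])


def _segment_volumes(a, b, l_s, first, last):
    """Frustum volumes between adjacent sites ``first..last`` (inclusive)."""
    return np.array([
        frustum_volume(a[i], b[i], a[i + 1], b[i + 1], l_s[i - first])
        for i in range(first, last)
    ])


def _extent_bounds(extent: Extent) -> tuple[int, int]:
    if Extent(extent) is Extent.NECK_TO_PELVIS:
        return _SITE_INDEX["pelvis"], _SITE_INDEX["neck"]
    return 0, N_SITES - 1


def body_volume(profile: MorphometricProfile, shape=Shape.ELLIPTICAL,
                extent=Extent.FULL_BODY):
    """Whole-body (or neck-to-pelvis) volume in cm^3, with per-segment detail.

    Sums frusta between adjacent sites; the full-body extent adds a
    posterior end cone (tail to ankles) and an anterior end cone (ears
    to nose tip).
    """
    a, b = profile.semi_axes(shape)
    m = profile.site_means()
    l_c = m["curvilinear"]
    first, last = _extent_bounds(extent)
    l_s = _straight_lengths(l_c, b, first, last)
    segs = _segment_volumes(a, b, l_s, first, last)
    detail = {
        f"{SITES[i]}-{SITES[i + 1]}": v
        for i, v in zip(range(first, last), segs)
    }
    total = float(segs.sum())
    if Extent(extent) is Extent.FULL_BODY:
        tail = end_cone_volume(a[0], b[0], l_c[0])
        nose = end_cone_volume(a[-1], b[-1], m["total_length"] - l_c[-1])
        detail["tail_cone"] = tail
        detail["nose_cone"] = nose
        total += tail + nose
    return total, detail


# ---------------------------------------------------------------------------
# Skin / blubber / core partition


def _shrink(a, b, da, db):
    """Subtract layer depths from semi-axes, clamping at zero."""
    a2, b2 = a - da, b - db
    clamped = bool(np.any(a2 < 0) or np.any(b2 < 0))
    if clamped:
        warnings.warn("layer depth exceeds a semi-axis; clamping to zero",
                      RuntimeWarning, stacklevel=3)
    return np.clip(a2, 0.0, None), np.clip(b2, 0.0, None), clamped


def partition_volumes(profile: MorphometricProfile, skin_depth: float,
                      shape=Shape.ELLIPTICAL, extent=Extent.FULL_BODY,
                      depth_source=DepthSource.PER_AXIS) -> VolumePartition:
    """Partition the body into skin, blubber, and core volumes.

    Three nested surfaces are built per site: the outer body surface,
    the surface with the (constant) skin depth removed, and the inner
    muscle surface with the full ultrasound sculp depth removed.  At the
    ears and ankles the sculp depth is taken to equal the skin depth, so
    blubber tapers to zero at the extremities; the full-body extent adds
    end cones (all core) beyond them.  Shell volumes are differences of
    the nested stacked-frustum volumes, so additivity
    ``V_skin + V_blubber + V_core == V_total`` is exact.

    With ``skin_depth=0`` and ``depth_source=MEAN`` this reduces to the
    traditional sculp-as-blubber partition.
    """
    if skin_depth < 0:
        raise ValueError("skin_depth must be non-negative")
    a, b = profile.semi_axes(shape)
    if skin_depth >= min(a.min(), b.min()):
        raise DegenerateBodyError("skin depth exceeds the smallest semi-axis")
    m = profile.site_means()
    l_c = m["curvilinear"]

    if profile.us_dorsal is None or profile.us_lateral is None:
        raise ValueError("partitioning requires ultrasound sculp depths")
    dors = m["us_dorsal"].copy()
    lat = m["us_lateral"].copy()
    # extremities carry no blubber: sculp there is skin only
    for i in (0, N_SITES - 1):
        dors[i] = skin_depth
        lat[i] = skin_depth
    if np.any(~np.isfinite(dors[1:-1])) or np.any(~np.isfinite(lat[1:-1])):
        raise ValueError("missing ultrasound depth at an interior site")
    if DepthSource(depth_source) is DepthSource.MEAN:
        mean_depth = (dors + lat) / 2.0
        dors = lat = mean_depth

    first, last = _extent_bounds(extent)
    a_sk, b_sk, c1 = _shrink(a, b, skin_depth, skin_depth)
    a_in, b_in, c2 = _shrink(a, b, lat, dors)

    l_s = _straight_lengths(l_c, b, first, last)
    v_outer = _segment_volumes(a, b, l_s, first, last).sum()
    v_minus_skin = _segment_volumes(a_sk, b_sk, l_s, first, last).sum()
    v_inner = _segment_volumes(a_in, b_in, l_s, first, last).sum()

    v_total = float(v_outer)
    segments = {}
    if Extent(extent) is Extent.FULL_BODY:
        tail = end_cone_volume(a[0], b[0], l_c[0])
        nose = end_cone_volume(a[-1], b[-1], m["total_length"] - l_c[-1])
        segments["tail_cone"] = tail
        segments["nose_cone"] = nose
        v_total += tail + nose

    v_skin = float(v_outer - v_minus_skin)
    v_blubber = float(v_minus_skin - v_inner)
    v_core = v_total - v_skin - v_blubber
    return VolumePartition(
        v_total=v_total, v_skin=v_skin, v_blubber=v_blubber, v_core=v_core,
        extent=Extent(extent), shape=Shape(shape), segments=segments,
        clamped=c1 or c2,
    )


# ---------------------------------------------------------------------------
# Ultrasound instrument calibration


@dataclass
class UltrasoundCalibration:
    """Linear map from non-image to image-equivalent sculp depth.

    One slope shared across body sites with per-site intercepts [cm]:
    ``y = slope * x + intercept[site]``.  Optional joint posterior draws
    (columns: slope, then intercepts in ``intercepts`` key order) let the
    conversion return a distribution instead of a point.
    """

    slope: float
    intercepts: dict[str, float]
    resid_var: float = 0.0
    surface: str = "dorsal"
    draws: np.ndarray | None = None

    def __post_init__(self):
        if self.draws is not None:
            d = np.asarray(self.draws, dtype=float)
            if d.shape[1] != 1 + len(self.intercepts):
                raise ValueError("draws must have one column per parameter")
            means = d.mean(axis=0)
            expect = np.array([self.slope, *self.intercepts.values()])
            if not np.allclose(means, expect, atol=1e-6, rtol=1e-6):
                raise ValueError("posterior draw means do not match stored point values")
            self.draws = d


def convert_ultrasound_depth(x: float, site: str, calibration: UltrasoundCalibration):
    """Convert a non-image ultrasound reading to its image-equivalent depth.

    Returns a float, or an array of posterior-propagated depths when the
    calibration carries joint posterior draws.
    """
    if site not in calibration.intercepts:
        raise KeyError(f"no intercept for site {site!r}")
    if calibration.draws is not None:
        j = 1 + list(calibration.intercepts).index(site)
        return calibration.draws[:, 0] * x + calibration.draws[:, j]
    return calibration.slope * x + calibration.intercepts[site]


# Posterior means of the study's instrument cross-calibration (image vs
# non-image sculp depth, shared slope, per-site intercepts in cm).
DORSAL_CALIBRATION = UltrasoundCalibration(
    slope=0.873,
    intercepts={
        "pelvis": 1.26, "umbilicus": 0.933, "mid": 0.851,
        "sternum": 0.841, "axilla": 0.827, "neck": 0.540,
    },
    resid_var=2.12e-3,
    surface="dorsal",
)

LATERAL_CALIBRATION = UltrasoundCalibration(
    slope=0.583,
    intercepts={
        "pelvis": 1.95, "umbilicus": 2.13, "mid": 2.15,
        "sternum": 2.21, "axilla": 2.23, "neck": 2.00,
    },
    resid_var=1.24e-3,
    surface="lateral",
)
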