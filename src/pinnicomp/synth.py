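"""Synthetic seals, dilution experiments, and regression datasets.

Every generator carries its own ground truth so each pipeline stage can
be tested for exact recovery (at zero noise) or calibration (under
noise).  Truth bodies are piecewise elliptical frusta — inside the
estimator's model class — with nested skin and blubber surfaces; girth
is the true ellipse perimeter, so the circular-shape assumption is
genuinely misspecified for elliptical truths, as it is for real seals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ellipe

from .dilution import DilutionRecord, StandardDilution
from .geometry import N_SITES, MorphometricProfile
from .tissue import TissueProperties

__all__ = [
    "SealTruth",
    "NoiseModel",
    "default_truth",
    "make_seal",
    "make_dilution",
    "make_standards",
    "make_regression",
    "ellipse_perimeter",
]


def ellipse_perimeter(a, b):
    """Exact ellipse perimeter via the complete elliptic integral."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    big, small = np.maximum(a, b), np.minimum(a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = 1.0 - (small / big) ** 2
    out = np.where(big > 0, 4.0 * big * ellipe(np.where(big > 0, m, 0.0)), 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class SealTruth:
    """A synthetic seal body with known tissue composition.

    Per-site outer semi-axes (a horizontal, b vertical, cm), a constant
    skin depth, per-site sculp depths (dorsal applies to b, lateral to
    a; the extremities carry skin only), straight segment lengths
    between adjacent sites, and axial end-cone lengths.  Tissue volumes
    and masses follow by exact frustum arithmetic.
    """

    outer_a: np.ndarray
    outer_b: np.ndarray
    skin_depth: float
    sculp_dorsal: np.ndarray
    sculp_lateral: np.ndarray
    segment_lengths: np.ndarray  # (7,) straight lengths, cm
    tail_cone_length: float
    nose_cone_length: float
    props: TissueProperties = field(default_factory=TissueProperties)
    core_density: float = 1.1  # g/mL, lean tissue
    phase: str = "early"
    w_adipose: float = 0.151  # water fraction of adipose tissue
    w_lean: float = 0.732  # water fraction of lean tissue

    def __post_init__(self):
        for name in ("outer_a", "outer_b", "sculp_dorsal", "sculp_lateral"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_SITES,):
                raise ValueError(f"{name} must have {N_SITES} entries")
            setattr(self, name, arr)
        self.segment_lengths = np.asarray(self.segment_lengths, dtype=float)
        if self.segment_lengths.shape != (N_SITES - 1,):
            raise ValueError("need one segment length per adjacent site pair")
        d, l = self.sculp_dorsal, self.sculp_lateral
        if d[0] != self.skin_depth or d[-1] != self.skin_depth \
                or l[0] != self.skin_depth or l[-1] != self.skin_depth:
            raise ValueError("extremity sculp depths must equal the skin depth")
        if np.any(d < self.skin_depth) or np.any(l < self.skin_depth):
            raise ValueError("blubber boundary must lie inside the skin boundary")
        if np.any(self.outer_b - d <= 0) or np.any(self.outer_a - l <= 0):
            raise ValueError("skin/blubber boundaries must lie inside the surface")

    # -- derived geometry ---------------------------------------------------

    def curvilinear(self) -> np.ndarray:
        """Surface (tape) length from the tail to each site."""
        lc = np.empty(N_SITES)
        lc[0] = self.tail_cone_length
        db = np.diff(self.outer_b)
        lc[1:] = lc[0] + np.cumsum(np.sqrt(self.segment_lengths**2 + db**2))
        return lc

    @property
    def total_length(self) -> float:
        return float(self.curvilinear()[-1] + self.nose_cone_length)

    def _stack_volume(self, a, b, end_cones: bool) -> float:
        ls = self.segment_lengths
        v = float(np.sum(np.pi * ls / 6.0 * (2 * a[:-1] * b[:-1] + a[1:] * b[:-1]
                                             + b[1:] * a[:-1] + 2 * a[1:] * b[1:])))
        if end_cones:
            v += np.pi * self.tail_cone_length * a[0] * b[0] / 3.0
            v += np.pi * self.nose_cone_length * a[-1] * b[-1] / 3.0
        return v

    def true_volumes(self) -> dict:
        """Exact total/skin/blubber/core volumes [cm^3]."""
        a, b = self.outer_a, self.outer_b
        a_sk, b_sk = a - self.skin_depth, b - self.skin_depth
        a_in, b_in = a - self.sculp_lateral, b - self.sculp_dorsal
        v_total = self._stack_volume(a, b, end_cones=True)
        v_skin = (self._stack_volume(a, b, False)
                  - self._stack_volume(a_sk, b_sk, False))
        v_blub = (self._stack_volume(a_sk, b_sk, False)
                  - self._stack_volume(a_in, b_in, False))
        return {"v_total": v_total, "v_skin": v_skin, "v_blubber": v_blub,
                "v_core": v_total - v_skin - v_blub}

    def true_masses(self) -> dict:
        """Exact tissue and fat masses [kg] and composition proportions."""
        v = self.true_volumes()
        skin_mass = v["v_skin"] * self.props.skin_density[0] / 1000.0
        blub_mass = v["v_blubber"] * self.props.blubber_density[0] / 1000.0
        core_mass = v["v_core"] * self.core_density / 1000.0
        total = skin_mass + blub_mass + core_mass
        fat = (blub_mass * self.props.fat_in_blubber_for(self.phase)[0]
               + skin_mass * self.props.fat_in_skin[0])
        return {
            "skin_mass_kg": skin_mass, "blubber_mass_kg": blub_mass,
            "core_mass_kg": core_mass, "total_mass_kg": total,
            "fat_mass_kg": fat, "proportion_fat": fat / total,
            "proportion_adipose": blub_mass / total,
        }

    def true_tbw_ml(self) -> float:
        """Water pool implied by tissue hydration fractions."""
        m = self.true_masses()
        water_kg = (self.w_adipose * m["blubber_mass_kg"]
                    + self.w_lean * (m["total_mass_kg"] - m["blubber_mass_kg"]))
        return 1000.0 * water_kg  # 1 g/mL


def default_truth(phase: str = "early", scale: float = 1.0,
                  props: TissueProperties | None = None) -> SealTruth:
    """A magnitude-realistic adult female: ~2.5 m, ~350 kg, ~30% adipose.

    Semi-axes taper toward both extremities; widths exceed heights
    (seals flatten under gravity on land).  ``scale`` multiplies all
    linear dimensions for smaller/larger animals.
    """
    b = np.array([7.0, 18.0, 22.0, 24.0, 23.0, 20.0, 14.0, 10.0]) * scale
    a = b * np.array([1.15, 1.3, 1.35, 1.35, 1.3, 1.25, 1.2, 1.05])
    skin = 1.32 * scale
    sculp_d = np.array([skin, 4.5, 5.0, 5.2, 4.8, 4.2, 3.5, skin])
    sculp_l = np.array([skin, 4.0, 4.6, 4.8, 4.4, 3.8, 3.2, skin])
    return SealTruth(
        outer_a=a, outer_b=b, skin_depth=skin,
        sculp_dorsal=sculp_d, sculp_lateral=sculp_l,
        segment_lengths=np.array([25.0, 30.0, 30.0, 30.0, 30.0, 30.0, 35.0]) * scale,
        tail_cone_length=10.0 * scale, nose_cone_length=30.0 * scale,
        props=props or TissueProperties(), phase=phase,
    )


@dataclass
class NoiseModel:
    """Triplicate-observer measurement noise.

    Additive normal SDs [cm] for tape/pole measurements; multiplicative
    lognormal noise (SD of the log) for ultrasound depth readings;
    coefficient of variation for scintillation count replicates.
    """

    sd_girth: float = 1.0
    sd_height: float = 0.5
    sd_width: float = 0.5
    sd_length: float = 1.0
    us_log_sd: float = 0.05
    count_cv: float = 0.05
    n_observers: int = 3

    def __post_init__(self):
        if min(self.sd_girth, self.sd_height, self.sd_width, self.sd_length,
               self.us_log_sd, self.count_cv) < 0:
            raise ValueError("noise SDs must be non-negative")

    def zero(self) -> "NoiseModel":
        return replace(self, sd_girth=0, sd_height=0, sd_width=0,
                       sd_length=0, us_log_sd=0, count_cv=0)


def make_seal(truth: SealTruth, noise: NoiseModel | None = None,
              seed: int = 0, animal_id: str = "synthetic") -> MorphometricProfile:
    """Emit replicated noisy morphometrics for a truth body.

    At zero noise the geometry + tissue pipeline (elliptical shape,
    per-axis depths, the truth's skin depth) recovers the true tissue
    volumes and masses exactly.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    k = noise.n_observers
    girth_true = ellipse_perimeter(truth.outer_a, truth.outer_b)
    lc_true = truth.curvilinear()

    def reps(true_row, sd):
        return true_row[None, :] + rng.normal(0.0, sd, (k, N_SITES)) if sd > 0 \
            else np.tile(true_row, (k, 1))

    def us_reps(true_row):
        base = np.tile(true_row, (k, 1))
        if noise.us_log_sd > 0:
            base = base * rng.lognormal(0.0, noise.us_log_sd, (k, N_SITES))
        base[:, 0] = np.nan
        base[:, -1] = np.nan
        return base

    total = np.full(k, truth.total_length)
    if noise.sd_length > 0:
        total = total + rng.normal(0.0, noise.sd_length, k)
    return MorphometricProfile(
        animal_id=animal_id,
        girth=reps(girth_true, noise.sd_girth),
        height=reps(2.0 * truth.outer_b, noise.sd_height),
        width=reps(2.0 * truth.outer_a, noise.sd_width),
        curvilinear=reps(lc_true, noise.sd_length),
        total_length=total,
        mass=truth.true_masses()["total_mass_kg"],
        us_dorsal=us_reps(truth.sculp_dorsal),
        us_lateral=us_reps(truth.sculp_lateral),
    )


def make_dilution(true_tbw_ml: float, stock_cpm_ml: float = 1.5e8,
                  injected_g: float = 10.0, bg_cpm_ml: float = 30.0,
                  noise: NoiseModel | None = None, seed: int = 0,
                  n_replicates: int = 3, mass_kg: float | None = None,
                  animal_id: str = "synthetic") -> DilutionRecord:
    """Forward-simulate a labeled-water experiment with known TBW.

    The equilibrium concentration is the injected activity diluted into
    the true water pool, plus background; count noise is multiplicative
    with the model's CV.  At zero noise the TBW inversion is exact.
    """
    if true_tbw_ml <= 0:
        raise ValueError("true TBW must be positive")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    eq_true = injected_g * stock_cpm_ml / true_tbw_ml + bg_cpm_ml
    eq = np.full(n_replicates, eq_true)
    bg = np.full(n_replicates, bg_cpm_ml)
    if noise.count_cv > 0:
        eq = eq * (1.0 + noise.count_cv * rng.standard_normal(n_replicates))
        bg = bg * (1.0 + noise.count_cv * rng.standard_normal(n_replicates))
    if mass_kg is None:
        mass_kg = 1.6 * true_tbw_ml / 1000.0  # ~62% water body
    return DilutionRecord(
        animal_id=animal_id, injected_g=injected_g,
        stock_cpm_ml=(stock_cpm_ml, 0.0), eq_cpm_ml=eq, bg_cpm_ml=bg,
        mass_kg=mass_kg,
    )


def make_standards(stock_cpm_ml: float = 1.5e8, aliquot_ml: float = 0.01,
                   diluent_ml: float = 1000.0, bg_cpm_ml: float = 30.0,
                   n_standards: int = 3, n_replicates: int = 3,
                   noise: NoiseModel | None = None, seed: int = 0
                   ) -> list[StandardDilution]:
    """Forward-simulate injectate standard dilutions with known stock activity."""
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_standards):
        true_act = stock_cpm_ml * aliquot_ml / (diluent_ml + aliquot_ml)
        acts = np.full(n_replicates, true_act)
        if noise.count_cv > 0:
            acts = acts * (1.0 + noise.count_cv * rng.standard_normal(n_replicates))
        out.append(StandardDilution(aliquot_ml=aliquot_ml, diluent_ml=diluent_ml,
                                    activities_cpm_ml=acts + bg_cpm_ml,
                                    background_cpm_ml=bg_cpm_ml))
    return out


def make_regression(kind: str, params: dict, n: int, seed: int = 0):
    """Generate a dataset exactly under one of the three fitted likelihoods.

    kind 'simple': params beta0, beta1, sigma (+ optional x_range);
    returns (x, y).  kind 'shared_slope': params beta_u, intercepts
    (dict site -> value), sigma; returns (x, y, site).  kind 'logit':
    params alpha0, alpha1, sigma (+ optional water_range); residuals are
    scaled by the water ratio; returns (p_h2o, p_fat).
    """
    if n < 3:
        raise ValueError("need at least 3 points")
    rng = np.random.default_rng(seed)
    if kind == "simple":
        lo, hi = params.get("x_range", (50.0, 300.0))
        x = rng.uniform(lo, hi, n)
        y = params["beta0"] + params["beta1"] * x \
            + params["sigma"] * rng.standard_normal(n)
        return x, y
    if kind == "shared_slope":
        sites = list(params["intercepts"])
        site = np.array([sites[i % len(sites)] for i in range(n)])
        lo, hi = params.get("x_range", (1.5, 6.0))
        x = rng.uniform(lo, hi, n)
        icpt = np.array([params["intercepts"][s] for s in site])
        y = params["beta_u"] * x + icpt + params["sigma"] * rng.standard_normal(n)
        return x, y, site
    if kind == "logit":
        lo, hi = params.get("water_range", (0.40, 0.75))
        p_h2o = rng.uniform(lo, hi, n)
        ratio = p_h2o / (1.0 - p_h2o)
        z = params["alpha0"] + params["alpha1"] * ratio \
            + ratio * params["sigma"] * rng.standard_normal(n)
        p_fat = 1.0 / (1.0 + np.exp(-z))
        return p_h2o, p_fat
    raise ValueError(f"unknown regression kind {kind!r}")
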