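"""End-to-end composition pipelines built from the core modules.

Two estimators are assembled here: the cones pipeline (morphometrics ->
volumes -> tissue masses -> proportion fat) in its traditional and
modified configurations, and the labeled-water pipeline (counts -> TBW
-> proportion water -> proportion fat).  Both are also exposed as
vectorized closures over named inputs so the uncertainty module can
propagate measurement and parameter uncertainty through them at full
Monte Carlo size.
"""

from __future__ import annotations

import numpy as np

from . import geometry, tissue
from .geometry import (SITES, INTERIOR_SITES, DepthSource, Extent,
                       MorphometricProfile, Shape, partition_volumes)
from .tissue import TissueProperties, modified_estimate, traditional_estimate
from .uncertainty import InputDistribution, distribution_from_replicates

__all__ = [
    "cones_composition",
    "modified_cones_mc",
    "labeled_water_mc",
    "labeled_water_composition",
]


def cones_composition(profile: MorphometricProfile, method: str = "modified",
                      props: TissueProperties | None = None,
                      phase: str = "early") -> dict:
    """Full cones pipeline for one animal.

    'traditional': circular cones from girth, neck-to-pelvis extent, the
    mean of dorsal/lateral depths subtracted from both radii, sculp
    treated as blubber.  'modified': elliptical cones from height/width,
    full-body extent with end cones, skin separated at the configured
    skin depth, per-axis depth subtraction.
    """
    props = props or TissueProperties()
    if method == "traditional":
        part = partition_volumes(profile, skin_depth=0.0, shape=Shape.CIRCULAR,
                                 extent=Extent.NECK_TO_PELVIS,
                                 depth_source=DepthSource.MEAN)
        est = traditional_estimate(part.v_blubber, profile.mass, props)
    elif method == "modified":
        part = partition_volumes(profile, skin_depth=props.skin_depth_cm[0],
                                 shape=Shape.ELLIPTICAL, extent=Extent.FULL_BODY,
                                 depth_source=DepthSource.PER_AXIS)
        est = modified_estimate(part, profile.mass, props, phase)
    else:
        raise ValueError(f"unknown method {method!r}")
    full_volume, _ = geometry.body_volume(
        profile, part.shape, Extent.FULL_BODY)
    return {
        "partition": part,
        "composition": est,
        "body_density_g_ml": tissue.total_body_density(profile.mass, full_volume),
    }


# ---------------------------------------------------------------------------
# Vectorized cones estimator for Monte Carlo propagation


def _vector_partition(a, b, lc, total_length, skin_depth, dors, lat):
    """Full-body skin/blubber/core volumes, vectorized over leading axis.

    All site arrays have shape (..., 8).  Draws whose measurements are
    geometrically inconsistent (curvilinear shorter than the radial
    offset) propagate NaN and are excluded by the uncertainty module.
    """
    def seg_sum(aa, bb):
        dlc = np.diff(lc, axis=-1)
        db = np.diff(b, axis=-1)  # tape follows the outer surface
        with np.errstate(invalid="ignore"):
            ls = np.sqrt(dlc**2 - db**2)
        return np.sum(np.pi * ls / 6.0 * (
            2 * aa[..., :-1] * bb[..., :-1] + aa[..., 1:] * bb[..., :-1]
            + bb[..., 1:] * aa[..., :-1] + 2 * aa[..., 1:] * bb[..., 1:]),
            axis=-1)

    sd = skin_depth[..., None] if np.ndim(skin_depth) else skin_depth
    a_sk = np.clip(a - sd, 0.0, None)
    b_sk = np.clip(b - sd, 0.0, None)
    a_in = np.clip(a - lat, 0.0, None)
    b_in = np.clip(b - dors, 0.0, None)
    v_outer = seg_sum(a, b)
    v_total = (v_outer
               + np.pi * lc[..., 0] * a[..., 0] * b[..., 0] / 3.0
               + np.pi * (total_length - lc[..., -1]) * a[..., -1] * b[..., -1] / 3.0)
    v_skin = v_outer - seg_sum(a_sk, b_sk)
    v_blubber = seg_sum(a_sk, b_sk) - seg_sum(a_in, b_in)
    return v_total, v_skin, v_blubber


def modified_cones_mc(profile: MorphometricProfile,
                      props: TissueProperties | None = None,
                      phase: str = "early"):
    """Inputs and vectorized estimator for modified-cones proportion fat.

    Returns ``(inputs, estimator)`` for :func:`pinnicomp.uncertainty.propagate`
    / :func:`~pinnicomp.uncertainty.sensitivity_oat`.  Measurement inputs
    come from the triplicate replicates (normal; lognormal for
    ultrasound depths, all replicates treated as independent); tissue
    inputs come from the property config (normal for densities and skin
    depth, beta for fat proportions).  Total mass is held fixed — its
    measurement repeatability is below scale resolution.
    """
    props = props or TissueProperties()
    inputs = []
    for j, s in enumerate(SITES):
        inputs.append(distribution_from_replicates(f"H_{s}", profile.height[:, j]))
        inputs.append(distribution_from_replicates(f"W_{s}", profile.width[:, j]))
        inputs.append(distribution_from_replicates(f"CL_{s}", profile.curvilinear[:, j]))
    for j, s in enumerate(SITES):
        if s in INTERIOR_SITES:
            inputs.append(distribution_from_replicates(
                f"USD_{s}", profile.us_dorsal[:, j], family="lognormal"))
            inputs.append(distribution_from_replicates(
                f"USL_{s}", profile.us_lateral[:, j], family="lognormal"))
    inputs.append(distribution_from_replicates("NCL", profile.total_length))
    inputs.append(InputDistribution("SDepth", "normal", props.skin_depth_cm))
    inputs.append(InputDistribution("DensB", "normal", props.blubber_density))
    inputs.append(InputDistribution("DensD", "normal", props.skin_density))
    from .uncertainty import beta_from_moments
    inputs.append(InputDistribution(
        "FLB", "beta", beta_from_moments(*props.fat_in_blubber_for(phase))))
    inputs.append(InputDistribution(
        "FLD", "beta", beta_from_moments(*props.fat_in_skin)))
    mass = profile.mass

    def estimator(**kw):
        h = np.stack([np.asarray(kw[f"H_{s}"], dtype=float) for s in SITES], axis=-1)
        w = np.stack([np.asarray(kw[f"W_{s}"], dtype=float) for s in SITES], axis=-1)
        lc = np.stack([np.asarray(kw[f"CL_{s}"], dtype=float) for s in SITES], axis=-1)
        a, b = w / 2.0, h / 2.0
        sd = np.asarray(kw["SDepth"], dtype=float)
        shape = a.shape[:-1]
        dors = np.empty(shape + (len(SITES),))
        lat = np.empty(shape + (len(SITES),))
        for j, s in enumerate(SITES):
            if s in INTERIOR_SITES:
                dors[..., j] = kw[f"USD_{s}"]
                lat[..., j] = kw[f"USL_{s}"]
            else:
                dors[..., j] = sd
                lat[..., j] = sd
        _, v_skin, v_blubber = _vector_partition(
            a, b, lc, np.asarray(kw["NCL"], dtype=float), sd, dors, lat)
        blubber_mass = v_blubber * kw["DensB"] / 1000.0
        skin_mass = v_skin * kw["DensD"] / 1000.0
        fat = blubber_mass * kw["FLB"] + skin_mass * kw["FLD"]
        return fat / mass

    return inputs, estimator


# ---------------------------------------------------------------------------
# Labeled-water pipeline


def labeled_water_composition(record, water_fat_model) -> dict:
    """Point estimate of proportion water and fat for one dilution record."""
    from .dilution import fat_from_water_logit

    tbw_ml = record.tbw_ml()
    p_h2o = record.proportion_water()
    p_fat = fat_from_water_logit(p_h2o, water_fat_model)
    return {"tbw_ml": tbw_ml, "proportion_water": p_h2o, "proportion_fat": p_fat}


def labeled_water_mc(record, alpha_mean, alpha_cov):
    """Inputs and vectorized estimator for labeled-water proportion fat.

    ``alpha_mean``/``alpha_cov`` are the posterior mean and covariance
    of the logit water-to-fat parameters (alpha0, alpha1); their joint
    uncertainty enters through two standard-normal inputs mapped through
    the Cholesky factor, so the strong negative parameter correlation is
    preserved.  Count inputs are normal over the pooled replicates.
    """
    alpha_mean = np.asarray(alpha_mean, dtype=float)
    chol = np.linalg.cholesky(np.asarray(alpha_cov, dtype=float))
    inputs = [
        InputDistribution("CPM_stock", "normal", record.stock_cpm_ml),
        distribution_from_replicates("CPM_eq", record.eq_cpm_ml),
        distribution_from_replicates("CPM_bg", record.bg_cpm_ml),
        InputDistribution("WF_z1", "normal", (0.0, 1.0)),
        InputDistribution("WF_z2", "normal", (0.0, 1.0)),
    ]
    injected = record.injected_g
    mass_g = 1000.0 * record.mass_kg

    def estimator(**kw):
        net = np.asarray(kw["CPM_eq"], dtype=float) - kw["CPM_bg"]
        with np.errstate(divide="ignore", invalid="ignore"):
            tbw_ml = np.where(net > 0, injected * kw["CPM_stock"] / net, np.nan)
            p_h2o = tbw_ml / mass_g
            p_h2o = np.where((p_h2o > 0) & (p_h2o < 1), p_h2o, np.nan)
            x = p_h2o / (1.0 - p_h2o)
        z = np.stack([np.asarray(kw["WF_z1"], dtype=float),
                      np.asarray(kw["WF_z2"], dtype=float)])
        alpha = alpha_mean[:, None] + chol @ z.reshape(2, -1)
        a0 = alpha[0].reshape(np.shape(kw["WF_z1"]))
        a1 = alpha[1].reshape(np.shape(kw["WF_z1"]))
        return 1.0 / (1.0 + np.exp(-(a0 + a1 * x)))

    return inputs, estimator
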