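"""Labeled-water (isotope dilution) body-composition estimation.

Total body water (TBW) is the injected tracer activity divided by the
net equilibrium specific activity in blood water.  Proportion water is
then converted to proportion fat (or adipose tissue) under one of three
models: a heteroscedastic logit calibration fitted to carcass data, the
linear gray-seal rule (fat mass = total - 1.37 * water mass), or the
guinea-pig hydration-constant (Pace-Rathbun) conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "StandardDilution",
    "DilutionRecord",
    "WaterFatModel",
    "load_water_fat_config",
    "stock_specific_activity",
    "tbw",
    "proportion_water",
    "fat_from_water_logit",
    "fat_from_water_iverson",
    "adipose_and_fat_from_water_pr",
    "IVERSON_COEFFICIENT",
]

#: Linear water-to-fat coefficient from gray seal carcasses.
IVERSON_COEFFICIENT = 1.37


@dataclass
class StandardDilution:
    """One standard: a small injectate aliquot diluted into DI water.

    The measured activities [CPM/mL] of the diluted standard, less
    background, back-compute the stock specific activity.
    """

    aliquot_ml: float
    diluent_ml: float
    activities_cpm_ml: np.ndarray
    background_cpm_ml: float = 0.0

    def __post_init__(self):
        if self.aliquot_ml <= 0 or self.diluent_ml <= 0:
            raise ValueError("aliquot and diluent volumes must be positive")
        self.activities_cpm_ml = np.atleast_1d(
            np.asarray(self.activities_cpm_ml, dtype=float))
        if self.activities_cpm_ml.size < 1:
            raise ValueError("at least one replicate activity is required")

    def stock_estimates(self) -> np.ndarray:
        """Per-replicate back-computed stock activities [CPM/mL]."""
        net = self.activities_cpm_ml - self.background_cpm_ml
        if np.any(net <= 0):
            raise ValueError("net standard activity must be positive")
        return net * (self.diluent_ml + self.aliquot_ml) / self.aliquot_ml


@dataclass
class DilutionRecord:
    """One animal's labeled-water experiment."""

    animal_id: str
    injected_g: float
    stock_cpm_ml: tuple  # (mean, sd) of stock specific activity
    eq_cpm_ml: np.ndarray  # equilibrium replicates
    bg_cpm_ml: np.ndarray  # background replicates
    mass_kg: float

    def __post_init__(self):
        if self.injected_g <= 0:
            raise ValueError("injected mass must be positive")
        self.eq_cpm_ml = np.atleast_1d(np.asarray(self.eq_cpm_ml, dtype=float))
        self.bg_cpm_ml = np.atleast_1d(np.asarray(self.bg_cpm_ml, dtype=float))
        if self.eq_cpm_ml.mean() <= self.bg_cpm_ml.mean():
            raise ValueError("equilibrium activity must exceed background")

    def tbw_ml(self) -> float:
        """Point TBW from replicate means (injectate assumed 1 g/mL)."""
        cpm_inj = self.injected_g * self.stock_cpm_ml[0]
        return tbw(cpm_inj, float(self.eq_cpm_ml.mean()), float(self.bg_cpm_ml.mean()))

    def proportion_water(self) -> float:
        return proportion_water(self.tbw_ml(), self.mass_kg)


def stock_specific_activity(standards) -> tuple:
    """Stock specific activity (mean, sd) [CPM/mL] from standards.

    Each replicate of each standard back-computes one stock estimate;
    all estimates are pooled (treated as independent) into a normal
    (mean, sd) summary.
    """
    if isinstance(standards, StandardDilution):
        standards = [standards]
    if len(standards) == 0:
        raise ValueError("at least one standard is required")
    est = np.concatenate([s.stock_estimates() for s in standards])
    return float(est.mean()), float(est.std(ddof=1)) if est.size > 1 else 0.0


def tbw(cpm_inj: float, eq_cpm_ml: float, bg_cpm_ml: float) -> float:
    """Total body water [mL]: injected activity over net equilibrium activity."""
    if eq_cpm_ml <= bg_cpm_ml:
        raise ValueError("equilibrium activity must exceed background (no signal)")
    return cpm_inj / (eq_cpm_ml - bg_cpm_ml)


def proportion_water(tbw_ml: float, mass_kg: float) -> float:
    """Proportion of body mass that is water (water density 1 g/mL)."""
    if tbw_ml < 0:
        raise ValueError("TBW must be non-negative")
    if tbw_ml >= 1000.0 * mass_kg:
        raise ValueError("TBW cannot reach total body mass")
    return tbw_ml / (1000.0 * mass_kg)


@dataclass
class WaterFatModel:
    """Parameters for one of the three water-to-fat conversions.

    kind 'logit': alpha0, alpha1, sigma2 (optionally posterior draws with
    columns alpha0, alpha1, sigma2).  kind 'iverson': coefficient.  kind
    'pace_rathbun': (mean, sd) for w_adipose, w_lean, f_adipose plus the
    multiplicative water-bias adjustment.
    """

    kind: str
    params: dict = field(default_factory=dict)
    draws: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("logit", "iverson", "pace_rathbun"):
            raise ValueError(f"unknown water-fat model kind {self.kind!r}")
        if self.kind == "pace_rathbun":
            wa = self.params["w_adipose"][0]
            wl = self.params["w_lean"][0]
            if not (0 < wa < wl < 1):
                raise ValueError("need 0 < w_adipose < w_lean < 1")


def load_water_fat_config(path=None) -> dict:
    """Load the water-to-fat model defaults (package config when path is None)."""
    if path is None:
        text = (resources.files("pinnicomp") / "data/water_fat.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    pr = raw["pace_rathbun"]

    def pair(key):
        return (float(pr[key]["mean"]), float(pr[key]["sd"]))

    return {
        "logit": WaterFatModel("logit", dict(raw["logit"])),
        "iverson": WaterFatModel("iverson", dict(raw["iverson"])),
        "pace_rathbun": WaterFatModel("pace_rathbun", {
            "w_adipose": pair("w_adipose"),
            "w_lean": pair("w_lean"),
            "f_adipose": pair("f_adipose"),
            "water_bias_adjustment": float(pr["water_bias_adjustment"]),
        }),
    }


def _expit(z):
    return 1.0 / (1.0 + np.exp(-z))


def fat_from_water_logit(p_h2o: float, model: WaterFatModel,
                         rng: np.random.Generator | None = None,
                         predictive: bool = False):
    """Proportion fat from proportion water via the logit calibration.

    ``logit(P_fat) = alpha0 + alpha1 * x`` with water ratio
    ``x = P_H2O / (1 - P_H2O)``; the inverse logit keeps the output
    strictly inside (0, 1).  With posterior draws the induced fat
    distribution is returned; ``predictive=True`` additionally adds the
    heteroscedastic residual ``x * eps`` (its SD grows with the water
    ratio), requiring ``rng``.
    """
    if model.kind != "logit":
        raise ValueError("model kind must be 'logit'")
    if not 0.0 < p_h2o < 1.0:
        raise ValueError("proportion water must lie strictly in (0, 1)")
    x = p_h2o / (1.0 - p_h2o)
    if model.draws is not None:
        a0, a1 = model.draws[:, 0], model.draws[:, 1]
        z = a0 + a1 * x
        if predictive:
            if rng is None:
                raise ValueError("predictive draws require an rng")
            sigma = np.sqrt(model.draws[:, 2])
            z = z + x * rng.standard_normal(z.size) * sigma
        return _expit(z)
    z = model.params["alpha0"] + model.params["alpha1"] * x
    if predictive:
        if rng is None:
            raise ValueError("predictive draws require an rng")
        z = z + x * rng.standard_normal() * np.sqrt(model.params["sigma2"])
    return float(_expit(z))


def fat_from_water_iverson(p_h2o: float, coefficient: float = IVERSON_COEFFICIENT):
    """Linear gray-seal rule: ``P_fat = 1 - 1.37 * P_H2O``.

    Returns ``(proportion_fat, negative_flag)``; negative outputs are
    flagged, not clamped — the linear rule's known failure mode at high
    proportion water.
    """
    if not 0.0 <= p_h2o <= 1.0:
        raise ValueError("proportion water must lie in [0, 1]")
    p_fat = 1.0 - coefficient * p_h2o
    return p_fat, p_fat < 0.0


def adipose_and_fat_from_water_pr(p_h2o: float, model: WaterFatModel,
                                  rng: np.random.Generator | None = None,
                                  n_draws: int = 0):
    """Proportion adipose and fat via the guinea-pig hydration constants.

    The bias-adjusted proportion water ``P_adj = 0.967 * P_H2O`` places
    the body on the line between all-lean (water fraction w_lean) and
    all-adipose (w_adipose):
    ``P_adipose = (w_lean - P_adj) / (w_lean - w_adipose)``,
    ``P_fat = P_adipose * f_adipose``.  With ``n_draws > 0`` and an rng,
    beta-distributed parameter uncertainty is propagated by Monte Carlo.
    Out-of-model inputs clamp adipose to [0, 1] with a flag.
    """
    if model.kind != "pace_rathbun":
        raise ValueError("model kind must be 'pace_rathbun'")
    if not 0.0 < p_h2o < 1.0:
        raise ValueError("proportion water must lie strictly in (0, 1)")
    adj = model.params.get("water_bias_adjustment", 1.0)
    p_adj = adj * p_h2o

    def point(wa, wl, fa):
        adipose = (wl - p_adj) / (wl - wa)
        flagged = bool(np.any(adipose < 0) or np.any(adipose > 1))
        adipose = np.clip(adipose, 0.0, 1.0)
        return adipose, adipose * fa, flagged

    if n_draws > 0:
        if rng is None:
            raise ValueError("Monte Carlo draws require an rng")
        from .uncertainty import beta_from_moments
        samples = []
        for key in ("w_adipose", "w_lean", "f_adipose"):
            m, s = model.params[key]
            if s > 0:
                a, b = beta_from_moments(m, s)
                samples.append(rng.beta(a, b, n_draws))
            else:
                samples.append(np.full(n_draws, m))
        adipose, fat, flagged = point(*samples)
        return {"proportion_adipose": adipose, "proportion_fat": fat,
                "clamped": flagged}
    wa, _ = model.params["w_adipose"]
    wl, _ = model.params["w_lean"]
    fa, _ = model.params["f_adipose"]
    adipose, fat, flagged = point(wa, wl, fa)
    return {"proportion_adipose": float(adipose), "proportion_fat": float(fat),
            "clamped": flagged}
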