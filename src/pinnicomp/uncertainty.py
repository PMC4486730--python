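"""Monte Carlo uncertainty propagation and one-at-a-time sensitivity.

Measurement replicates and literature constants are summarized as named
input distributions (normal for most measurements, lognormal for
ultrasound depth readings, beta for proportions).  ``propagate`` pushes
joint draws through an arbitrary estimator; ``sensitivity_oat`` varies
one input at a time with all others held at their means, ranking inputs
by the output spread they alone induce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InputDistribution",
    "PropagationResult",
    "beta_from_moments",
    "distribution_from_replicates",
    "propagate",
    "sensitivity_oat",
]

DEFAULT_N = 15_000


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta shape parameters (alpha, beta) matching a mean and SD.

    Feasible only when ``sd^2 < mean * (1 - mean)``.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError("beta mean must lie strictly in (0, 1)")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ValueError("SD too large for a beta distribution with this mean")
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


@dataclass
class InputDistribution:
    """A named input with one of four sampling families.

    normal: params (mean, sd).  lognormal: params (mu, sigma) of the log
    (reserved for ultrasound depth readings — positive, right-skewed).
    beta: params (alpha, beta) (reserved for proportions).  fixed:
    params (value,).
    """

    name: str
    family: str
    params: tuple

    _FAMILIES = ("normal", "lognormal", "beta", "fixed")

    def __post_init__(self):
        if self.family not in self._FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        self.params = tuple(float(p) for p in self.params)
        if self.family in ("normal", "lognormal") and self.params[1] < 0:
            raise ValueError("SD must be non-negative")

    @property
    def mean(self) -> float:
        if self.family == "normal":
            return self.params[0]
        if self.family == "lognormal":
            mu, sig = self.params
            return float(np.exp(mu + 0.5 * sig * sig))
        if self.family == "beta":
            a, b = self.params
            return a / (a + b)
        return self.params[0]

    @property
    def sd(self) -> float:
        if self.family == "normal":
            return self.params[1]
        if self.family == "lognormal":
            mu, sig = self.params
            return float(np.sqrt((np.exp(sig * sig) - 1.0)
                                 * np.exp(2 * mu + sig * sig)))
        if self.family == "beta":
            a, b = self.params
            return float(np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0))))
        return 0.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "normal":
            m, s = self.params
            return rng.normal(m, s, n) if s > 0 else np.full(n, m)
        if self.family == "lognormal":
            mu, sig = self.params
            return rng.lognormal(mu, sig, n) if sig > 0 else np.full(n, np.exp(mu))
        if self.family == "beta":
            a, b = self.params
            return rng.beta(a, b, n)
        return np.full(n, self.params[0])


def distribution_from_replicates(name: str, values, family: str = "normal"
                                 ) -> InputDistribution:
    """Fit an input distribution to replicate measurements.

    normal: sample mean and SD.  lognormal: mean and SD of the log
    values (all replicates must be positive).  beta: moment-matched from
    the sample mean and SD.  A single replicate yields zero spread.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 1:
        raise ValueError("no finite replicate values")
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    mean = float(values.mean())
    if family == "normal":
        return InputDistribution(name, "normal", (mean, sd))
    if family == "lognormal":
        if np.any(values <= 0):
            raise ValueError("lognormal requires strictly positive replicates")
        logs = np.log(values)
        lsd = float(logs.std(ddof=1)) if values.size > 1 else 0.0
        return InputDistribution(name, "lognormal", (float(logs.mean()), lsd))
    if family == "beta":
        if sd == 0.0:
            return InputDistribution(name, "fixed", (mean,))
        return InputDistribution(name, "beta", beta_from_moments(mean, sd))
    if family == "fixed":
        return InputDistribution(name, "fixed", (mean,))
    raise ValueError(f"unknown family {family!r}")


@dataclass
class PropagationResult:
    """Summaries of Monte Carlo output draws."""

    draws: np.ndarray
    n: int
    seed: int
    n_failed: int = 0
    failed_fraction: float = 0.0

    mean: float = field(init=False)
    sd: float = field(init=False)
    interval_95: tuple = field(init=False)

    def __post_init__(self):
        d = self.draws
        self.mean = float(d.mean())
        self.sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
        lo, hi = np.percentile(d, [2.5, 97.5])
        self.interval_95 = (float(lo), float(hi))


def _evaluate(estimator, draws: dict, n: int, vectorized: bool,
              max_failure_fraction: float):
    if vectorized:
        out = np.asarray(estimator(**draws), dtype=float)
        bad = ~np.isfinite(out)
    else:
        out = np.empty(n)
        bad = np.zeros(n, dtype=bool)
        for i in range(n):
            point = {k: v[i] for k, v in draws.items()}
            try:
                out[i] = estimator(**point)
            except Exception:
                out[i] = np.nan
            bad[i] = not np.isfinite(out[i])
    frac = bad.mean()
    if frac > max_failure_fraction:
        raise RuntimeError(
            f"estimator failed on {frac:.1%} of draws "
            f"(limit {max_failure_fraction:.1%})")
    return out[~bad], int(bad.sum()), float(frac)


def propagate(estimator, inputs, n: int = DEFAULT_N, seed: int = 0,
              vectorized: bool = False,
              max_failure_fraction: float = 0.01) -> PropagationResult:
    """Push joint input draws through an estimator.

    ``inputs`` is an iterable of :class:`InputDistribution`; the
    estimator is called with one keyword argument per input name.
    Draws that raise or return non-finite values are recorded and
    excluded; the run aborts if their fraction exceeds
    ``max_failure_fraction``.
    """
    inputs = list(inputs)
    rng = np.random.default_rng(seed)
    draws = {d.name: d.sample(rng, n) for d in inputs}
    out, n_failed, frac = _evaluate(estimator, draws, n, vectorized,
                                    max_failure_fraction)
    return PropagationResult(draws=out, n=n, seed=seed,
                             n_failed=n_failed, failed_fraction=frac)


def sensitivity_oat(estimator, inputs, n: int = DEFAULT_N, seed: int = 0,
                    vectorized: bool = False,
                    max_failure_fraction: float = 0.01) -> pd.DataFrame:
    """One-at-a-time sensitivity: output SD when each input alone varies.

    Every input except one is pinned at its mean; the remaining one is
    drawn ``n`` times and the output SD recorded.  Returns a DataFrame
    sorted by descending output SD.
    """
    inputs = list(inputs)
    rows = []
    for k, target in enumerate(inputs):
        rng = np.random.default_rng((seed, k))
        draws = {}
        for d in inputs:
            if d.name == target.name:
                draws[d.name] = d.sample(rng, n)
            else:
                draws[d.name] = np.full(n, d.mean)
        out, _, _ = _evaluate(estimator, draws, n, vectorized,
                              max_failure_fraction)
        sd = float(out.std(ddof=1)) if out.size > 1 else 0.0
        rows.append({"input": target.name, "family": target.family,
                     "input_sd": target.sd, "output_sd": sd})
    frame = pd.DataFrame(rows).sort_values("output_sd", ascending=False)
    return frame.reset_index(drop=True)
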