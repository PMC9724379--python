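"""Method-of-moments parameterization and sampling of model inputs.

Each uncertain input is described by a mean (its deterministic base value)
and a standard deviation, plus a distribution family: beta for probabilities
and utilities, gamma for costs, lognormal for the treatment-effect
reduction, or fixed for quantities with no second-order uncertainty.  The
moment-matching formulas are closed-form and reproduce the requested
(mean, SD) exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

FAMILIES = ("beta", "gamma", "lognormal", "fixed")
# Parameter kinds whose draws must live in [0, 1] (clamped with a counted
# warning when the family can exceed it, e.g. lognormal effect reductions).
KINDS = ("probability", "utility", "cost", "effect", "wtp", "other")
UNIT_INTERVAL_KINDS = frozenset({"probability", "utility", "effect"})


class InfeasibleMomentsError(ValueError):
    pass


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta (alpha, beta) with the given mean and SD.

    alpha = mean * nu, beta = (1 - mean) * nu with
    nu = mean * (1 - mean) / sd**2 - 1.  Requires sd**2 < mean * (1 - mean).
    """
    if not 0.0 < mean < 1.0:
        raise InfeasibleMomentsError(f"beta mean must be in (0, 1), got {mean}")
    if sd <= 0.0:
        raise InfeasibleMomentsError(f"beta sd must be > 0, got {sd}")
    if sd * sd >= mean * (1.0 - mean):
        raise InfeasibleMomentsError(
            f"infeasible beta moments: sd^2 = {sd * sd} >= "
            f"mean*(1-mean) = {mean * (1.0 - mean)}"
        )
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Gamma (shape, scale) with the given mean and SD.

    shape = (mean / sd)**2, scale = sd**2 / mean.
    """
    if mean <= 0.0 or sd <= 0.0:
        raise InfeasibleMomentsError(
            f"gamma requires mean > 0 and sd > 0, got mean={mean}, sd={sd}"
        )
    return (mean / sd) ** 2, sd * sd / mean


def lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Lognormal (mu, sigma) on the log scale with the given natural-scale
    mean and SD: sigma^2 = ln(1 + (sd/mean)^2), mu = ln(mean) - sigma^2 / 2.
    """
    if mean <= 0.0 or sd <= 0.0:
        raise InfeasibleMomentsError(
            f"lognormal requires mean > 0 and sd > 0, got mean={mean}, sd={sd}"
        )
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclass(frozen=True)
class FittedDistribution:
    """A concrete sampling distribution with its shape parameters.

    ``params`` holds (alpha, beta) for beta, (shape, scale) for gamma,
    (mu, sigma) for lognormal and (value,) for fixed.
    """

    family: str
    params: tuple[float, ...]

    def __post_init__(self):
        if self.family in ("beta", "gamma") and any(p <= 0 for p in self.params):
            raise ValueError(
                f"non-positive shape parameter in {self.family}{self.params}"
            )
        if self.family == "lognormal" and self.params[1] <= 0:
            raise ValueError(f"non-positive lognormal sigma in {self.params}")

    def mean_sd(self) -> tuple[float, float]:
        """Analytic (mean, SD) of the fitted distribution."""
        if self.family == "beta":
            a, b = self.params
            m = a / (a + b)
            v = a * b / ((a + b) ** 2 * (a + b + 1.0))
            return m, math.sqrt(v)
        if self.family == "gamma":
            k, theta = self.params
            return k * theta, math.sqrt(k) * theta
        if self.family == "lognormal":
            mu, sigma = self.params
            m = math.exp(mu + sigma * sigma / 2.0)
            v = (math.exp(sigma * sigma) - 1.0) * m * m
            return m, math.sqrt(v)
        return self.params[0], 0.0

    def draw(self, rng: np.random.Generator, size: Optional[int] = None):
        if self.family == "beta":
            return rng.beta(*self.params, size=size)
        if self.family == "gamma":
            return rng.gamma(self.params[0], self.params[1], size=size)
        if self.family == "lognormal":
            return rng.lognormal(self.params[0], self.params[1], size=size)
        if size is None:
            return self.params[0]
        return np.full(size, self.params[0])


@dataclass(frozen=True)
class ParameterSpec:
    """One model-input row: base value, distribution family, SD, kind and an
    optional explicit one-way sensitivity range."""

    name: str
    base_value: float
    family: str = "fixed"
    sd: float = 0.0
    kind: str = "other"
    dsa_low: Optional[float] = None
    dsa_high: Optional[float] = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"{self.name}: unknown family {self.family!r}")
        if self.kind not in KINDS:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        if self.family == "fixed":
            if self.sd not in (0, 0.0):
                raise ValueError(f"{self.name}: fixed parameter must have sd 0")
        else:
            try:
                self.fit()
            except InfeasibleMomentsError as exc:
                raise InfeasibleMomentsError(f"{self.name}: {exc}") from None
        if self.dsa_low is not None and self.dsa_low > self.base_value:
            raise ValueError(f"{self.name}: dsa_low must be <= base_value")
        if self.dsa_high is not None and self.dsa_high < self.base_value:
            raise ValueError(f"{self.name}: dsa_high must be >= base_value")

    def fit(self) -> FittedDistribution:
        """Moment-match this spec's family to (base_value, sd)."""
        if self.family == "beta":
            return FittedDistribution("beta", beta_from_moments(self.base_value, self.sd))
        if self.family == "gamma":
            return FittedDistribution("gamma", gamma_from_moments(self.base_value, self.sd))
        if self.family == "lognormal":
            return FittedDistribution(
                "lognormal", lognormal_from_moments(self.base_value, self.sd)
            )
        return FittedDistribution("fixed", (self.base_value,))

    @property
    def clamp_to_unit(self) -> bool:
        return self.kind in UNIT_INTERVAL_KINDS


def sample_many(
    spec: ParameterSpec, rng: np.random.Generator, n: int
) -> tuple[np.ndarray, int]:
    """Draw ``n`` values; returns (values, clamp_count).

    Draws for probability-like, utility and effect parameters are clamped to
    [0, 1]; the number of clamped draws is returned and a warning is issued
    when it is nonzero.
    """
    fitted = spec.fit()
    values = np.asarray(fitted.draw(rng, size=n), dtype=float)
    clamped = 0
    if spec.clamp_to_unit:
        outside = (values < 0.0) | (values > 1.0)
        clamped = int(outside.sum())
        if clamped:
            warnings.warn(
                f"{spec.name}: clamped {clamped} draw(s) to [0, 1]",
                RuntimeWarning,
                stacklevel=2,
            )
            values = np.clip(values, 0.0, 1.0)
    return values, clamped


def sample(spec: ParameterSpec, rng: np.random.Generator) -> float:
    """Draw a single value from the spec's fitted distribution."""
    values, _ = sample_many(spec, rng, 1)
    return float(values[0])


@dataclass
class ParameterSampler:
    """Joint sampler over a set of parameters with per-parameter substreams.

    A single master seed is split (via ``numpy.random.SeedSequence.spawn``)
    into one independent child stream per parameter, assigned in sorted name
    order, so the draw sequence of each parameter is invariant to unrelated
    changes elsewhere in the model.
    """

    specs: dict[str, ParameterSpec]
    seed: int
    clamp_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        names = sorted(self.specs)
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        self._rngs = {
            name: np.random.default_rng(child)
            for name, child in zip(names, children)
        }

    def draw(self, n: int) -> dict[str, np.ndarray]:
        """Sample ``n`` joint parameter vectors, one array per parameter."""
        out: dict[str, np.ndarray] = {}
        for name in sorted(self.specs):
            values, clamped = sample_many(self.specs[name], self._rngs[name], n)
            self.clamp_counts[name] = self.clamp_counts.get(name, 0) + clamped
            out[name] = values
        return out
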