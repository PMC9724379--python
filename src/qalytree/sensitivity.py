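"""Sensitivity analyses: one-way deterministic (tornado) and second-order
Monte Carlo probabilistic sensitivity analysis with cost-effectiveness plane
and acceptability-curve summaries.

The tornado outcome metric is the incremental net monetary benefit (INMB)
at the model's willingness-to-pay threshold: the base case of the shipped
study is dominant, so an ICER would be undefined there.

The PSA samples every non-fixed parameter once per replication from its
moment-matched distribution and evaluates both strategies on the shared
binding, so parameters common to the arms induce the intended correlation.
Evaluation is vectorized: the tree is rolled back once on array-valued
bindings covering all replications.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.stats

from .distributions import ParameterSampler, UNIT_INTERVAL_KINDS
from .evaluation import StrategyOutcome
from .model import DecisionModel
from .tree import expected_values

logger = logging.getLogger(__name__)

DEFAULT_PSA_SEED = 0
EFFECT_CI_LEVEL = 0.95  # DSA range for lognormal effect parameters


class SensitivityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity analysis


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_input: float
    high_input: float
    outcome_at_low: float
    outcome_at_high: float
    base_outcome: float
    clipped: bool = False

    @property
    def spread(self) -> float:
        return abs(self.outcome_at_high - self.outcome_at_low)


def _inmb_at(model: DecisionModel, binding) -> float:
    outs = expected_values(model.tree, binding)
    c_ref, q_ref = outs[model.reference]
    c_int, q_int = outs[model.intervention]
    return float((q_int - q_ref) * model.wtp - (c_int - c_ref))


def _dsa_range(model: DecisionModel, spec, fraction: float) -> tuple[float, float, bool]:
    """Low/high inputs for a one-way analysis, plus a clipped flag.

    Explicit dsa_low/dsa_high win.  Lognormal effect parameters default to
    the central 95% interval of their fitted distribution (the uncertainty
    interval implied by the published CI); everything else uses
    base * (1 -/+ fraction).  Probabilities, utilities and effects are
    clipped to [0, 1].
    """
    if spec.dsa_low is not None and spec.dsa_high is not None:
        low, high = spec.dsa_low, spec.dsa_high
    elif spec.family == "lognormal":
        mu, sigma = spec.fit().params
        alpha = (1.0 - EFFECT_CI_LEVEL) / 2.0
        low = float(scipy.stats.lognorm.ppf(alpha, sigma, scale=np.exp(mu)))
        high = float(scipy.stats.lognorm.ppf(1.0 - alpha, sigma, scale=np.exp(mu)))
    else:
        low = spec.base_value * (1.0 - fraction)
        high = spec.base_value * (1.0 + fraction)

    clipped = False
    if spec.kind in UNIT_INTERVAL_KINDS:
        lo, hi = max(low, 0.0), min(high, 1.0)
        clipped = (lo, hi) != (low, high)
        low, high = lo, hi
    if low >= high:
        raise SensitivityError(
            f"{spec.name}: empty feasible one-way range [{low}, {high}]"
        )
    return low, high, clipped


def one_way_dsa(
    model: DecisionModel, parameter: str, fraction: float = 0.25
) -> TornadoEntry:
    """Vary one parameter over its range, all others at base values."""
    if parameter not in model.parameters:
        raise SensitivityError(f"unknown parameter {parameter!r}")
    spec = model.parameters[parameter]
    low, high, clipped = _dsa_range(model, spec, fraction)
    base = model.base_binding()
    base_outcome = _inmb_at(model, base)
    at_low = _inmb_at(model, {**base, parameter: low})
    at_high = _inmb_at(model, {**base, parameter: high})
    return TornadoEntry(
        parameter=parameter,
        low_input=low,
        high_input=high,
        outcome_at_low=at_low,
        outcome_at_high=at_high,
        base_outcome=base_outcome,
        clipped=clipped,
    )


def tornado(model: DecisionModel, fraction: float = 0.25) -> list[TornadoEntry]:
    """One-way analyses for every non-fixed parameter, widest spread first;
    ties broken alphabetically by parameter name."""
    names = [n for n, s in model.parameters.items() if s.family != "fixed"]
    if not names:
        raise SensitivityError("tornado requires at least one varying parameter")
    entries = [one_way_dsa(model, name, fraction) for name in names]
    return sorted(entries, key=lambda e: (-e.spread, e.parameter))


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low_input": [e.low_input for e in entries],
            "high_input": [e.high_input for e in entries],
            "inmb_at_low": [e.outcome_at_low for e in entries],
            "inmb_at_high": [e.outcome_at_high for e in entries],
            "spread": [e.spread for e in entries],
            "clipped": [e.clipped for e in entries],
        }
    )


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis


@dataclass(frozen=True)
class PSASample:
    """One PSA replication: the sampled binding and both strategies' outcomes."""

    iteration: int
    binding: dict[str, float]
    reference: StrategyOutcome
    intervention: StrategyOutcome
    delta_cost: float
    delta_qaly: float
    inmb: float


class PSAResult(Sequence):
    """Result of a PSA run; indexable as PSASample objects and exportable as
    a flat table.  All per-iteration quantities are held as arrays."""

    def __init__(
        self,
        model: DecisionModel,
        seed: int,
        bindings: dict[str, np.ndarray],
        cost_ref: np.ndarray,
        qaly_ref: np.ndarray,
        cost_int: np.ndarray,
        qaly_int: np.ndarray,
        clamp_counts: dict[str, int],
    ):
        self.model = model
        self.seed = seed
        self.bindings = bindings
        self.cost_ref = cost_ref
        self.qaly_ref = qaly_ref
        self.cost_int = cost_int
        self.qaly_int = qaly_int
        self.clamp_counts = clamp_counts
        self.delta_cost = cost_int - cost_ref
        self.delta_qaly = qaly_int - qaly_ref
        self.inmb = self.delta_qaly * model.wtp - self.delta_cost

    @property
    def n(self) -> int:
        return len(self.cost_ref)

    def __len__(self) -> int:
        return self.n

    def __getitem__(self, i: int) -> PSASample:
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(self.n))]
        if i < 0:
            i += self.n
        if not 0 <= i < self.n:
            raise IndexError(i)
        return PSASample(
            iteration=i,
            binding={k: float(v[i]) for k, v in self.bindings.items()},
            reference=StrategyOutcome(
                self.model.reference, float(self.cost_ref[i]), float(self.qaly_ref[i])
            ),
            intervention=StrategyOutcome(
                self.model.intervention, float(self.cost_int[i]), float(self.qaly_int[i])
            ),
            delta_cost=float(self.delta_cost[i]),
            delta_qaly=float(self.delta_qaly[i]),
            inmb=float(self.inmb[i]),
        )

    def table(self) -> pd.DataFrame:
        """Flat per-iteration table: parameters, outcomes, deltas, INMB."""
        data = {"iteration": np.arange(self.n)}
        for name in sorted(self.bindings):
            data[name] = self.bindings[name]
        ref, inter = self.model.reference, self.model.intervention
        data[f"cost_{ref}"] = self.cost_ref
        data[f"qaly_{ref}"] = self.qaly_ref
        data[f"cost_{inter}"] = self.cost_int
        data[f"qaly_{inter}"] = self.qaly_int
        data["delta_cost"] = self.delta_cost
        data["delta_qaly"] = self.delta_qaly
        data["inmb"] = self.inmb
        return pd.DataFrame(data)


def run_psa(
    model: DecisionModel, n: int = 10_000, seed: Optional[int] = None
) -> PSAResult:
    """Second-order Monte Carlo: ``n`` replications, each sampling every
    non-fixed parameter once and evaluating both strategies on the shared
    binding.  Reproducible given the seed."""
    if n < 1:
        raise SensitivityError(f"PSA needs n >= 1, got {n}")
    if seed is None:
        seed = model.seed if model.seed is not None else DEFAULT_PSA_SEED
        logger.info("run_psa: no seed supplied, defaulting to %d", seed)
    # surface infeasible specs before iteration 1
    for spec in model.parameters.values():
        spec.fit()

    sampler = ParameterSampler(model.parameters, seed)
    bindings = sampler.draw(n)
    outs = expected_values(model.tree, bindings)
    cost_ref, qaly_ref = outs[model.reference]
    cost_int, qaly_int = outs[model.intervention]
    full = np.broadcast_to  # fixed parameters resolve to scalars
    return PSAResult(
        model=model,
        seed=seed,
        bindings=bindings,
        cost_ref=np.asarray(full(cost_ref, (n,)), dtype=float).copy(),
        qaly_ref=np.asarray(full(qaly_ref, (n,)), dtype=float).copy(),
        cost_int=np.asarray(full(cost_int, (n,)), dtype=float).copy(),
        qaly_int=np.asarray(full(qaly_int, (n,)), dtype=float).copy(),
        clamp_counts=dict(sampler.clamp_counts),
    )


# ---------------------------------------------------------------------------
# PSA summaries

SamplesLike = Union[PSAResult, Iterable[PSASample]]


def _deltas(samples: SamplesLike) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """(delta_qaly, delta_cost, inmb, wtp) arrays from either representation."""
    if isinstance(samples, PSAResult):
        return samples.delta_qaly, samples.delta_cost, samples.inmb, samples.model.wtp
    items = list(samples)
    if not items:
        raise SensitivityError("empty PSA sample set")
    dq = np.array([s.delta_qaly for s in items])
    dc = np.array([s.delta_cost for s in items])
    inmb = np.array([s.inmb for s in items])
    # recover wtp from the identity inmb = dq*wtp - dc on any dq != 0 sample
    nz = np.nonzero(dq)[0]
    wtp = float((inmb[nz[0]] + dc[nz[0]]) / dq[nz[0]]) if len(nz) else 0.0
    return dq, dc, inmb, wtp


@dataclass(frozen=True)
class QuadrantSummary:
    """Cost-effectiveness-plane proportions keyed by delta signs.

    Zero deltas count to the favourable side: a zero QALY delta joins the
    "more effective" half and a zero cost delta joins the "cost-saving"
    half.  Quadrant numbering is deliberately not used.
    """

    gain_save: float  # dQ >= 0, dC < 0   (dominant direction)
    gain_cost: float  # dQ >= 0, dC >= 0
    loss_save: float  # dQ < 0,  dC < 0
    loss_cost: float  # dQ < 0,  dC >= 0  (dominated direction)
    cost_effective: float  # fraction with INMB > 0 at the model's WTP
    n: int

    def proportions(self) -> dict[tuple[str, str], float]:
        return {
            ("dq>=0", "dc<0"): self.gain_save,
            ("dq>=0", "dc>=0"): self.gain_cost,
            ("dq<0", "dc<0"): self.loss_save,
            ("dq<0", "dc>=0"): self.loss_cost,
        }


def quadrant_summary(samples: SamplesLike) -> QuadrantSummary:
    dq, dc, inmb, _ = _deltas(samples)
    n = len(dq)
    gain = dq >= 0
    save = dc < 0
    gain_save = float(np.mean(gain & save))
    gain_cost = float(np.mean(gain & ~save))
    loss_save = float(np.mean(~gain & save))
    # residual, so the four proportions sum to exactly 1.0 in float
    loss_cost = 1.0 - (gain_save + gain_cost + loss_save)
    return QuadrantSummary(
        gain_save=gain_save,
        gain_cost=gain_cost,
        loss_save=loss_save,
        loss_cost=loss_cost,
        cost_effective=float(np.mean(inmb > 0)),
        n=n,
    )


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    probability: float


def ceac(samples: SamplesLike, wtp_grid: Sequence[float]) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve.

    For each threshold in the grid the per-iteration INMB is recomputed from
    the stored deltas and the point records the fraction of replications
    with INMB > 0.
    """
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise SensitivityError("empty willingness-to-pay grid")
    if np.any(grid < 0):
        raise SensitivityError("willingness-to-pay grid must be non-negative")
    if np.any(np.diff(grid) < 0):
        raise SensitivityError("willingness-to-pay grid must be sorted ascending")
    dq, dc, _, _ = _deltas(samples)
    return [
        CEACPoint(float(w), float(np.mean(dq * w - dc > 0))) for w in grid
    ]


def ceac_frame(points: Sequence[CEACPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {"wtp": [p.wtp for p in points], "probability": [p.probability for p in points]}
    )
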