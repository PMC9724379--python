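"""Synthetic patient-level cohorts and parameter recovery.

The decision tree assumes a simple per-patient event structure over the
horizon: a Bernoulli repeat-RTI event (its probability scaled down in the
treated arm), Bernoulli mortality given an event, gamma-distributed episode
costs and fixed health-state utilities.  This module generates cohorts with
exactly that structure and recovers the generating parameters with standard
errors, so the full pipeline can be exercised end to end without any
external data.

Utilities are assigned state values rather than sampled per patient:
second-order uncertainty about the state utilities themselves belongs to
the PSA, not to patient-level variation.

Also hosts :func:`random_tree`, the random valid-tree generator used by the
rollback-vs-enumeration oracle tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import DecisionModel
from .tree import (
    ChanceBranch,
    ChanceNode,
    TerminalNode,
    TerminalPayoff,
    TreeNode,
)

ARMS = ("om85", "placebo")

COHORT_COLUMNS = [
    "arm",
    "repeat_event",
    "death",
    "episode_cost",
    "drug_cost",
    "utility",
]

#: Parameter names generate_cohort expects in the model's parameter table.
REQUIRED_PARAMS = ("p_repeat", "p_mort", "u_base", "u_rti", "c_rti", "c_drug", "reduction")


@dataclass(frozen=True)
class CohortRecord:
    arm: str
    repeat_event: bool
    death: bool
    episode_cost: float
    drug_cost: float
    utility: float

    def __post_init__(self):
        if self.death and not self.repeat_event:
            raise ValueError("death without a repeat event")
        if self.episode_cost < 0 or self.drug_cost < 0:
            raise ValueError("negative cost in cohort record")


def generate_cohort(
    n_per_arm: int, params: DecisionModel, seed: int
) -> list[CohortRecord]:
    """Simulate ``n_per_arm`` patients per arm under the model's parameters.

    Placebo repeat events are Bernoulli(p_repeat); the treated arm uses
    p_repeat * (1 - reduction).  Deaths are Bernoulli(p_mort) given an
    event; episode costs are drawn from the fitted gamma for c_rti; every
    treated patient incurs the drug cost at its base value.
    """
    if n_per_arm < 1:
        raise ValueError(f"n_per_arm must be >= 1, got {n_per_arm}")
    missing = [p for p in REQUIRED_PARAMS if p not in params.parameters]
    if missing:
        raise ValueError(f"model lacks required parameters: {missing}")
    spec = {name: params.parameters[name] for name in REQUIRED_PARAMS}
    for s in spec.values():
        s.fit()  # surface infeasible specs before generation

    p_repeat = spec["p_repeat"].base_value
    p_treated = p_repeat * (1.0 - spec["reduction"].base_value)
    p_mort = spec["p_mort"].base_value
    u_base = spec["u_base"].base_value
    u_rti = spec["u_rti"].base_value
    c_drug = spec["c_drug"].base_value
    cost_dist = spec["c_rti"].fit()

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    records: list[CohortRecord] = []
    for arm, p_event in (("om85", p_treated), ("placebo", p_repeat)):
        events = rng.random(n_per_arm) < p_event
        deaths = events & (rng.random(n_per_arm) < p_mort)
        costs = np.where(events, cost_dist.draw(rng, n_per_arm), 0.0)
        for i in range(n_per_arm):
            if deaths[i]:
                utility = 0.0
            elif events[i]:
                utility = u_rti
            else:
                utility = u_base
            records.append(
                CohortRecord(
                    arm=arm,
                    repeat_event=bool(events[i]),
                    death=bool(deaths[i]),
                    episode_cost=float(costs[i]),
                    drug_cost=c_drug if arm == "om85" else 0.0,
                    utility=utility,
                )
            )
    return records


@dataclass(frozen=True)
class RecoveredParameter:
    name: str
    estimate: Optional[float]
    se: Optional[float]
    n: int
    flag: str = ""


def _proportion(k: int, n: int) -> tuple[float, Optional[float]]:
    p = k / n
    se = math.sqrt(p * (1.0 - p) / n) if n > 1 else None
    return p, se


def estimate_params(cohort: Sequence[CohortRecord]) -> list[RecoveredParameter]:
    """Recover event rates, the implied reduction, the death rate given an
    event and the gamma event-cost moments, each with a standard error.

    The implied reduction is 1 - rate_om85 / rate_placebo (delta-method SE).
    The cost SD is estimated from event costs only — zero-cost non-events
    are excluded.  Degenerate inputs yield flags instead of crashes.
    """
    arms = {arm: [r for r in cohort if r.arm == arm] for arm in ARMS}
    if any(not recs for recs in arms.values()):
        raise ValueError("cohort must contain both arms")
    events_total = sum(r.repeat_event for r in cohort)
    if events_total == 0:
        raise ValueError("cohort contains no events; nothing to recover")

    out: list[RecoveredParameter] = []
    rates: dict[str, tuple[float, Optional[float], int]] = {}
    for arm in ARMS:
        recs = arms[arm]
        k = sum(r.repeat_event for r in recs)
        p, se = _proportion(k, len(recs))
        rates[arm] = (p, se, len(recs))
        out.append(
            RecoveredParameter(
                f"rate_{arm}", p, se, len(recs), "" if se is not None else "se undefined"
            )
        )

    p1, se1, n1 = rates["om85"]
    p0, se0, n0 = rates["placebo"]
    if p0 == 0.0:
        out.append(
            RecoveredParameter("reduction", None, None, n0 + n1, "no placebo events")
        )
    elif p1 == 0.0:
        out.append(RecoveredParameter("reduction", 1.0, None, n0 + n1, "no treated events"))
    else:
        ratio = p1 / p0
        if se1 is None or se0 is None:
            se_red, flag = None, "se undefined"
        else:
            # delta method on log(p1/p0)
            var_log = (1.0 - p1) / (n1 * p1) + (1.0 - p0) / (n0 * p0)
            se_red, flag = ratio * math.sqrt(var_log), ""
        out.append(RecoveredParameter("reduction", 1.0 - ratio, se_red, n0 + n1, flag))

    deaths = sum(r.death for r in cohort)
    p_mort, se_mort = _proportion(deaths, events_total)
    out.append(
        RecoveredParameter(
            "p_mort_given_event",
            p_mort,
            se_mort,
            events_total,
            "" if se_mort is not None else "se undefined",
        )
    )

    costs = np.array([r.episode_cost for r in cohort if r.repeat_event])
    mean = float(costs.mean())
    if len(costs) > 1:
        sd = float(costs.std(ddof=1))
        se_mean = sd / math.sqrt(len(costs))
        se_sd = sd / math.sqrt(2.0 * (len(costs) - 1.0))
        out.append(RecoveredParameter("cost_mean", mean, se_mean, len(costs)))
        out.append(RecoveredParameter("cost_sd", sd, se_sd, len(costs)))
    else:
        out.append(
            RecoveredParameter("cost_mean", mean, None, len(costs), "se undefined")
        )
        out.append(
            RecoveredParameter("cost_sd", None, None, len(costs), "single event cost")
        )
    return out


def recovered_frame(recovered: Sequence[RecoveredParameter]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in recovered])


# ---------------------------------------------------------------------------
# Cohort I/O (CSV + JSON metadata sidecar)


def write_cohort(
    cohort: Sequence[CohortRecord],
    path: Union[str, Path],
    metadata: Optional[dict] = None,
) -> None:
    path = Path(path)
    frame = pd.DataFrame([asdict(r) for r in cohort], columns=COHORT_COLUMNS)
    frame.to_csv(path, index=False, float_format="%.17g")
    if metadata is not None:
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(metadata, indent=2) + "\n"
        )


def read_cohort(path: Union[str, Path]) -> list[CohortRecord]:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(COHORT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"cohort file lacks columns: {sorted(missing)}")
    return [
        CohortRecord(
            arm=row.arm,
            repeat_event=bool(row.repeat_event),
            death=bool(row.death),
            episode_cost=float(row.episode_cost),
            drug_cost=float(row.drug_cost),
            utility=float(row.utility),
        )
        for row in frame.itertuples()
    ]


# ---------------------------------------------------------------------------
# Random valid trees (oracle-test generator)


def random_tree(depth: int, max_branching: int = 4, seed: int = 0) -> TreeNode:
    """A random valid chance/terminal tree of at most the given depth.

    Branch probabilities are normalized to sum to one, payoffs are random
    non-negative costs and utilities in [0, 1]; the same seed always yields
    the same tree.
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def build(level: int) -> TreeNode:
        if level >= depth - 1 or rng.random() < 0.3:
            return TerminalNode(
                TerminalPayoff(float(rng.uniform(0, 5000)), float(rng.uniform(0, 1)))
            )
        k = int(rng.integers(2, max_branching + 1))
        raw = rng.dirichlet(np.ones(k))
        # force exact unit sum despite float rounding
        probs = raw / raw.sum()
        probs[-1] = 1.0 - float(probs[:-1].sum())
        return ChanceNode(
            tuple(
                ChanceBranch(float(p), build(level + 1), label=f"b{i}")
                for i, p in enumerate(probs)
            )
        )

    return build(0)
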