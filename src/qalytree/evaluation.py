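"""Incremental cost-effectiveness metrics: ICER with dominance handling,
net monetary benefit (NMB) and incremental NMB (INMB)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

DOMINANT = "dominant"
DOMINATED = "dominated"
RATIO = "ratio"


@dataclass(frozen=True)
class StrategyOutcome:
    """Expected cost and expected QALY for one strategy.

    QALYs are carried on the health-state utility scale over the model's
    horizon; no annualization is applied (see the package README).
    """

    strategy: str
    expected_cost: float
    expected_qaly: float


def nmb(outcome: StrategyOutcome, wtp: float) -> float:
    """Net monetary benefit: expected_qaly * wtp - expected_cost."""
    if wtp < 0:
        raise ValueError(f"willingness-to-pay must be >= 0, got {wtp}")
    return outcome.expected_qaly * wtp - outcome.expected_cost


@dataclass(frozen=True)
class ComparisonResult:
    """Pairwise comparison of an intervention against a reference strategy.

    ``icer_status`` is one of ``dominant`` (intervention cheaper and more
    effective), ``dominated`` (costlier and less effective) or ``ratio``.
    ``icer_value`` is populated only when the ratio is meaningful: both
    deltas strictly share a sign.  A zero QALY delta under ``ratio`` status
    sets ``icer_undefined``.
    """

    reference: str
    intervention: str
    delta_cost: float
    delta_qaly: float
    icer_status: str
    icer_value: Optional[float]
    icer_undefined: bool
    nmb_reference: float
    nmb_intervention: float
    inmb: float
    wtp: float


def compare(
    reference: StrategyOutcome, intervention: StrategyOutcome, wtp: float
) -> ComparisonResult:
    """Compare two strategies at a willingness-to-pay threshold.

    Dominance is decided before any ratio is formed; the ICER value is
    withheld whenever opposing signs would make it misleading.  Strict
    inequalities define dominance, so exact-zero deltas fall through to
    ``ratio`` status.
    """
    if reference.strategy == intervention.strategy:
        raise ValueError("compare() requires two distinct strategies")
    dc = intervention.expected_cost - reference.expected_cost
    dq = intervention.expected_qaly - reference.expected_qaly

    if dc < 0 and dq > 0:
        status, value, undefined = DOMINANT, None, False
    elif dc > 0 and dq < 0:
        status, value, undefined = DOMINATED, None, False
    else:
        status = RATIO
        if dq == 0:
            value, undefined = None, True
        elif (dc > 0 and dq > 0) or (dc < 0 and dq < 0):
            value, undefined = dc / dq, False
        else:
            value, undefined = None, False

    nmb_ref = nmb(reference, wtp)
    nmb_int = nmb(intervention, wtp)
    return ComparisonResult(
        reference=reference.strategy,
        intervention=intervention.strategy,
        delta_cost=dc,
        delta_qaly=dq,
        icer_status=status,
        icer_value=value,
        icer_undefined=undefined,
        nmb_reference=nmb_ref,
        nmb_intervention=nmb_int,
        inmb=dq * wtp - dc,
        wtp=wtp,
    )
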