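"""The OM-85 BV recurrent-RTI cost-utility study as a packaged configuration.

A two-strategy decision tree over a six-month horizon: each arm faces a
chance of a repeat respiratory-tract-infection episode; a repeat episode
carries a treatment cost, a lowered health-state utility and a small
mortality risk (death utility 0).  The OM-85 arm multiplies the repeat
probability by ``1 - reduction`` and charges the drug cost to every patient
in the arm.

QALYs are reported on the utility scale over the six-month horizon; they
are NOT multiplied by 0.5 years.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path
from typing import Optional

from .distributions import ParameterSpec
from .model import DecisionModel
from .tree import (
    ChanceBranch,
    ChanceNode,
    DecisionNode,
    TerminalNode,
    TerminalPayoff,
    TreeNode,
    add_terminal_cost,
)

PLACEBO = "placebo"
OM85 = "om85"

HORIZON = "6 months"
WTP = 5180.0
N_PSA = 10_000
DSA_FRACTION = 0.25

#: Model inputs: mean (base value), distribution family and SD per parameter.
PARAMETER_TABLE: tuple[ParameterSpec, ...] = (
    ParameterSpec("p_repeat", 0.20, "beta", 0.05, kind="probability"),
    ParameterSpec("p_mort", 0.008, "beta", 0.001, kind="probability"),
    ParameterSpec("u_base", 0.94, "beta", 0.01, kind="utility"),
    ParameterSpec("u_rti", 0.87, "beta", 0.2, kind="utility"),
    ParameterSpec("c_rti", 2022.0, "gamma", 505.0, kind="cost"),
    ParameterSpec("c_drug", 74.0, "gamma", 18.5, kind="cost"),
    ParameterSpec("reduction", 0.65, "lognormal", 0.07, kind="effect"),
    ParameterSpec("wtp", WTP, "fixed", 0.0, kind="wtp"),
)


def _arm(repeat_prob: str) -> TreeNode:
    """One strategy arm: chance(repeat) -> chance(die/survive); else well."""
    repeat_subtree = ChanceNode(
        (
            ChanceBranch(
                "1 - p_mort",
                TerminalNode(TerminalPayoff("c_rti", "u_rti")),
                label="survive",
            ),
            ChanceBranch(
                "p_mort",
                TerminalNode(TerminalPayoff("c_rti", 0.0)),
                label="die",
            ),
        )
    )
    return ChanceNode(
        (
            ChanceBranch(repeat_prob, repeat_subtree, label="repeat_rti"),
            ChanceBranch(
                f"1 - ({repeat_prob})",
                TerminalNode(TerminalPayoff(0.0, "u_base")),
                label="no_repeat",
            ),
        )
    )


def build_tree() -> DecisionNode:
    placebo_arm = _arm("p_repeat")
    om85_arm = add_terminal_cost(_arm("p_repeat * (1 - reduction)"), "c_drug")
    return DecisionNode({OM85: om85_arm, PLACEBO: placebo_arm})


def build_om85_model(seed: Optional[int] = None) -> DecisionModel:
    """The study model with all inputs at their published values."""
    return DecisionModel(
        name="om85-rrti-cua",
        parameters={spec.name: spec for spec in PARAMETER_TABLE},
        tree=build_tree(),
        reference=PLACEBO,
        intervention=OM85,
        wtp=WTP,
        horizon=HORIZON,
        n_psa=N_PSA,
        dsa_fraction=DSA_FRACTION,
        seed=seed,
        metadata={"parameterization": "method of moments"},
    )


def bundled_config_path() -> Path:
    """Path of the shipped ``om85.json`` model configuration."""
    return Path(importlib.resources.files("qalytree.data") / "om85.json")


def reproduce_results(
    seed: int,
    outdir: Optional[Path] = None,
    n_psa: int = N_PSA,
    plots: bool = False,
) -> dict:
    """Run the full study pipeline and (optionally) write the report files.

    Emits the base-case comparison with its dominance verdict, the tornado
    table, the PSA quadrant/CEAC summaries and run metadata.  Output is a
    pure function of (configuration, seed): re-running writes identical
    files.
    """
    from . import reporting  # local import to keep module load light

    model = build_om85_model(seed=seed)
    return reporting.run_report(model, seed=seed, n_psa=n_psa, outdir=outdir, plots=plots)
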