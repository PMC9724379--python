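"""A decision model bundles a tree with its parameter table and analysis
settings (WTP, PSA size, DSA fraction)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .distributions import ParameterSpec
from .evaluation import ComparisonResult, StrategyOutcome, compare
from .tree import (
    DecisionNode,
    TreeNode,
    referenced_parameters,
    rollback,
    validate_tree,
)

DEFAULT_WTP_GRID_POINTS = 51


@dataclass
class DecisionModel:
    name: str
    parameters: dict[str, ParameterSpec]
    tree: TreeNode
    reference: str
    intervention: str
    wtp: float
    horizon: str = ""
    n_psa: int = 10_000
    dsa_fraction: float = 0.25
    wtp_grid: Optional[np.ndarray] = None
    seed: Optional[int] = None
    metadata: dict = field(default_factory=dict)

    def base_binding(self) -> dict[str, float]:
        return {name: spec.base_value for name, spec in self.parameters.items()}

    def default_wtp_grid(self) -> np.ndarray:
        """0 to 2*WTP in 51 evenly spaced points, unless overridden."""
        if self.wtp_grid is not None:
            return np.asarray(self.wtp_grid, dtype=float)
        return np.linspace(0.0, 2.0 * self.wtp, DEFAULT_WTP_GRID_POINTS)

    def validate(self) -> list[str]:
        """Structural + numeric tree diagnostics plus dangling-reference checks."""
        diagnostics = validate_tree(self.tree, self.base_binding())
        missing = referenced_parameters(self.tree) - set(self.parameters)
        for name in sorted(missing):
            diagnostics.append(f"tree references undefined parameter {name!r}")
        if isinstance(self.tree, DecisionNode):
            for strat in (self.reference, self.intervention):
                if strat not in self.tree.strategies:
                    diagnostics.append(f"strategy {strat!r} not present in tree")
        if self.wtp < 0:
            diagnostics.append(f"willingness-to-pay {self.wtp} is negative")
        return diagnostics

    def outcomes(self, binding=None) -> dict[str, StrategyOutcome]:
        return rollback(self.tree, binding if binding is not None else self.base_binding())

    def base_case(self) -> ComparisonResult:
        """Deterministic comparison of intervention vs reference at base values."""
        outs = self.outcomes()
        return compare(outs[self.reference], outs[self.intervention], self.wtp)
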