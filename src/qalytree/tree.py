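"""Decision-tree representation and evaluation.

Trees are built from three node kinds: a ``DecisionNode`` (root only) whose
children are named strategies, ``ChanceNode``s whose branches carry
probabilities, and ``TerminalNode``s carrying a cost/utility payoff.
Probabilities and payoffs may be numeric literals or expressions over named
parameters (see :mod:`qalytree.expressions`).

Two independent evaluation routes are provided: :func:`rollback`
(leaves-to-root expected values, vectorizable over parameter arrays) and
:func:`enumerate_paths` (exhaustive root-to-leaf enumeration, the test
oracle).  Probability-weighted path aggregation must agree with rollback to
floating-point accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Union

from .evaluation import StrategyOutcome
from .expressions import Quantity, expression_names, resolve

PROB_TOL = 1e-9

ROOT_STRATEGY = "root"  # strategy label used when the root is not a decision


@dataclass(frozen=True)
class TerminalPayoff:
    cost: Quantity
    utility: Quantity


@dataclass(frozen=True)
class TerminalNode:
    payoff: TerminalPayoff


@dataclass(frozen=True)
class ChanceBranch:
    probability: Quantity
    child: "TreeNode"
    label: str = ""


@dataclass(frozen=True)
class ChanceNode:
    branches: tuple[ChanceBranch, ...]

    def __post_init__(self):
        object.__setattr__(self, "branches", tuple(self.branches))


@dataclass(frozen=True)
class DecisionNode:
    strategies: dict[str, "TreeNode"] = field(default_factory=dict)


TreeNode = Union[DecisionNode, ChanceNode, TerminalNode]

ParameterBinding = Mapping[str, object]


class TreeEvaluationError(ValueError):
    pass


def iter_nodes(root: TreeNode) -> Iterator[tuple[str, TreeNode]]:
    """Depth-first (path, node) pairs; paths are '/'-joined labels."""
    stack = [("root", root)]
    while stack:
        path, node = stack.pop()
        yield path, node
        if isinstance(node, DecisionNode):
            for name, child in reversed(list(node.strategies.items())):
                stack.append((f"{path}/{name}", child))
        elif isinstance(node, ChanceNode):
            for i, br in enumerate(reversed(node.branches)):
                j = len(node.branches) - 1 - i
                label = br.label or f"branch[{j}]"
                stack.append((f"{path}/{label}", br.child))


def referenced_parameters(root: TreeNode) -> frozenset[str]:
    """All parameter names appearing in probabilities or payoffs."""
    names: set[str] = set()
    for _, node in iter_nodes(root):
        if isinstance(node, ChanceNode):
            for br in node.branches:
                names |= expression_names(br.probability)
        elif isinstance(node, TerminalNode):
            names |= expression_names(node.payoff.cost)
            names |= expression_names(node.payoff.utility)
    return frozenset(names)


def _try_resolve(quantity: Quantity, binding: Optional[ParameterBinding]):
    """Resolve if possible; None when an expression needs an absent binding."""
    try:
        return resolve(quantity, binding or {})
    except KeyError:
        return None


def validate_tree(
    root: TreeNode, binding: Optional[ParameterBinding] = None
) -> list[str]:
    """Return a list of human-readable diagnostics; empty iff the tree is valid.

    Structural rules are always checked (decision node only at the root,
    acyclicity).  Numeric rules (branch probabilities in [0,1] summing to 1,
    payoff ranges) are checked for every quantity that is a literal or is
    resolvable through ``binding``; unresolvable expressions are skipped.
    """
    diagnostics: list[str] = []

    def walk(node: TreeNode, path: str, ancestors: frozenset[int], at_root: bool):
        if id(node) in ancestors:
            diagnostics.append(f"{path}: cycle detected")
            return
        ancestors = ancestors | {id(node)}
        if isinstance(node, DecisionNode):
            if not at_root:
                diagnostics.append(f"{path}: non-root decision node")
            if not node.strategies:
                diagnostics.append(f"{path}: decision node has no strategies")
            for name, child in node.strategies.items():
                walk(child, f"{path}/{name}", ancestors, False)
        elif isinstance(node, ChanceNode):
            if not node.branches:
                diagnostics.append(f"{path}: chance node has no branches")
            probs = [_try_resolve(br.probability, binding) for br in node.branches]
            for i, p in enumerate(probs):
                if p is not None and not (0.0 <= p <= 1.0):
                    diagnostics.append(
                        f"{path}/branch[{i}]: probability {p} outside [0, 1]"
                    )
            if node.branches and all(p is not None for p in probs):
                total = sum(probs)  # type: ignore[arg-type]
                if abs(total - 1.0) > PROB_TOL:
                    diagnostics.append(
                        f"{path}: branch probabilities sum to {total}, not 1"
                    )
            for i, br in enumerate(node.branches):
                label = br.label or f"branch[{i}]"
                walk(br.child, f"{path}/{label}", ancestors, False)
        elif isinstance(node, TerminalNode):
            cost = _try_resolve(node.payoff.cost, binding)
            util = _try_resolve(node.payoff.utility, binding)
            if cost is not None and cost < 0:
                diagnostics.append(f"{path}: negative terminal cost {cost}")
            if util is not None and not (0.0 <= util <= 1.0):
                diagnostics.append(f"{path}: terminal utility {util} outside [0, 1]")
        else:
            diagnostics.append(f"{path}: unknown node type {type(node).__name__}")

    walk(root, "root", frozenset(), True)
    return diagnostics


def _expected(node: TreeNode, binding: ParameterBinding):
    """Expected (cost, utility) of a strategy subtree.

    Works elementwise when binding values are numpy arrays, which is how the
    PSA evaluates all replications at once.
    """
    if isinstance(node, TerminalNode):
        return (
            resolve(node.payoff.cost, binding),
            resolve(node.payoff.utility, binding),
        )
    if isinstance(node, ChanceNode):
        cost = 0.0
        utility = 0.0
        for br in node.branches:
            p = resolve(br.probability, binding)
            c, u = _expected(br.child, binding)
            cost = cost + p * c
            utility = utility + p * u
        return cost, utility
    if isinstance(node, DecisionNode):
        raise TreeEvaluationError("decision node encountered below the root")
    raise TreeEvaluationError(f"unresolved node type {type(node).__name__}")


def expected_values(root: TreeNode, binding: ParameterBinding) -> dict[str, tuple]:
    """Per-strategy expected (cost, utility); supports array-valued bindings."""
    if isinstance(root, DecisionNode):
        return {
            name: _expected(child, binding)
            for name, child in root.strategies.items()
        }
    return {ROOT_STRATEGY: _expected(root, binding)}


def rollback(root: TreeNode, binding: ParameterBinding) -> dict[str, StrategyOutcome]:
    """Expected-value rollback: map strategy name -> StrategyOutcome."""
    return {
        name: StrategyOutcome(name, float(cost), float(utility))
        for name, (cost, utility) in expected_values(root, binding).items()
    }


@dataclass(frozen=True)
class TreePath:
    strategy: str
    probability: float
    cost: float
    utility: float
    labels: tuple[str, ...] = ()


def enumerate_paths(root: TreeNode, binding: ParameterBinding) -> list[TreePath]:
    """Exhaustive root-to-leaf path enumeration (the rollback oracle)."""
    paths: list[TreePath] = []

    def walk(node: TreeNode, strategy: str, prob: float, labels: tuple[str, ...]):
        if isinstance(node, TerminalNode):
            paths.append(
                TreePath(
                    strategy=strategy,
                    probability=prob,
                    cost=float(resolve(node.payoff.cost, binding)),
                    utility=float(resolve(node.payoff.utility, binding)),
                    labels=labels,
                )
            )
        elif isinstance(node, ChanceNode):
            for i, br in enumerate(node.branches):
                p = float(resolve(br.probability, binding))
                walk(br.child, strategy, prob * p, labels + (br.label or f"branch[{i}]",))
        elif isinstance(node, DecisionNode):
            raise TreeEvaluationError("decision node encountered below the root")
        else:
            raise TreeEvaluationError(f"unresolved node type {type(node).__name__}")

    if isinstance(root, DecisionNode):
        for name, child in root.strategies.items():
            walk(child, name, 1.0, ())
    else:
        walk(root, ROOT_STRATEGY, 1.0, ())
    return paths


def aggregate_paths(paths: list[TreePath]) -> dict[str, StrategyOutcome]:
    """Probability-weighted aggregation of enumerated paths, per strategy."""
    outcomes: dict[str, StrategyOutcome] = {}
    strategies = dict.fromkeys(p.strategy for p in paths)
    for strat in strategies:
        mine = [p for p in paths if p.strategy == strat]
        cost = sum(p.probability * p.cost for p in mine)
        utility = sum(p.probability * p.utility for p in mine)
        outcomes[strat] = StrategyOutcome(strat, cost, utility)
    return outcomes


def map_terminals(node: TreeNode, fn) -> TreeNode:
    """Structure-preserving rewrite applying ``fn`` to every TerminalPayoff."""
    if isinstance(node, TerminalNode):
        return TerminalNode(fn(node.payoff))
    if isinstance(node, ChanceNode):
        return ChanceNode(
            tuple(
                ChanceBranch(br.probability, map_terminals(br.child, fn), br.label)
                for br in node.branches
            )
        )
    if isinstance(node, DecisionNode):
        return DecisionNode(
            {n: map_terminals(c, fn) for n, c in node.strategies.items()}
        )
    raise TreeEvaluationError(f"unresolved node type {type(node).__name__}")


def add_terminal_cost(node: TreeNode, extra: Quantity) -> TreeNode:
    """Add a (possibly expression-valued) cost to every terminal payoff.

    Attaching a strategy-level additive cost this way is rollback-equivalent
    to charging it once at the strategy root, since path probabilities sum
    to one.
    """

    def bump(payoff: TerminalPayoff) -> TerminalPayoff:
        if isinstance(payoff.cost, str) or isinstance(extra, str):
            base = payoff.cost if isinstance(payoff.cost, str) else repr(payoff.cost)
            add = extra if isinstance(extra, str) else repr(extra)
            return TerminalPayoff(f"({base}) + ({add})", payoff.utility)
        return TerminalPayoff(payoff.cost + extra, payoff.utility)

    return map_terminals(node, bump)
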