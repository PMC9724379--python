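"""Reading and writing model configurations (strict JSON schema).

A configuration file fully describes a model: the parameter table, the tree
topology (node kind tags ``decision`` | ``chance`` | ``terminal``), the two
compared strategies and the analysis settings.  Validation is exhaustive —
all errors are collected and reported together, not just the first.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np

from .distributions import ParameterSpec
from .model import DecisionModel
from .tree import (
    ChanceBranch,
    ChanceNode,
    DecisionNode,
    TerminalNode,
    TerminalPayoff,
    TreeNode,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

_TOP_KEYS = {"schema_version", "name", "horizon", "strategies", "parameters", "analysis", "tree"}
_PARAM_KEYS = {"name", "base_value", "family", "sd", "kind", "dsa_low", "dsa_high"}
_ANALYSIS_KEYS = {"wtp", "n_psa", "seed", "dsa_fraction", "wtp_grid"}
_STRATEGY_KEYS = {"reference", "intervention"}


class ConfigError(ValueError):
    """Carries the full list of validation errors for a configuration."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid model configuration:\n" + "\n".join(f"  - {e}" for e in errors))


def _check_keys(obj: dict, allowed: set, where: str, errors: list[str]) -> None:
    for key in set(obj) - allowed:
        errors.append(f"{where}: unknown key {key!r}")


def _parse_tree(node: Any, where: str, errors: list[str]) -> Optional[TreeNode]:
    if not isinstance(node, dict):
        errors.append(f"{where}: node must be an object")
        return None
    kind = node.get("kind")
    if kind == "decision":
        _check_keys(node, {"kind", "strategies"}, where, errors)
        strategies = node.get("strategies")
        if not isinstance(strategies, dict) or not strategies:
            errors.append(f"{where}: decision node needs a non-empty 'strategies' map")
            return None
        children = {
            name: _parse_tree(child, f"{where}/{name}", errors)
            for name, child in strategies.items()
        }
        if any(c is None for c in children.values()):
            return None
        return DecisionNode(children)  # type: ignore[arg-type]
    if kind == "chance":
        _check_keys(node, {"kind", "branches"}, where, errors)
        branches = node.get("branches")
        if not isinstance(branches, list) or not branches:
            errors.append(f"{where}: chance node needs a non-empty 'branches' list")
            return None
        parsed = []
        for i, raw in enumerate(branches):
            bwhere = f"{where}/branch[{i}]"
            if not isinstance(raw, dict):
                errors.append(f"{bwhere}: branch must be an object")
                return None
            _check_keys(raw, {"probability", "child", "label"}, bwhere, errors)
            if "probability" not in raw or "child" not in raw:
                errors.append(f"{bwhere}: branch needs 'probability' and 'child'")
                return None
            child = _parse_tree(raw["child"], bwhere, errors)
            if child is None:
                return None
            parsed.append(ChanceBranch(raw["probability"], child, raw.get("label", "")))
        return ChanceNode(tuple(parsed))
    if kind == "terminal":
        _check_keys(node, {"kind", "cost", "utility"}, where, errors)
        if "cost" not in node or "utility" not in node:
            errors.append(f"{where}: terminal node needs 'cost' and 'utility'")
            return None
        return TerminalNode(TerminalPayoff(node["cost"], node["utility"]))
    errors.append(f"{where}: unknown node kind {kind!r}")
    return None


def _parse_parameters(raw: Any, errors: list[str]) -> dict[str, ParameterSpec]:
    specs: dict[str, ParameterSpec] = {}
    if not isinstance(raw, list):
        errors.append("parameters: must be a list")
        return specs
    for i, row in enumerate(raw):
        where = f"parameters[{i}]"
        if not isinstance(row, dict):
            errors.append(f"{where}: must be an object")
            continue
        _check_keys(row, _PARAM_KEYS, where, errors)
        if "name" not in row or "base_value" not in row:
            errors.append(f"{where}: needs 'name' and 'base_value'")
            continue
        name = row["name"]
        if name in specs:
            errors.append(f"{where}: duplicate parameter {name!r}")
            continue
        try:
            specs[name] = ParameterSpec(
                name=name,
                base_value=float(row["base_value"]),
                family=row.get("family", "fixed"),
                sd=float(row.get("sd", 0.0)),
                kind=row.get("kind", "other"),
                dsa_low=row.get("dsa_low"),
                dsa_high=row.get("dsa_high"),
            )
        except (TypeError, ValueError) as exc:
            errors.append(f"{where}: {exc}")
    return specs


def parse_config(raw: dict, source: str = "<config>") -> DecisionModel:
    """Validate a configuration dict and build the model, or raise
    :class:`ConfigError` listing every problem found."""
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError([f"{source}: top level must be an object"])
    _check_keys(raw, _TOP_KEYS, source, errors)

    version = raw.get("schema_version")
    if version != SCHEMA_VERSION:
        errors.append(f"schema_version: expected {SCHEMA_VERSION}, got {version!r}")

    strategies = raw.get("strategies")
    reference = intervention = None
    if not isinstance(strategies, dict):
        errors.append("strategies: must be an object with 'reference' and 'intervention'")
    else:
        _check_keys(strategies, _STRATEGY_KEYS, "strategies", errors)
        reference = strategies.get("reference")
        intervention = strategies.get("intervention")
        if not reference or not intervention:
            errors.append("strategies: both 'reference' and 'intervention' are required")

    specs = _parse_parameters(raw.get("parameters"), errors)

    analysis = raw.get("analysis")
    wtp = None
    n_psa, seed, dsa_fraction, wtp_grid = 10_000, None, 0.25, None
    if not isinstance(analysis, dict):
        errors.append("analysis: must be an object (with at least 'wtp')")
    else:
        _check_keys(analysis, _ANALYSIS_KEYS, "analysis", errors)
        if "wtp" not in analysis:
            errors.append("analysis: 'wtp' (willingness-to-pay) is required")
        else:
            wtp = float(analysis["wtp"])
            fixed_wtp = specs.get("wtp")
            if fixed_wtp is not None and fixed_wtp.base_value != wtp:
                errors.append(
                    f"analysis.wtp = {wtp} disagrees with the fixed 'wtp' "
                    f"parameter ({fixed_wtp.base_value})"
                )
        if "n_psa" in analysis:
            n_psa = int(analysis["n_psa"])
        else:
            logger.info("%s: analysis.n_psa not set, defaulting to 10000", source)
        seed = analysis.get("seed")
        dsa_fraction = float(analysis.get("dsa_fraction", 0.25))
        if analysis.get("wtp_grid") is not None:
            wtp_grid = np.asarray(analysis["wtp_grid"], dtype=float)

    tree = None
    if "tree" not in raw:
        errors.append("tree: missing")
    else:
        tree = _parse_tree(raw["tree"], "tree", errors)

    if errors:
        raise ConfigError(errors)
    assert tree is not None and wtp is not None

    model = DecisionModel(
        name=raw.get("name", "model"),
        parameters=specs,
        tree=tree,
        reference=reference,
        intervention=intervention,
        wtp=wtp,
        horizon=raw.get("horizon", ""),
        n_psa=n_psa,
        dsa_fraction=dsa_fraction,
        wtp_grid=wtp_grid,
        seed=seed,
    )
    # model-level validation (dangling parameter refs, branch sums at base)
    diagnostics = model.validate()
    if diagnostics:
        raise ConfigError(diagnostics)
    return model


def read_config(path: Union[str, Path]) -> DecisionModel:
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError([f"{path}: JSON parse failure: {exc}"]) from None
    return parse_config(raw, source=str(path))


# ---------------------------------------------------------------------------
# Serialization


def _serialize_tree(node: TreeNode) -> dict:
    if isinstance(node, DecisionNode):
        return {
            "kind": "decision",
            "strategies": {n: _serialize_tree(c) for n, c in node.strategies.items()},
        }
    if isinstance(node, ChanceNode):
        return {
            "kind": "chance",
            "branches": [
                {
                    "probability": br.probability,
                    **({"label": br.label} if br.label else {}),
                    "child": _serialize_tree(br.child),
                }
                for br in node.branches
            ],
        }
    return {"kind": "terminal", "cost": node.payoff.cost, "utility": node.payoff.utility}


def serialize_model(model: DecisionModel) -> dict:
    """Round-trippable configuration dict for a model."""
    params = []
    for spec in model.parameters.values():
        row: dict[str, Any] = {
            "name": spec.name,
            "base_value": spec.base_value,
            "family": spec.family,
            "sd": spec.sd,
            "kind": spec.kind,
        }
        if spec.dsa_low is not None:
            row["dsa_low"] = spec.dsa_low
        if spec.dsa_high is not None:
            row["dsa_high"] = spec.dsa_high
        params.append(row)
    out: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "name": model.name,
        "horizon": model.horizon,
        "strategies": {"reference": model.reference, "intervention": model.intervention},
        "parameters": params,
        "analysis": {
            "wtp": model.wtp,
            "n_psa": model.n_psa,
            "dsa_fraction": model.dsa_fraction,
        },
        "tree": _serialize_tree(model.tree),
    }
    if model.seed is not None:
        out["analysis"]["seed"] = model.seed
    if model.wtp_grid is not None:
        out["analysis"]["wtp_grid"] = list(map(float, model.wtp_grid))
    return out


def write_config(model: DecisionModel, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(serialize_model(model), indent=2) + "\n")


def config_hash(model: DecisionModel) -> str:
    """SHA-256 of the canonical serialized configuration."""
    canonical = json.dumps(serialize_model(model), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()
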