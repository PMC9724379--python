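"""Tiny safe arithmetic expressions over named parameters.

Branch probabilities and terminal payoffs may be given either as numeric
literals or as strings such as ``"p_repeat * (1 - reduction)"``.  Only the
four arithmetic operators, unary minus, parentheses, numbers and bare
parameter names are accepted; anything else is rejected at parse time.
Evaluation works transparently on scalars and on numpy arrays, which is what
lets the probabilistic sensitivity analysis evaluate all replications in one
vectorized pass.
"""

from __future__ import annotations

import ast
from functools import lru_cache
from typing import Mapping, Union

Quantity = Union[int, float, str]

_BINOPS = {
    ast.Add: lambda a, b: a + b,
    ast.Sub: lambda a, b: a - b,
    ast.Mult: lambda a, b: a * b,
    ast.Div: lambda a, b: a / b,
}
_UNARYOPS = {ast.USub: lambda a: -a, ast.UAdd: lambda a: +a}


class ExpressionError(ValueError):
    """Raised for syntactically invalid or disallowed expressions."""


class MissingParameterError(KeyError):
    """Raised when an expression references a name absent from the binding."""

    def __init__(self, name: str):
        super().__init__(name)
        self.name = name

    def __str__(self) -> str:  # KeyError quotes its arg; we want a message
        return f"no value bound for parameter {self.name!r}"


@lru_cache(maxsize=None)
def _parse(text: str) -> ast.expr:
    try:
        node = ast.parse(text, mode="eval").body
    except SyntaxError as exc:
        raise ExpressionError(f"invalid expression {text!r}: {exc.msg}") from None
    _check(node, text)
    return node


def _check(node: ast.expr, text: str) -> None:
    if isinstance(node, ast.BinOp) and type(node.op) in _BINOPS:
        _check(node.left, text)
        _check(node.right, text)
    elif isinstance(node, ast.UnaryOp) and type(node.op) in _UNARYOPS:
        _check(node.operand, text)
    elif isinstance(node, ast.Constant):
        if not isinstance(node.value, (int, float)):
            raise ExpressionError(
                f"non-numeric constant {node.value!r} in expression {text!r}"
            )
    elif isinstance(node, ast.Name):
        pass
    else:
        raise ExpressionError(
            f"disallowed construct {type(node).__name__} in expression {text!r}"
        )


def _eval(node: ast.expr, binding: Mapping[str, object]):
    if isinstance(node, ast.BinOp):
        return _BINOPS[type(node.op)](_eval(node.left, binding), _eval(node.right, binding))
    if isinstance(node, ast.UnaryOp):
        return _UNARYOPS[type(node.op)](_eval(node.operand, binding))
    if isinstance(node, ast.Constant):
        return node.value
    # ast.Name — _check guarantees nothing else reaches here
    try:
        return binding[node.id]
    except KeyError:
        raise MissingParameterError(node.id) from None


def resolve(quantity: Quantity, binding: Mapping[str, object]):
    """Resolve a literal or expression against a parameter binding.

    Scalars pass through unchanged; strings are parsed (cached) and
    evaluated.  Binding values may be floats or numpy arrays.
    """
    if isinstance(quantity, str):
        return _eval(_parse(quantity), binding)
    return quantity


def expression_names(quantity: Quantity) -> frozenset[str]:
    """Parameter names referenced by a quantity (empty for literals)."""
    if not isinstance(quantity, str):
        return frozenset()
    return frozenset(
        n.id for n in ast.walk(_parse(quantity)) if isinstance(n, ast.Name)
    )
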