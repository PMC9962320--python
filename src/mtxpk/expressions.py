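"""Tiny safe arithmetic-expression evaluator for covariate models.

Published population-PK models are shipped as declarative text formulas
(e.g. ``"6.9 * (weight/19)**0.75"``) so that the model catalog can be
serialized to YAML and users can add models without code changes.  Formulas
are parsed with :mod:`ast` and evaluated against a covariate environment;
only arithmetic, comparisons, conditionals and a small set of named
functions are permitted — no attribute access, no subscripts, no builtins.
"""

from __future__ import annotations

import ast
import math
from typing import Mapping

__all__ = ["ExpressionError", "evaluate", "variables"]


class ExpressionError(ValueError):
    """Raised when a covariate formula is malformed or uses a forbidden construct."""


def _where(cond, a, b):
    return a if cond else b


_FUNCTIONS = {
    "where": _where,
    "exp": math.exp,
    "log": math.log,
    "sqrt": math.sqrt,
    "min": min,
    "max": max,
}

_BINOPS = {
    ast.Add: lambda a, b: a + b,
    ast.Sub: lambda a, b: a - b,
    ast.Mult: lambda a, b: a * b,
    ast.Div: lambda a, b: a / b,
    ast.Pow: lambda a, b: a ** b,
}

_CMPOPS = {
    ast.Lt: lambda a, b: a < b,
    ast.LtE: lambda a, b: a <= b,
    ast.Gt: lambda a, b: a > b,
    ast.GtE: lambda a, b: a >= b,
    ast.Eq: lambda a, b: a == b,
    ast.NotEq: lambda a, b: a != b,
}


def _parse(expr: str) -> ast.expr:
    try:
        return ast.parse(expr, mode="eval").body
    except SyntaxError as exc:  # pragma: no cover - message formatting only
        raise ExpressionError(f"cannot parse formula {expr!r}: {exc}") from exc


def _eval(node: ast.expr, env: Mapping[str, float]) -> float:
    if isinstance(node, ast.Constant):
        if isinstance(node.value, (int, float)):
            return float(node.value)
        raise ExpressionError(f"non-numeric constant {node.value!r}")
    if isinstance(node, ast.Name):
        try:
            return env[node.id]
        except KeyError:
            raise ExpressionError(f"unknown variable {node.id!r}") from None
    if isinstance(node, ast.BinOp):
        op = _BINOPS.get(type(node.op))
        if op is None:
            raise ExpressionError(f"operator {type(node.op).__name__} not allowed")
        return op(_eval(node.left, env), _eval(node.right, env))
    if isinstance(node, ast.UnaryOp):
        val = _eval(node.operand, env)
        if isinstance(node.op, ast.USub):
            return -val
        if isinstance(node.op, ast.UAdd):
            return val
        raise ExpressionError(f"operator {type(node.op).__name__} not allowed")
    if isinstance(node, ast.Compare):
        if len(node.ops) != 1:
            raise ExpressionError("chained comparisons not allowed")
        op = _CMPOPS.get(type(node.ops[0]))
        if op is None:
            raise ExpressionError(f"comparison {type(node.ops[0]).__name__} not allowed")
        return float(op(_eval(node.left, env), _eval(node.comparators[0], env)))
    if isinstance(node, ast.IfExp):
        return _eval(node.body, env) if _eval(node.test, env) else _eval(node.orelse, env)
    if isinstance(node, ast.Call):
        if not isinstance(node.func, ast.Name) or node.func.id not in _FUNCTIONS:
            raise ExpressionError("only where/exp/log/sqrt/min/max calls allowed")
        if node.keywords:
            raise ExpressionError("keyword arguments not allowed")
        args = [_eval(a, env) for a in node.args]
        return float(_FUNCTIONS[node.func.id](*args))
    raise ExpressionError(f"construct {type(node).__name__} not allowed")


def evaluate(expr: str, env: Mapping[str, float]) -> float:
    """Evaluate a covariate formula against an environment of scalars."""
    return float(_eval(_parse(expr), env))


def variables(expr: str) -> set[str]:
    """Names referenced by a formula (excluding the permitted function names)."""
    names = set()
    for node in ast.walk(_parse(expr)):
        if isinstance(node, ast.Name) and node.id not in _FUNCTIONS:
            names.add(node.id)
    return names
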