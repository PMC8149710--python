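"""Safe arithmetic over table columns.

Derived columns are defined by small arithmetic expressions over existing
numeric columns (e.g. the ratio of two ChIP-seq signal columns).  The
grammar is deliberately tiny: identifiers, numeric literals, ``+ - * /``,
unary minus, parentheses, and the functions ``log2``, ``log10``, ``abs``
plus the pseudocounted helpers ``ratio(a, b, p) = (a+p)/(b+p)`` and
``l2fc(a, b, p) = log2((a+p)/(b+p))``.

Expressions are parsed with the stdlib ``ast`` module and evaluated
vectorised over numpy arrays.  Any row where evaluation produces a
non-finite value (division by zero, log of a non-positive number, or
propagation of a missing input) yields the missing marker (NaN).
"""

from __future__ import annotations

import ast
from typing import Mapping

import numpy as np

__all__ = ["ExpressionError", "parse_expression", "evaluate", "expression_names"]

_ALLOWED_FUNCTIONS = frozenset({"log2", "log10", "abs", "ratio", "l2fc"})

_FUNCTION_ARITY = {"log2": 1, "log10": 1, "abs": 1, "ratio": 3, "l2fc": 3}


class ExpressionError(ValueError):
    """Raised for syntax errors, unknown names, or disallowed constructs."""


def parse_expression(expr: str) -> ast.Expression:
    """Parse ``expr`` and validate it against the restricted grammar."""
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(f"syntax error in expression {expr!r}: {exc.msg}") from exc
    _validate(tree.body, expr)
    return tree


def expression_names(expr: str) -> set[str]:
    """Column names referenced by ``expr`` (functions excluded)."""
    tree = parse_expression(expr)
    names: set[str] = set()
    func_names: set[ast.Name] = set()
    for node in ast.walk(tree):
        if isinstance(node, ast.Call) and isinstance(node.func, ast.Name):
            func_names.add(node.func)
    for node in ast.walk(tree):
        if isinstance(node, ast.Name) and node not in func_names:
            names.add(node.id)
    return names


def _validate(node: ast.AST, expr: str) -> None:
    if isinstance(node, ast.BinOp):
        if not isinstance(node.op, (ast.Add, ast.Sub, ast.Mult, ast.Div)):
            raise ExpressionError(f"operator not allowed in {expr!r}")
        _validate(node.left, expr)
        _validate(node.right, expr)
    elif isinstance(node, ast.UnaryOp):
        if not isinstance(node.op, (ast.USub, ast.UAdd)):
            raise ExpressionError(f"unary operator not allowed in {expr!r}")
        _validate(node.operand, expr)
    elif isinstance(node, ast.Call):
        if not isinstance(node.func, ast.Name) or node.func.id not in _ALLOWED_FUNCTIONS:
            raise ExpressionError(f"unknown function in {expr!r}")
        if node.keywords:
            raise ExpressionError("keyword arguments are not supported")
        want = _FUNCTION_ARITY[node.func.id]
        if len(node.args) != want:
            raise ExpressionError(
                f"{node.func.id}() takes {want} argument(s), got {len(node.args)}"
            )
        for arg in node.args:
            _validate(arg, expr)
    elif isinstance(node, ast.Name):
        pass
    elif isinstance(node, ast.Constant):
        if not isinstance(node.value, (int, float)):
            raise ExpressionError(f"only numeric literals are allowed in {expr!r}")
    else:
        raise ExpressionError(f"construct {type(node).__name__} not allowed in {expr!r}")


def _eval(node: ast.AST, env: Mapping[str, np.ndarray]) -> np.ndarray:
    if isinstance(node, ast.BinOp):
        left = _eval(node.left, env)
        right = _eval(node.right, env)
        if isinstance(node.op, ast.Add):
            return left + right
        if isinstance(node.op, ast.Sub):
            return left - right
        if isinstance(node.op, ast.Mult):
            return left * right
        return left / right
    if isinstance(node, ast.UnaryOp):
        operand = _eval(node.operand, env)
        return -operand if isinstance(node.op, ast.USub) else +operand
    if isinstance(node, ast.Call):
        name = node.func.id  # type: ignore[union-attr]
        args = [_eval(a, env) for a in node.args]
        if name == "log2":
            return np.log2(args[0])
        if name == "log10":
            return np.log10(args[0])
        if name == "abs":
            return np.abs(args[0])
        if name == "ratio":
            return (args[0] + args[2]) / (args[1] + args[2])
        # l2fc
        return np.log2((args[0] + args[2]) / (args[1] + args[2]))
    if isinstance(node, ast.Name):
        return env[node.id]
    # Constant (validated numeric)
    return np.asarray(float(node.value))  # type: ignore[union-attr]


def evaluate(expr: str, env: Mapping[str, np.ndarray]) -> np.ndarray:
    """Evaluate ``expr`` over aligned float arrays.

    Unknown identifiers raise :class:`ExpressionError` before any
    computation.  Rows producing non-finite results come back as NaN.
    """
    tree = parse_expression(expr)
    missing = expression_names(expr) - set(env)
    if missing:
        raise ExpressionError(f"unknown column(s): {', '.join(sorted(missing))}")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.asarray(_eval(tree.body, env), dtype=float)
    if out.ndim == 0:  # constant expression: broadcast to table length
        n = len(next(iter(env.values()))) if env else 1
        out = np.full(n, float(out))
    out = out.copy()
    out[~np.isfinite(out)] = np.nan
    return out
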