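"""Sandboxed integer expression mini-language for task variables and conditions.

Grammar (a strict subset of Python expression syntax, interpreted over ints):

* integer literals, declared variable names
* arithmetic: ``+ - * / // %`` (``/`` and ``//`` both mean integer division,
  truncating toward zero, as on the microcontroller targets this emulates)
* comparisons (``== != < <= > >=``, chaining allowed) yielding 0/1
* boolean ``and``/``or``/``not`` (short-circuit, yielding 0/1)
* unary ``-``/``+``
* random primitives: ``rand_int(lo, hi)`` (uniform inclusive) and
  ``rand_bernoulli_pct(p)`` (1 with probability p/100, p an integer percent)

No attribute access, subscripts, floats, strings, loops or calls beyond the two
primitives: expressions are total (modulo division by zero) and deterministic
given the run's random generator.
"""

from __future__ import annotations

import ast
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np

RANDOM_PRIMITIVES = ("rand_int", "rand_bernoulli_pct")


class ExpressionError(ValueError):
    """Raised when an expression is malformed, unsafe, or fails to evaluate."""


def _trunc_div(a: int, b: int) -> int:
    if b == 0:
        raise ExpressionError("division by zero")
    q = abs(a) // abs(b)
    return q if (a >= 0) == (b >= 0) else -q


def _mod(a: int, b: int) -> int:
    # C-style: remainder has the sign of the dividend
    if b == 0:
        raise ExpressionError("modulo by zero")
    return a - _trunc_div(a, b) * b


_BINOPS = {
    ast.Add: lambda a, b: a + b,
    ast.Sub: lambda a, b: a - b,
    ast.Mult: lambda a, b: a * b,
    ast.Div: _trunc_div,
    ast.FloorDiv: _trunc_div,
    ast.Mod: _mod,
}

_CMPOPS = {
    ast.Eq: lambda a, b: a == b,
    ast.NotEq: lambda a, b: a != b,
    ast.Lt: lambda a, b: a < b,
    ast.LtE: lambda a, b: a <= b,
    ast.Gt: lambda a, b: a > b,
    ast.GtE: lambda a, b: a >= b,
}


@lru_cache(maxsize=4096)
def parse(expression: str) -> ast.expr:
    """Parse and whitelist-check an expression; cached per source string."""
    try:
        tree = ast.parse(expression, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(f"syntax error in {expression!r}: {exc.msg}") from None
    _check(tree.body, expression)
    return tree.body


def _check(node: ast.expr, src: str) -> None:
    if isinstance(node, ast.Constant):
        if not isinstance(node.value, int) or isinstance(node.value, bool):
            raise ExpressionError(f"only integer literals allowed in {src!r}")
    elif isinstance(node, ast.Name):
        pass
    elif isinstance(node, ast.BinOp):
        if type(node.op) not in _BINOPS:
            raise ExpressionError(f"operator not allowed in {src!r}")
        _check(node.left, src)
        _check(node.right, src)
    elif isinstance(node, ast.UnaryOp):
        if not isinstance(node.op, (ast.USub, ast.UAdd, ast.Not)):
            raise ExpressionError(f"operator not allowed in {src!r}")
        _check(node.operand, src)
    elif isinstance(node, ast.BoolOp):
        for v in node.values:
            _check(v, src)
    elif isinstance(node, ast.Compare):
        if any(type(op) not in _CMPOPS for op in node.ops):
            raise ExpressionError(f"comparison not allowed in {src!r}")
        _check(node.left, src)
        for c in node.comparators:
            _check(c, src)
    elif isinstance(node, ast.Call):
        if not isinstance(node.func, ast.Name) or node.func.id not in RANDOM_PRIMITIVES:
            raise ExpressionError(f"only {RANDOM_PRIMITIVES} calls allowed in {src!r}")
        if node.keywords:
            raise ExpressionError(f"keyword arguments not allowed in {src!r}")
        n_expected = 2 if node.func.id == "rand_int" else 1
        if len(node.args) != n_expected:
            raise ExpressionError(
                f"{node.func.id} takes {n_expected} argument(s) in {src!r}"
            )
        for a in node.args:
            _check(a, src)
    else:
        raise ExpressionError(f"construct {type(node).__name__} not allowed in {src!r}")


def variables(expression: str) -> set[str]:
    """Names of all variables referenced by *expression*."""
    node = parse(expression)
    names: set[str] = set()
    for sub in ast.walk(node):
        if isinstance(sub, ast.Name):
            names.add(sub.id)
        elif isinstance(sub, ast.Call):
            names.discard(sub.func.id)  # type: ignore[union-attr]
    names -= set(RANDOM_PRIMITIVES)
    return names


def uses_random(expression: str) -> bool:
    """True if *expression* calls any random primitive."""
    return any(isinstance(n, ast.Call) for n in ast.walk(parse(expression)))


def evaluate(
    expression: str, env: Mapping[str, int], rng: np.random.Generator
) -> int:
    """Evaluate *expression* over integer variables *env*, drawing from *rng*."""
    return _eval(parse(expression), env, rng, expression)


def _eval(node: ast.expr, env, rng, src: str) -> int:
    if isinstance(node, ast.Constant):
        return int(node.value)
    if isinstance(node, ast.Name):
        try:
            return int(env[node.id])
        except KeyError:
            raise ExpressionError(f"undeclared variable {node.id!r} in {src!r}") from None
    if isinstance(node, ast.BinOp):
        return _BINOPS[type(node.op)](
            _eval(node.left, env, rng, src), _eval(node.right, env, rng, src)
        )
    if isinstance(node, ast.UnaryOp):
        v = _eval(node.operand, env, rng, src)
        if isinstance(node.op, ast.USub):
            return -v
        if isinstance(node.op, ast.UAdd):
            return v
        return int(v == 0)  # not
    if isinstance(node, ast.BoolOp):
        if isinstance(node.op, ast.And):
            for sub in node.values:
                if _eval(sub, env, rng, src) == 0:
                    return 0
            return 1
        for sub in node.values:  # Or
            if _eval(sub, env, rng, src) != 0:
                return 1
        return 0
    if isinstance(node, ast.Compare):
        left = _eval(node.left, env, rng, src)
        for op, comp in zip(node.ops, node.comparators):
            right = _eval(comp, env, rng, src)
            if not _CMPOPS[type(op)](left, right):
                return 0
            left = right
        return 1
    if isinstance(node, ast.Call):
        args = [_eval(a, env, rng, src) for a in node.args]
        name = node.func.id  # type: ignore[union-attr]
        if name == "rand_int":
            lo, hi = args
            if hi < lo:
                raise ExpressionError(f"rand_int({lo},{hi}): empty range in {src!r}")
            return int(rng.integers(lo, hi + 1))
        p = args[0]
        if not 0 <= p <= 100:
            raise ExpressionError(f"rand_bernoulli_pct({p}): percent outside [0,100]")
        return int(int(rng.integers(0, 100)) < p)
    raise AssertionError("unreachable: whitelist enforced at parse time")


def evaluate_scalar(
    value: int | str, env: Mapping[str, int], rng: np.random.Generator
) -> int:
    """Resolve an int-or-variable-reference parameter (durations, thresholds)."""
    if isinstance(value, str):
        return evaluate(value, env, rng)
    return int(value)


def referenced_names(value: int | str | None) -> Iterable[str]:
    if isinstance(value, str):
        return variables(value)
    return ()
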