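"""Server-side execution of the tidy data-manipulation verbs.

Fifteen verbs run against workspace frames: select, rename, mutate,
if_else, case_when, bind_cols, bind_rows, filter, slice, arrange,
group_by, ungroup, group_keys, distinct and tibble conversion.  Each
takes an already-parsed (and, at the federation layer, already
allowlist-validated) expression tree; this module never sees raw client
text.

Evaluation is vectorized and column-oriented: identifiers resolve to
columns of the context frame, scalars recycle to frame length, and
missingness propagates through arithmetic, comparisons and boolean
logic.  On a grouped frame the reduction helpers (mean, median, sd,
var, mode, nth) evaluate per group and broadcast within it.
"""

from __future__ import annotations

import math
import re as _re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .expr import (Binary, BoolLit, Call, ExprList, ExprNode, Formula,
                   Identifier, MissingLit, NamedArg, NumberLit, StringLit,
                   Unary)
from .frame import (ColumnVector, FrameError, GroupedFrame, ShapeError,
                    TabularFrame, TypeMismatchError, UnknownColumnError)

__all__ = [
    "EvalError", "ArgumentError", "EvalContext", "CaseClause",
    "eval_expr", "resolve_selector", "apply_select", "apply_rename",
    "apply_mutate", "eval_if_else", "eval_case_when", "apply_filter",
    "apply_slice", "apply_arrange", "apply_bind_rows", "apply_bind_cols",
    "apply_group_by", "apply_ungroup", "compute_group_keys",
    "apply_distinct", "to_canonical_frame",
]


class EvalError(FrameError):
    pass


class ArgumentError(FrameError):
    pass


@dataclass
class EvalContext:
    """Resolution context: one frame, optional grouping for reductions."""

    frame: TabularFrame
    group_ids: Optional[np.ndarray] = None
    n_groups: int = 0

    @classmethod
    def for_frame(cls, f: TabularFrame | GroupedFrame) -> "EvalContext":
        if isinstance(f, GroupedFrame):
            ids, k = f.group_index()
            return cls(f.base, ids, k)
        return cls(f)

    def column(self, name: str) -> ColumnVector:
        return self.frame.column(name)


@dataclass(frozen=True)
class CaseClause:
    condition: ExprNode
    value: ExprNode


# ---------------------------------------------------------------------------
# numeric plumbing
# ---------------------------------------------------------------------------

def _as_numeric(col: ColumnVector, what: str = "operand") -> np.ndarray:
    if col.dtype in ("numeric", "integer"):
        return col.values.astype(np.float64)
    if col.dtype == "boolean":
        return col.values.astype(np.float64)
    raise TypeMismatchError(f"{what} of dtype {col.dtype} is not numeric")


def _recycle(col: ColumnVector, n: int) -> ColumnVector:
    if len(col) == n:
        return col
    if len(col) == 1:
        idx = np.zeros(n, dtype=np.int64)
        return col.take(idx)
    raise ShapeError(f"result length {len(col)} is neither 1 nor {n}")


def _num_result(values: np.ndarray, missing: np.ndarray, integral: bool = False) -> ColumnVector:
    if integral:
        safe = np.where(missing, 0, values).astype(np.int64)
        return ColumnVector.from_arrays(safe, missing, "integer")
    safe = np.where(missing, np.nan, values.astype(np.float64))
    return ColumnVector.from_arrays(safe, missing, "numeric")


_ARITH = {"+", "-", "*", "/", "^"}
_COMPARE = {"<", "<=", ">", ">=", "==", "!="}
_LOGIC = {"&", "|"}


def _binary(op: str, a: ColumnVector, b: ColumnVector) -> ColumnVector:
    # recycle length-1 operands to the other side (which may be empty)
    if len(a) == len(b):
        n = len(a)
    elif len(a) == 1:
        n = len(b)
    elif len(b) == 1:
        n = len(a)
    else:
        raise ShapeError(f"operand lengths {len(a)} and {len(b)} do not align")
    a, b = _recycle(a, n), _recycle(b, n)
    miss = a.missing | b.missing
    if op in _ARITH:
        x, y = _as_numeric(a), _as_numeric(b)
        with np.errstate(all="ignore"):
            if op == "+":
                out = x + y
            elif op == "-":
                out = x - y
            elif op == "*":
                out = x * y
            elif op == "/":
                out = x / y
            else:
                out = x ** y
        integral = (a.dtype == b.dtype == "integer" and op in ("+", "-", "*"))
        miss = miss | ~np.isfinite(np.where(miss, 0.0, out))
        return _num_result(out, miss, integral)
    if op in _COMPARE:
        if a.dtype in ("string", "categorical") or b.dtype in ("string", "categorical"):
            if not (a.dtype in ("string", "categorical") and b.dtype in ("string", "categorical")):
                raise TypeMismatchError(f"cannot compare {a.dtype} with {b.dtype}")
            x, y = a.values.astype(str), b.values.astype(str)
        else:
            x, y = _as_numeric(a), _as_numeric(b)
        cmp = {"<": np.less, "<=": np.less_equal, ">": np.greater,
               ">=": np.greater_equal, "==": np.equal, "!=": np.not_equal}[op]
        with np.errstate(invalid="ignore"):
            out = cmp(x, y)
        safe = np.where(miss, False, out)
        return ColumnVector.from_arrays(safe.astype(bool), miss, "boolean")
    if op in _LOGIC:
        if a.dtype != "boolean" or b.dtype != "boolean":
            raise TypeMismatchError(f"logical {op} needs boolean operands, "
                                    f"got {a.dtype} and {b.dtype}")
        out = (a.values & b.values) if op == "&" else (a.values | b.values)
        return ColumnVector.from_arrays(out, miss, "boolean")
    if op == ":":
        raise EvalError("name ranges (:) are only valid in column selections")
    raise EvalError(f"operator {op!r} not supported in evaluation")


# per-group reduction, broadcast back to row length
def _grouped_reduce(ctx: EvalContext, col: ColumnVector, fn) -> ColumnVector:
    n = ctx.frame.n_rows
    values = np.empty(n, dtype=np.float64)
    missing = np.zeros(n, dtype=bool)
    x = _as_numeric(col)
    for g in range(ctx.n_groups):
        sel = ctx.group_ids == g
        if col.missing[sel].any():
            missing[sel] = True
            values[sel] = np.nan
        else:
            values[sel] = fn(x[sel])
    return _num_result(values, missing)


def _reduce(ctx: EvalContext, col: ColumnVector, fn) -> ColumnVector:
    if ctx.group_ids is not None:
        return _grouped_reduce(ctx, col, fn)
    if col.missing.any():
        return ColumnVector([None], "numeric")
    return ColumnVector([float(fn(_as_numeric(col)))], "numeric")


def _stat_mode(x: np.ndarray) -> float:
    vals, counts = np.unique(x, return_counts=True)
    return float(vals[np.argmax(counts)])


_REDUCTIONS = {
    "mean": np.mean,
    "median": np.median,
    "sd": lambda x: np.std(x, ddof=1),
    "var": lambda x: np.var(x, ddof=1),
    "mode": _stat_mode,
}

_ELEMENTWISE = {
    "exp": np.exp, "sqrt": np.sqrt, "floor": np.floor, "ceiling": np.ceil,
    "abs": np.abs, "sin": np.sin, "cos": np.cos, "tan": np.tan,
    "asin": np.arcsin, "acos": np.arccos, "atan": np.arctan,
}

_SELECTOR_FNS = {"everything", "last_col", "group_cols", "starts_with",
                 "ends_with", "contains", "matches", "num_range",
                 "all_of", "any_of", "where"}


def _positional_args(call: Call) -> list[ExprNode]:
    return [a.value if isinstance(a, NamedArg) else a for a in call.args]


def _eval_call(ctx: EvalContext, call: Call) -> ColumnVector:
    name = call.fn_name
    args = _positional_args(call)
    if name in _ELEMENTWISE:
        if len(args) != 1:
            raise ArgumentError(f"{name}() takes exactly one argument")
        col = eval_expr(ctx, args[0])
        x = _as_numeric(col, name)
        with np.errstate(all="ignore"):
            out = _ELEMENTWISE[name](x)
        miss = col.missing | np.isnan(np.where(col.missing, 0.0, out))
        return _num_result(out, miss)
    if name == "round":
        if not 1 <= len(args) <= 2:
            raise ArgumentError("round() takes one or two arguments")
        col = eval_expr(ctx, args[0])
        digits = 0
        if len(args) == 2:
            d = eval_expr(ctx, args[1])
            digits = int(_as_numeric(d)[0])
        x = _as_numeric(col, "round")
        # round half to even, matching the usual numerical convention
        out = np.round(x, digits)
        return _num_result(out, col.missing)
    if name == "scale":
        if len(args) != 1:
            raise ArgumentError("scale() takes exactly one argument")
        col = eval_expr(ctx, args[0])
        x = _as_numeric(col, "scale")
        ok = ~col.missing
        mu = x[ok].mean() if ok.any() else np.nan
        sigma = x[ok].std(ddof=1) if ok.sum() > 1 else np.nan
        with np.errstate(all="ignore"):
            out = (x - mu) / sigma
        miss = col.missing | ~np.isfinite(np.where(col.missing, 0.0, out))
        return _num_result(out, miss)
    if name in _REDUCTIONS:
        if len(args) != 1:
            raise ArgumentError(f"{name}() takes exactly one argument")
        col = eval_expr(ctx, args[0])
        return _reduce(ctx, col, _REDUCTIONS[name])
    if name == "nth":
        if len(args) != 2:
            raise ArgumentError("nth() takes a vector and a 1-based position")
        col = eval_expr(ctx, args[0])
        k = int(_as_numeric(eval_expr(ctx, args[1]))[0])
        if not 1 <= k <= len(col):
            return ColumnVector([None], col.dtype)
        return col.take(np.array([k - 1]))
    if name == "c":
        parts = [eval_expr(ctx, a) for a in args]
        if not parts:
            raise ArgumentError("c() needs at least one element")
        dtype = _common_dtype([p.dtype for p in parts])
        vals: list = []
        for p in parts:
            vals.extend(_cast_list(p, dtype))
        return ColumnVector(vals, dtype)
    if name == "if_else":
        if len(args) != 3:
            raise ArgumentError("if_else() takes condition, yes, no")
        cond = eval_expr(ctx, args[0])
        yes = eval_expr(ctx, args[1])
        no = eval_expr(ctx, args[2])
        return eval_if_else(cond, yes, no)
    if name == "case_when":
        clauses = [_as_clause(a) for a in args]
        return eval_case_when(ctx, clauses)
    if name == "desc":
        raise EvalError("desc() is only valid inside arrange()")
    if name in _SELECTOR_FNS:
        raise EvalError(f"{name}() is only valid in column selections")
    raise EvalError(f"function {name!r} is not available for evaluation")


def eval_expr(ctx: EvalContext, node: ExprNode) -> ColumnVector:
    """Evaluate an expression to a column (scalars come back length 1)."""
    if isinstance(node, Identifier):
        return ctx.column(node.name)
    if isinstance(node, NumberLit):
        if isinstance(node.value, int):
            return ColumnVector([node.value], "integer")
        return ColumnVector([node.value], "numeric")
    if isinstance(node, StringLit):
        return ColumnVector([node.value], "string")
    if isinstance(node, BoolLit):
        return ColumnVector([node.value], "boolean")
    if isinstance(node, MissingLit):
        return ColumnVector([None], "numeric")
    if isinstance(node, Binary):
        return _binary(node.op, eval_expr(ctx, node.lhs), eval_expr(ctx, node.rhs))
    if isinstance(node, Unary):
        col = eval_expr(ctx, node.operand)
        if node.op == "-":
            x = _as_numeric(col, "negation")
            integral = col.dtype == "integer"
            return _num_result(-x, col.missing, integral)
        if col.dtype != "boolean":
            raise TypeMismatchError(f"! needs a boolean operand, got {col.dtype}")
        return ColumnVector.from_arrays(~col.values, col.missing, "boolean")
    if isinstance(node, Call):
        return _eval_call(ctx, node)
    if isinstance(node, Formula):
        raise EvalError("a ~ clause is only valid inside case_when() or rename()")
    raise EvalError(f"cannot evaluate node of kind {type(node).__name__}")


# ---------------------------------------------------------------------------
# dtype unification used by c(), if_else, case_when, bind_rows
# ---------------------------------------------------------------------------

_NUM_CHAIN = ("boolean", "integer", "numeric")


def _common_dtype(dtypes: Sequence[str]) -> str:
    kinds = set(dtypes)
    if kinds <= set(_NUM_CHAIN):
        return _NUM_CHAIN[max(_NUM_CHAIN.index(d) for d in kinds)]
    if kinds <= {"string", "categorical"}:
        return "string" if kinds == {"string", "categorical"} else kinds.pop()
    raise TypeMismatchError(f"no common dtype for {sorted(kinds)}")


def _cast_list(col: ColumnVector, dtype: str) -> list:
    out = []
    for v in col.to_list():
        if v is None:
            out.append(None)
        elif dtype == "numeric":
            out.append(float(v))
        elif dtype == "integer":
            out.append(int(v))
        else:
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# selectors
# ---------------------------------------------------------------------------

def _literal_string(node: ExprNode) -> str:
    if isinstance(node, StringLit):
        return node.value
    if isinstance(node, Identifier):
        return node.name
    raise ArgumentError(f"expected a column name, got {type(node).__name__}")


def _name_args(args: Sequence[ExprNode]) -> list[str]:
    names: list[str] = []
    for a in args:
        if isinstance(a, Call) and a.fn_name == "c":
            names.extend(_name_args(a.args))
        else:
            names.append(_literal_string(a))
    return names


def resolve_selector(f: TabularFrame, sel: ExprNode,
                     group_cols: Sequence[str] = ()) -> list[str]:
    """Resolve one selector expression to an ordered column-name list.

    Supports bare names, string names, 1-based positions, ``a:b`` name
    ranges and the tidy selection helpers.  ``all_of`` errors on a
    missing name; ``any_of`` skips it silently.  Duplicates keep the
    first occurrence.
    """
    order = f.column_order

    def present(name: str) -> str:
        if name not in f.columns:
            raise UnknownColumnError(f"unknown column {name!r}")
        return name

    if isinstance(sel, ExprList):
        out: list[str] = []
        for item in sel.items:
            for n in resolve_selector(f, item, group_cols):
                if n not in out:
                    out.append(n)
        return out
    if isinstance(sel, Identifier):
        return [present(sel.name)]
    if isinstance(sel, StringLit):
        return [present(sel.value)]
    if isinstance(sel, NumberLit):
        k = int(sel.value)
        if not 1 <= k <= len(order):
            raise UnknownColumnError(f"column position {k} out of range")
        return [order[k - 1]]
    if isinstance(sel, Binary) and sel.op == ":":
        a = resolve_selector(f, sel.lhs, group_cols)[0]
        b = resolve_selector(f, sel.rhs, group_cols)[0]
        i, j = order.index(a), order.index(b)
        return order[i:j + 1] if i <= j else order[j:i + 1][::-1]
    if isinstance(sel, Call):
        name, args = sel.fn_name, _positional_args(sel)
        if name == "everything":
            return list(order)
        if name == "last_col":
            offset = int(args[0].value) if args else 0
            if not 0 <= offset < len(order):
                raise UnknownColumnError(f"last_col offset {offset} out of range")
            return [order[-1 - offset]]
        if name == "group_cols":
            return [c for c in group_cols if c in f.columns]
        if name in ("starts_with", "ends_with", "contains", "matches"):
            pat = _literal_string(args[0])
            if name == "starts_with":
                keep = [c for c in order if c.startswith(pat)]
            elif name == "ends_with":
                keep = [c for c in order if c.endswith(pat)]
            elif name == "contains":
                keep = [c for c in order if pat in c]
            else:
                rx = _re.compile(pat)
                keep = [c for c in order if rx.search(c)]
            return keep
        if name == "num_range":
            prefix = _literal_string(args[0])
            rng = args[1]
            if isinstance(rng, Binary) and rng.op == ":":
                lo, hi = int(rng.lhs.value), int(rng.rhs.value)
                numbers = range(lo, hi + 1)
            elif isinstance(rng, Call) and rng.fn_name == "c":
                numbers = [int(a.value) for a in _positional_args(rng)]
            else:
                numbers = [int(rng.value)]
            return [f"{prefix}{i}" for i in numbers if f"{prefix}{i}" in f.columns]
        if name == "all_of":
            return [present(n) for n in _name_args(args)]
        if name == "any_of":
            return [n for n in _name_args(args) if n in f.columns]
        if name == "where":
            pred = args[0]
            if isinstance(pred, Identifier) and pred.name in ("is.numeric", "is.character", "is.logical"):
                wanted = {"is.numeric": ("numeric", "integer"),
                          "is.character": ("string", "categorical"),
                          "is.logical": ("boolean",)}[pred.name]
                return [c for c in order if f.columns[c].dtype in wanted]
            raise ArgumentError("where() supports only is.numeric, is.character, is.logical")
        raise ArgumentError(f"{name!r} is not a selection helper")
    raise ArgumentError(f"cannot use {type(sel).__name__} as a column selector")


def apply_select(f: TabularFrame, sels: Sequence[ExprNode] | ExprNode) -> TabularFrame:
    """Keep the named columns, in selection order; row count is preserved."""
    items = sels.items if isinstance(sels, ExprList) else (
        sels if isinstance(sels, (list, tuple)) else [sels])
    names: list[str] = []
    for sel in items:
        for n in resolve_selector(f, sel):
            if n not in names:
                names.append(n)
    return TabularFrame([(n, f.columns[n]) for n in names])


def _as_items(node) -> list:
    if isinstance(node, ExprList):
        return list(node.items)
    if isinstance(node, (list, tuple)):
        return list(node)
    return [node]


def apply_rename(f: TabularFrame, pairs: Sequence[ExprNode] | ExprList) -> TabularFrame:
    """Rename columns (``new = old`` pairs); values and order unchanged."""
    items = _as_items(pairs)
    mapping: dict[str, str] = {}  # old -> new
    for p in items:
        if isinstance(p, NamedArg):
            new, old = p.name, _literal_string(p.value)
        elif isinstance(p, Formula):
            new, old = _literal_string(p.lhs), _literal_string(p.rhs)
        else:
            raise ArgumentError("rename expects new = old pairs")
        if old not in f.columns:
            raise UnknownColumnError(f"unknown column {old!r}")
        mapping[old] = new
    new_order = [mapping.get(n, n) for n in f.column_order]
    if len(set(new_order)) != len(new_order):
        raise FrameError("rename would create duplicate column names")
    return TabularFrame([(mapping.get(n, n), f.columns[n]) for n in f.column_order])


def apply_mutate(f: TabularFrame | GroupedFrame,
                 assigns: Sequence[NamedArg] | ExprList) -> TabularFrame | GroupedFrame:
    """Add or overwrite columns; assignments see earlier results.

    On a grouped frame the reductions evaluate per group and broadcast.
    """
    items = _as_items(assigns)
    grouped = isinstance(f, GroupedFrame)
    work = f.base if grouped else f
    group_cols = f.group_cols if grouped else ()
    for a in items:
        if not isinstance(a, NamedArg):
            raise ArgumentError("mutate expects name = expression assignments")
        ctx = EvalContext.for_frame(GroupedFrame(work, group_cols) if grouped else work)
        col = eval_expr(ctx, a.value)
        col = _recycle(col, work.n_rows) if work.n_rows else col
        work = work.with_columns([(a.name, col)])
    return GroupedFrame(work, group_cols) if grouped else work


def eval_if_else(cond: ColumnVector, yes, no) -> ColumnVector:
    """Vectorized two-way choice; a missing condition yields missing."""
    if cond.dtype != "boolean":
        raise TypeMismatchError("if_else condition must be boolean")
    n = len(cond)
    yes = _recycle(yes, n) if isinstance(yes, ColumnVector) else ColumnVector([yes] * n, _scalar_dtype(yes))
    no = _recycle(no, n) if isinstance(no, ColumnVector) else ColumnVector([no] * n, _scalar_dtype(no))
    dtype = _common_dtype([yes.dtype, no.dtype])
    yv, nv = _cast_list(yes, dtype), _cast_list(no, dtype)
    out = []
    for i in range(n):
        if cond.missing[i]:
            out.append(None)
        else:
            out.append(yv[i] if cond.values[i] else nv[i])
    return ColumnVector(out, dtype)


def _scalar_dtype(v) -> str:
    if isinstance(v, bool):
        return "boolean"
    if isinstance(v, int):
        return "integer"
    if isinstance(v, float):
        return "numeric"
    return "string"


def _as_clause(node: ExprNode) -> CaseClause:
    if isinstance(node, CaseClause):
        return node
    if isinstance(node, Formula):
        return CaseClause(node.lhs, node.rhs)
    raise ArgumentError("case_when clauses must be condition ~ value formulas")


def eval_case_when(ctx: EvalContext, clauses: Sequence) -> ColumnVector:
    """First matching clause wins per row; unmatched rows are missing."""
    clauses = [_as_clause(c) for c in clauses]
    if not clauses:
        raise ArgumentError("case_when needs at least one clause")
    n = ctx.frame.n_rows
    conds, values = [], []
    for cl in clauses:
        cond = _recycle(eval_expr(ctx, cl.condition), n)
        if cond.dtype != "boolean":
            raise TypeMismatchError("case_when condition must be boolean")
        conds.append(cond)
        values.append(_recycle(eval_expr(ctx, cl.value), n))
    dtype = _common_dtype([v.dtype for v in values])
    casted = [_cast_list(v, dtype) for v in values]
    out: list = []
    for i in range(n):
        chosen = None
        for cond, vals in zip(conds, casted):
            if not cond.missing[i] and cond.values[i]:
                chosen = vals[i]
                break
        out.append(chosen)
    return ColumnVector(out, dtype)


# ---------------------------------------------------------------------------
# row verbs
# ---------------------------------------------------------------------------

def _regrouped(f, base: TabularFrame):
    if isinstance(f, GroupedFrame):
        return GroupedFrame(base, f.group_cols)
    return base


def apply_filter(f: TabularFrame | GroupedFrame, predicate: ExprNode):
    """Keep rows where the predicate is true; missing predicate drops the row."""
    if isinstance(predicate, ExprList):
        if len(predicate.items) != 1:
            raise ArgumentError("filter expects a single predicate expression")
        predicate = predicate.items[0]
    base = f.base if isinstance(f, GroupedFrame) else f
    ctx = EvalContext.for_frame(base)
    cond = _recycle(eval_expr(ctx, predicate), base.n_rows)
    if cond.dtype != "boolean":
        raise TypeMismatchError("filter predicate must evaluate to boolean")
    keep = np.flatnonzero(cond.values & ~cond.missing)
    return _regrouped(f, base.take_rows(keep))


def apply_slice(f: TabularFrame | GroupedFrame, positions: Sequence[int]):
    """Select rows by 1-based position; out-of-range positions are dropped.

    All-negative positions exclude instead; mixing signs is an error.
    """
    base = f.base if isinstance(f, GroupedFrame) else f
    pos = [int(p) for p in positions]
    if any(p > 0 for p in pos) and any(p < 0 for p in pos):
        raise ArgumentError("slice cannot mix positive and negative positions")
    n = base.n_rows
    if pos and all(p < 0 for p in pos):
        drop = {-p - 1 for p in pos if 1 <= -p <= n}
        idx = np.array([i for i in range(n) if i not in drop], dtype=np.int64)
    else:
        idx = np.array([p - 1 for p in pos if 1 <= p <= n], dtype=np.int64)
    return _regrouped(f, base.take_rows(idx))


def _sort_key_array(col: ColumnVector, descending: bool) -> np.ndarray:
    """Float key: ascending order of the key = requested order; missing last."""
    if col.dtype in ("numeric", "integer", "boolean"):
        x = col.values.astype(np.float64)
    else:
        # bytewise (codepoint) ordering, locale-independent
        uniq = sorted(set(col.values[~col.missing].astype(str)))
        code = {v: i for i, v in enumerate(uniq)}
        x = np.array([code.get(str(v), 0) for v in col.values], dtype=np.float64)
    if descending:
        x = -x
    return np.where(col.missing, np.inf, x)


def apply_arrange(f: TabularFrame | GroupedFrame, keys: Sequence[ExprNode] | ExprList):
    """Stable multi-key sort; ``desc()`` reverses one key; missing values last."""
    items = _as_items(keys)
    if not items:
        raise ArgumentError("arrange needs at least one key")
    base = f.base if isinstance(f, GroupedFrame) else f
    ctx = EvalContext(base)  # grouping deliberately ignored for ordering
    arrays = []
    for k in items:
        descending = False
        if isinstance(k, Call) and k.fn_name == "desc":
            if len(k.args) != 1:
                raise ArgumentError("desc() takes exactly one key")
            k = k.args[0]
            descending = True
        col = _recycle(eval_expr(ctx, k), base.n_rows)
        arrays.append(_sort_key_array(col, descending))
    # lexsort: last key is primary, so feed keys reversed; stable for ties
    order = np.lexsort(arrays[::-1])
    return _regrouped(f, base.take_rows(order))


# ---------------------------------------------------------------------------
# combining
# ---------------------------------------------------------------------------

def apply_bind_rows(frames: Sequence[TabularFrame]) -> TabularFrame:
    """Stack frames; column set is the union in first-seen order, absent
    cells become missing, {boolean,integer,numeric} unify upward."""
    if not frames:
        raise ArgumentError("bind_rows needs at least one frame")
    order: list[str] = []
    dtypes: dict[str, str] = {}
    for fr in frames:
        for n in fr.column_order:
            d = fr.columns[n].dtype
            if n not in dtypes:
                order.append(n)
                dtypes[n] = d
            else:
                dtypes[n] = _common_dtype([dtypes[n], d])
    cols = []
    for n in order:
        cells: list = []
        for fr in frames:
            if n in fr.columns:
                cells.extend(_cast_list(fr.columns[n], dtypes[n]))
            else:
                cells.extend([None] * fr.n_rows)
        cols.append((n, ColumnVector(cells, dtypes[n])))
    return TabularFrame(cols)


def apply_bind_cols(frames: Sequence[TabularFrame]) -> TabularFrame:
    """Concatenate columns; duplicate names get positional __k suffixes."""
    if not frames:
        raise ArgumentError("bind_cols needs at least one frame")
    n = frames[0].n_rows
    for fr in frames[1:]:
        if fr.n_rows != n:
            raise ShapeError(f"bind_cols row counts differ: {n} vs {fr.n_rows}")
    counts: dict[str, int] = {}
    cols = []
    for fr in frames:
        for name in fr.column_order:
            counts[name] = counts.get(name, 0) + 1
            out = name if counts[name] == 1 else f"{name}__{counts[name]}"
            cols.append((out, fr.columns[name]))
    return TabularFrame(cols)


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def apply_group_by(f: TabularFrame | GroupedFrame, cols: Sequence[str]) -> GroupedFrame:
    base = f.base if isinstance(f, GroupedFrame) else f
    return GroupedFrame(base, tuple(cols))


def apply_ungroup(g: GroupedFrame | TabularFrame) -> TabularFrame:
    return g.base if isinstance(g, GroupedFrame) else g


def compute_group_keys(g: GroupedFrame) -> TabularFrame:
    """One row per distinct key tuple, sorted ascending by the key columns.

    This is the package's sole aggregate-type result; disclosure
    screening happens in the federation layer before release.
    """
    base = g.base
    seen = set()
    idx = []
    lists = {c: base.columns[c].to_list() for c in g.group_cols}
    for i in range(base.n_rows):
        key = tuple(lists[c][i] for c in g.group_cols)
        if key not in seen:
            seen.add(key)
            idx.append(i)
    keys = TabularFrame([(c, base.columns[c].take(np.array(idx, dtype=np.int64)))
                         for c in g.group_cols])
    return apply_arrange(keys, [Identifier(c) for c in g.group_cols])


def apply_distinct(f: TabularFrame | GroupedFrame, cols: Sequence[str] = (),
                   keep_all: bool = False):
    """Unique rows over ``cols`` (all columns when empty); first occurrence
    kept, input order preserved.  With ``keep_all`` the full rows of the
    kept occurrences are returned; otherwise only ``cols``."""
    base = f.base if isinstance(f, GroupedFrame) else f
    use = list(cols) or list(base.column_order)
    for c in use:
        if c not in base.columns:
            raise UnknownColumnError(f"unknown column {c!r}")
    lists = {c: base.columns[c].to_list() for c in use}
    seen = set()
    idx = []
    for i in range(base.n_rows):
        key = tuple(lists[c][i] for c in use)
        if key not in seen:
            seen.add(key)
            idx.append(i)
    rows = base.take_rows(np.array(idx, dtype=np.int64))
    if not keep_all and cols:
        rows = TabularFrame([(c, rows.columns[c]) for c in use])
    return _regrouped(f, rows) if isinstance(f, GroupedFrame) and not cols else rows


# ---------------------------------------------------------------------------
# coercion
# ---------------------------------------------------------------------------

def to_canonical_frame(obj) -> TabularFrame:
    """Coerce tabular-like input to a TabularFrame (tibble conversion).

    Frames pass through; a grouped frame loses its grouping; a single
    column becomes a one-column frame; mappings name their columns; a
    list of equal-length columns gets synthesized names V1, V2, ...
    """
    if isinstance(obj, GroupedFrame):
        return obj.base
    if isinstance(obj, TabularFrame):
        return obj
    if isinstance(obj, ColumnVector):
        return TabularFrame([("V1", obj)])
    if isinstance(obj, dict):
        return TabularFrame([(k, v if isinstance(v, ColumnVector)
                              else _infer_column(v)) for k, v in obj.items()])
    if isinstance(obj, (list, tuple)):
        cols = [v if isinstance(v, ColumnVector) else _infer_column(v) for v in obj]
        lengths = {len(c) for c in cols}
        if len(lengths) > 1:
            raise ShapeError(f"ragged input: column lengths {sorted(lengths)}")
        return TabularFrame([(f"V{i + 1}", c) for i, c in enumerate(cols)])
    raise ArgumentError(f"cannot coerce {type(obj).__name__} to a frame")


def _infer_column(values) -> ColumnVector:
    present = [v for v in values if v is not None
               and not (isinstance(v, float) and math.isnan(v))]
    if all(isinstance(v, bool) for v in present) and present:
        dtype = "boolean"
    elif all(isinstance(v, (int, bool)) for v in present) and present:
        dtype = "integer"
    elif all(isinstance(v, (int, float, bool)) for v in present) and present:
        dtype = "numeric"
    else:
        dtype = "string"
    return ColumnVector(list(values), dtype)
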