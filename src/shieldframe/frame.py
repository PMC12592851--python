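"""Core tabular data types held in server workspaces.

The unit of server-held data is a :class:`TabularFrame`: an ordered
collection of equal-length, typed columns.  Each column is a
:class:`ColumnVector` carrying an explicit per-cell missingness mask, so
that missing values behave identically across dtypes and survive CSV
round trips.  A :class:`GroupedFrame` is a frame plus grouping metadata;
a :class:`ServerWorkspace` is the named-object store of one simulated
server.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

__all__ = [
    "DTYPES",
    "ColumnVector",
    "TabularFrame",
    "GroupedFrame",
    "ServerWorkspace",
    "FrameError",
    "NamingError",
    "ObjectNotFoundError",
    "ShapeError",
    "TypeMismatchError",
    "UnknownColumnError",
    "is_valid_identifier",
    "read_csv",
    "write_csv",
]

DTYPES = ("numeric", "integer", "boolean", "string", "categorical")

# letters, digits, underscore, dot; must not start with a digit
_IDENTIFIER_RE = re.compile(r"^[A-Za-z._][A-Za-z0-9._]*$")


class FrameError(Exception):
    """Base class for frame-layer errors."""


class NamingError(FrameError):
    pass


class ObjectNotFoundError(FrameError):
    pass


class ShapeError(FrameError):
    pass


class TypeMismatchError(FrameError):
    pass


class UnknownColumnError(FrameError):
    pass


def is_valid_identifier(name: str) -> bool:
    return bool(_IDENTIFIER_RE.match(name))


def _storage_dtype(dtype: str):
    return {
        "numeric": np.float64,
        "integer": np.int64,
        "boolean": np.bool_,
        "string": object,
        "categorical": object,
    }[dtype]


class ColumnVector:
    """A typed column with an explicit missingness mask.

    Parameters
    ----------
    values:
        Cell values.  ``None`` entries are recorded as missing; the slot
        then holds a dtype-appropriate placeholder.
    dtype:
        One of ``numeric``, ``integer``, ``boolean``, ``string``,
        ``categorical``.
    missing:
        Optional explicit mask; merged with ``None`` positions.
    """

    __slots__ = ("values", "dtype", "missing")

    def __init__(self, values: Iterable, dtype: str, missing=None):
        if dtype not in DTYPES:
            raise TypeMismatchError(f"unknown dtype {dtype!r}")
        raw = list(values)
        mask = np.zeros(len(raw), dtype=bool)
        if missing is not None:
            mask |= np.asarray(missing, dtype=bool)
            if len(mask) != len(raw):
                raise ShapeError("missing mask length differs from values")
        fill = {"numeric": np.nan, "integer": 0, "boolean": False,
                "string": "", "categorical": ""}[dtype]
        cleaned = []
        for i, v in enumerate(raw):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                mask[i] = True
                cleaned.append(fill)
            elif mask[i]:
                cleaned.append(fill)
            else:
                cleaned.append(self._coerce(v, dtype))
        self.values = np.array(cleaned, dtype=_storage_dtype(dtype))
        self.dtype = dtype
        self.missing = mask

    @staticmethod
    def _coerce(v, dtype):
        if dtype == "numeric":
            try:
                return float(v)
            except (TypeError, ValueError):
                raise TypeMismatchError(f"non-numeric value {v!r} in numeric column") from None
        if dtype == "integer":
            if isinstance(v, (bool, np.bool_)):
                return int(v)
            if isinstance(v, str) or not float(v) == int(v):
                raise TypeMismatchError(f"non-integral value {v!r} in integer column")
            return int(v)
        if dtype == "boolean":
            if not isinstance(v, (bool, np.bool_)):
                raise TypeMismatchError(f"non-boolean value {v!r} in boolean column")
            return bool(v)
        return str(v)

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ColumnVector):
            return NotImplemented
        if self.dtype != other.dtype or len(self) != len(other):
            return False
        if not np.array_equal(self.missing, other.missing):
            return False
        ok = ~self.missing
        if self.dtype == "numeric":
            return np.allclose(self.values[ok], other.values[ok], rtol=0, atol=0)
        return bool(np.array_equal(self.values[ok], other.values[ok]))

    def __repr__(self) -> str:
        return f"ColumnVector({self.to_list()!r}, dtype={self.dtype!r})"

    def to_list(self) -> list:
        """Values as a plain list with ``None`` for missing cells."""
        out = []
        for v, m in zip(self.values, self.missing):
            if m:
                out.append(None)
            elif self.dtype == "numeric":
                out.append(float(v))
            elif self.dtype == "integer":
                out.append(int(v))
            elif self.dtype == "boolean":
                out.append(bool(v))
            else:
                out.append(str(v))
        return out

    def take(self, idx: np.ndarray) -> "ColumnVector":
        """Row subset/reorder by 0-based integer positions."""
        out = ColumnVector.__new__(ColumnVector)
        out.values = self.values[idx]
        out.missing = self.missing[idx]
        out.dtype = self.dtype
        return out

    @classmethod
    def from_arrays(cls, values: np.ndarray, missing: np.ndarray, dtype: str) -> "ColumnVector":
        out = cls.__new__(cls)
        out.values = np.asarray(values, dtype=_storage_dtype(dtype))
        out.missing = np.asarray(missing, dtype=bool)
        if len(out.values) != len(out.missing):
            raise ShapeError("missing mask length differs from values")
        out.dtype = dtype
        return out


class TabularFrame:
    """Ordered, named, equal-length typed columns."""

    def __init__(self, columns: Mapping[str, ColumnVector] | Sequence[tuple[str, ColumnVector]] = ()):
        items = list(columns.items()) if isinstance(columns, Mapping) else list(columns)
        self.column_order: list[str] = []
        self.columns: dict[str, ColumnVector] = {}
        n = None
        for name, col in items:
            if not is_valid_identifier(name):
                raise NamingError(f"invalid column name {name!r}")
            if name in self.columns:
                raise NamingError(f"duplicate column name {name!r}")
            if n is None:
                n = len(col)
            elif len(col) != n:
                raise ShapeError(f"column {name!r} has length {len(col)}, expected {n}")
            self.column_order.append(name)
            self.columns[name] = col
        self._n_rows = 0 if n is None else n

    @property
    def n_rows(self) -> int:
        return self._n_rows

    @property
    def n_cols(self) -> int:
        return len(self.column_order)

    def schema(self) -> list[tuple[str, str]]:
        """Ordered (name, dtype) listing; never exposes cell values."""
        return [(name, self.columns[name].dtype) for name in self.column_order]

    def column(self, name: str) -> ColumnVector:
        try:
            return self.columns[name]
        except KeyError:
            raise UnknownColumnError(f"unknown column {name!r}") from None

    def take_rows(self, idx: np.ndarray) -> "TabularFrame":
        idx = np.asarray(idx, dtype=np.int64)
        return TabularFrame([(n, self.columns[n].take(idx)) for n in self.column_order])

    def with_columns(self, items: Sequence[tuple[str, ColumnVector]]) -> "TabularFrame":
        """Copy with columns appended (new names) or overwritten in place."""
        cols = [(n, self.columns[n]) for n in self.column_order]
        index = {n: i for i, (n, _) in enumerate(cols)}
        for name, col in items:
            if name in index:
                cols[index[name]] = (name, col)
            else:
                index[name] = len(cols)
                cols.append((name, col))
        return TabularFrame(cols)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TabularFrame) or isinstance(other, GroupedFrame) != isinstance(self, GroupedFrame):
            return NotImplemented
        return (self.column_order == other.column_order
                and all(self.columns[n] == other.columns[n] for n in self.column_order))

    def __repr__(self) -> str:
        return f"<TabularFrame {self.n_rows}x{self.n_cols} {self.column_order}>"

    def to_pandas(self):
        import pandas as pd

        data = {}
        for name in self.column_order:
            col = self.columns[name]
            vals = col.to_list()
            if col.dtype == "numeric":
                data[name] = pd.array([np.nan if v is None else v for v in vals], dtype="float64")
            elif col.dtype == "integer":
                data[name] = pd.array(vals, dtype="Int64")
            elif col.dtype == "boolean":
                data[name] = pd.array(vals, dtype="boolean")
            else:
                data[name] = pd.array(vals, dtype="object")
        return pd.DataFrame(data, columns=list(self.column_order))


@dataclass
class GroupedFrame:
    """A frame plus an ordered list of grouping columns."""

    base: TabularFrame
    group_cols: tuple[str, ...]

    def __post_init__(self):
        self.group_cols = tuple(self.group_cols)
        if not self.group_cols:
            raise FrameError("group_cols must be non-empty")
        for c in self.group_cols:
            if c not in self.base.columns:
                raise UnknownColumnError(f"unknown grouping column {c!r}")

    @property
    def n_rows(self) -> int:
        return self.base.n_rows

    def schema(self) -> list[tuple[str, str]]:
        return self.base.schema()

    def group_index(self) -> tuple[np.ndarray, int]:
        """Group id per row (stable over first appearance) and group count."""
        keys = list(zip(*[
            tuple(zip(self.base.columns[c].to_list(), self.base.columns[c].missing))
            for c in self.group_cols
        ])) if self.n_rows else []
        seen: dict = {}
        ids = np.empty(self.n_rows, dtype=np.int64)
        for i, k in enumerate(keys):
            ids[i] = seen.setdefault(k, len(seen))
        return ids, len(seen)


StoredObject = Union[TabularFrame, GroupedFrame, ColumnVector]


@dataclass
class ServerWorkspace:
    """Named-object store of one simulated server."""

    objects: dict[str, StoredObject] = field(default_factory=dict)

    def assign(self, name: str, obj: StoredObject) -> None:
        if not isinstance(name, str) or not is_valid_identifier(name):
            raise NamingError(f"invalid object name {name!r}")
        self.objects[name] = obj

    def get(self, name: str) -> StoredObject:
        try:
            return self.objects[name]
        except KeyError:
            raise ObjectNotFoundError(f"no object named {name!r} in workspace") from None

    def __contains__(self, name: str) -> bool:
        return name in self.objects


# ---------------------------------------------------------------------------
# CSV interchange.  Headers are type-tagged ("mpg:numeric") so that dtypes,
# values and the missing mask round-trip exactly; bare headers are also
# accepted, with dtypes inferred.  Missing cells are empty fields.
# ---------------------------------------------------------------------------

_TAG_RE = re.compile(r"^(.*):(numeric|integer|boolean|string|categorical)$")


def _format_cell(col: ColumnVector, i: int) -> str:
    if col.missing[i]:
        return ""
    v = col.values[i]
    if col.dtype == "numeric":
        return repr(float(v))
    if col.dtype == "integer":
        return str(int(v))
    if col.dtype == "boolean":
        return "true" if v else "false"
    return str(v)


def write_csv(frame: TabularFrame, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow([f"{n}:{frame.columns[n].dtype}" for n in frame.column_order])
        for i in range(frame.n_rows):
            w.writerow([_format_cell(frame.columns[n], i) for n in frame.column_order])


_INT_RE = re.compile(r"^-?\d+$")
_FLOAT_RE = re.compile(r"^-?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _infer_dtype(cells: list[str]) -> str:
    present = [c for c in cells if c != ""]
    if not present:
        return "string"
    if all(c in ("true", "false", "TRUE", "FALSE") for c in present):
        return "boolean"
    if all(_INT_RE.match(c) for c in present):
        return "integer"
    if all(_FLOAT_RE.match(c) for c in present):
        return "numeric"
    return "string"


def _parse_cell(text: str, dtype: str):
    if text == "":
        return None
    if dtype == "numeric":
        return float(text)
    if dtype == "integer":
        return int(text)
    if dtype == "boolean":
        return text.lower() == "true"
    return text


def read_csv(path) -> TabularFrame:
    with open(path, "r", newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FrameError(f"{path}: empty CSV, header row is mandatory")
    header = rows[0]
    body = rows[1:]
    tags = [_TAG_RE.match(h) for h in header]
    if all(tags):
        names = [m.group(1) for m in tags]
        dtypes = [m.group(2) for m in tags]
    else:
        names = header
        dtypes = [_infer_dtype([r[j] for r in body]) for j in range(len(header))]
    cols = []
    for j, (name, dtype) in enumerate(zip(names, dtypes)):
        cells = []
        for r in body:
            if len(r) != len(header):
                raise ShapeError(f"{path}: ragged row with {len(r)} fields, expected {len(header)}")
            cells.append(_parse_cell(r[j], dtype))
        cols.append((name, ColumnVector(cells, dtype)))
    return TabularFrame(cols)
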