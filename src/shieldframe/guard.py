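"""Disclosure control: privacy profiles and output checks.

Almost every verb here is assign-type — nothing comes back to the
analyst — but subsetting verbs still enable indirect attacks: compare
summary statistics of a frame and of a subset one row smaller and the
difference reveals the missing row.  The guard therefore screens every
subset for (i) a minimum row count, (ii) a minimum difference from the
parent frame, and screens the one aggregate output (group keys) for a
group-count cap relative to frame length (one group per row would
release an entire participant column).  Data owners tune all thresholds
through a :class:`PrivacyProfile`, which also carries the expression
function allowlist and a per-mode set of blocked verbs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

__all__ = [
    "DEFAULT_PERMITTED_FUNCTIONS", "REGISTERED_VERBS", "PrivacyProfile",
    "GuardVerdict", "check_subset", "check_group_keys", "check_verb_allowed",
    "builtin_profile",
]

# Functions permitted inside tidy_expr: tidy selection helpers, the
# conditional/recoding helpers, ordering, and elementwise/aggregate maths.
DEFAULT_PERMITTED_FUNCTIONS: tuple[str, ...] = (
    "everything", "last_col", "group_cols", "starts_with", "ends_with",
    "contains", "matches", "num_range", "all_of", "any_of", "where",
    "rename", "mutate", "if_else", "case_when",
    "mean", "median", "mode", "desc", "nth",
    "exp", "sqrt", "scale", "round", "floor", "ceiling", "abs",
    "sd", "var", "sin", "cos", "tan", "asin", "acos", "atan", "c",
)

# Top-level verbs a server will dispatch; distinct from the expression
# allowlist above (what may appear INSIDE tidy_expr).
REGISTERED_VERBS: tuple[str, ...] = (
    "select", "rename", "mutate", "if_else", "case_when",
    "bind_cols", "bind_rows", "filter", "slice", "arrange",
    "group_by", "ungroup", "group_keys", "distinct", "as_tibble",
)


@dataclass
class PrivacyProfile:
    """Thresholds, allowlist and verb blocking set by a data owner."""

    mode_name: str = "default"
    permitted_functions: tuple[str, ...] = DEFAULT_PERMITTED_FUNCTIONS
    max_name_length: int = 80
    min_subset_rows: int = 3
    min_row_difference: int = 3
    max_group_fraction: float = 0.33
    blocked_verbs: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.permitted_functions = tuple(self.permitted_functions)
        self.blocked_verbs = frozenset(self.blocked_verbs)
        if self.min_subset_rows < 1:
            raise ValueError("min_subset_rows must be >= 1")
        if self.min_row_difference < 0:
            raise ValueError("min_row_difference must be >= 0")
        if not (0 < self.max_group_fraction <= 1):
            raise ValueError("max_group_fraction must be in (0, 1]")

    def to_json(self) -> str:
        d = asdict(self)
        d["permitted_functions"] = list(self.permitted_functions)
        d["blocked_verbs"] = sorted(self.blocked_verbs)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PrivacyProfile":
        d = json.loads(text)
        return cls(
            mode_name=d["mode_name"],
            permitted_functions=tuple(d["permitted_functions"]),
            max_name_length=int(d["max_name_length"]),
            min_subset_rows=int(d["min_subset_rows"]),
            min_row_difference=int(d["min_row_difference"]),
            max_group_fraction=float(d["max_group_fraction"]),
            blocked_verbs=frozenset(d["blocked_verbs"]),
        )

    @classmethod
    def load(cls, path) -> "PrivacyProfile":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_json(fh.read())


def builtin_profile(name: str) -> PrivacyProfile:
    """Bundled modes: ``permissive`` (no subset checks), ``default``,
    and ``avocado`` (blocks the subsetting verbs outright)."""
    if name == "permissive":
        return PrivacyProfile(mode_name="permissive", min_subset_rows=1,
                              min_row_difference=0, max_group_fraction=1.0)
    if name == "default":
        return PrivacyProfile()
    if name == "avocado":
        return PrivacyProfile(mode_name="avocado",
                              blocked_verbs=frozenset({"filter", "slice", "distinct"}))
    raise ValueError(f"unknown built-in profile {name!r}")


@dataclass(frozen=True)
class GuardVerdict:
    code: str  # OK | SUBSET_TOO_SMALL | DIFFERENCE_TOO_SMALL | TOO_MANY_GROUPS | VERB_BLOCKED_IN_MODE
    detail: str = ""

    @property
    def allowed(self) -> bool:
        return self.code == "OK"


_OK = GuardVerdict("OK")


def check_subset(n_original: int, n_subset: int, p: PrivacyProfile) -> GuardVerdict:
    """Screen a subsetting result.

    Blocks small non-empty subsets (0 < n_subset < min_subset_rows) and
    near-complete subsets (0 < n_original - n_subset < min_row_difference).
    An exactly-empty subset reveals only that no row matched, and an
    identical one reveals nothing new; both pass.
    """
    if n_subset > n_original:
        raise ValueError(f"subset of {n_subset} rows exceeds original {n_original}")
    if 0 < n_subset < p.min_subset_rows:
        return GuardVerdict(
            "SUBSET_TOO_SMALL",
            f"subset has {n_subset} rows, fewer than the minimum of {p.min_subset_rows}")
    diff = n_original - n_subset
    if 0 < diff < p.min_row_difference:
        return GuardVerdict(
            "DIFFERENCE_TOO_SMALL",
            f"subset differs from original by {diff} rows, "
            f"fewer than the minimum of {p.min_row_difference}")
    return _OK


def check_group_keys(n_groups: int, n_rows: int, p: PrivacyProfile) -> GuardVerdict:
    """Cap released group counts at max_group_fraction * n_rows (inclusive)."""
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    limit = p.max_group_fraction * n_rows
    if n_groups > limit:
        return GuardVerdict(
            "TOO_MANY_GROUPS",
            f"{n_groups} groups over {n_rows} rows exceeds the allowed "
            f"fraction {p.max_group_fraction}")
    return _OK


def check_verb_allowed(verb: str, p: PrivacyProfile) -> GuardVerdict:
    if verb not in REGISTERED_VERBS:
        raise ValueError(f"unregistered verb {verb!r}")
    if verb in p.blocked_verbs:
        return GuardVerdict(
            "VERB_BLOCKED_IN_MODE",
            f"verb {verb!r} is blocked in privacy mode {p.mode_name!r}")
    return _OK
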