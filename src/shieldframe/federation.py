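"""Simulated client–server federation.

The analyst sits on the client side and never sees the data.  A call
travels as a :class:`CommandMessage` — verb name, target frame name, a
serialized tidy expression, and (for assign calls) the name of the new
object — fanned out to every connected :class:`ServerNode`.  Each
server runs the same lifecycle regardless of what the client claims to
have checked:

1. registry check — the verb must exist server-side;
2. expression re-parse and allowlist/name-length validation against the
   server's own privacy profile;
3. privacy-mode check — the verb may be blocked outright in this mode;
4. verb execution against the named workspace object;
5. output disclosure checks (subset size/difference, group-count cap);
6. bind the result (assign) or release it (aggregate).

Any failing stage short-circuits with that stage's code.  Assign
responses echo only the result's schema — never cell values.  Fan-out
is sequential and failure-isolated: sites are autonomous, so one
server blocking a call does not roll it back elsewhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import verbs
from .expr import (Call, ExprList, ExprParseError, NumberLit, Unary,
                   parse_tidy_expr, validate_expression)
from .frame import (ColumnVector, FrameError, GroupedFrame, NamingError,
                    ObjectNotFoundError, ServerWorkspace, TabularFrame,
                    is_valid_identifier)
from .guard import (REGISTERED_VERBS, PrivacyProfile, check_group_keys,
                    check_subset, check_verb_allowed)

__all__ = ["CommandMessage", "ResponsePayload", "ServerNode", "ClientSession",
           "ClientError", "ASSIGN_VERBS", "AGGREGATE_VERBS"]

AGGREGATE_VERBS = frozenset({"group_keys"})
ASSIGN_VERBS = frozenset(REGISTERED_VERBS) - AGGREGATE_VERBS

# verbs whose output is a row subset of the input frame
_SUBSET_VERBS = frozenset({"filter", "slice", "distinct"})


class ClientError(Exception):
    """Raised client-side; no message is sent to any server."""


@dataclass
class CommandMessage:
    call_type: str  # assign | aggregate
    function_name: str
    df_name: Optional[str] = None
    tidy_expr: Optional[str] = None
    newobj: Optional[str] = None
    extra_args: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "call_type": self.call_type, "function_name": self.function_name,
            "df_name": self.df_name, "tidy_expr": self.tidy_expr,
            "newobj": self.newobj, "extra_args": self.extra_args,
        })

    @classmethod
    def from_dict(cls, d: dict) -> "CommandMessage":
        return cls(call_type=d["call_type"], function_name=d["function_name"],
                   df_name=d.get("df_name"), tidy_expr=d.get("tidy_expr"),
                   newobj=d.get("newobj"), extra_args=dict(d.get("extra_args", {})))

    @classmethod
    def from_json(cls, text: str) -> "CommandMessage":
        return cls.from_dict(json.loads(text))


@dataclass
class ResponsePayload:
    status: str  # ok | blocked | error
    code: str = "OK"
    detail: str = ""
    result: Optional[dict] = None          # aggregate-ok only
    schema_echo: Optional[list] = None     # assign-ok only

    def to_json(self) -> str:
        return json.dumps({"status": self.status, "code": self.code,
                           "detail": self.detail, "result": self.result,
                           "schema_echo": self.schema_echo})


def _frame_payload(f: TabularFrame) -> dict:
    return {"schema": [list(t) for t in f.schema()],
            "n_rows": f.n_rows,
            "columns": {n: f.columns[n].to_list() for n in f.column_order}}


def _schema_of(obj, fallback_name: str) -> list:
    if isinstance(obj, (TabularFrame, GroupedFrame)):
        return [list(t) for t in obj.schema()]
    return [[fallback_name, obj.dtype]]


def _int_positions(node) -> list[int]:
    items = node.items if isinstance(node, ExprList) else [node]
    out = []
    for it in items:
        if isinstance(it, Unary) and it.op == "-" and isinstance(it.operand, NumberLit):
            out.append(-int(it.operand.value))
        elif isinstance(it, NumberLit):
            out.append(int(it.value))
        else:
            raise verbs.ArgumentError("slice positions must be integers")
    return out


def _column_names(frame, node) -> list[str]:
    items = node.items if isinstance(node, ExprList) else [node]
    names = []
    for it in items:
        names.extend(verbs.resolve_selector(frame, it))
    return names


@dataclass
class ServerNode:
    """One simulated data-holding site."""

    node_id: str
    workspace: ServerWorkspace = field(default_factory=ServerWorkspace)
    profile: PrivacyProfile = field(default_factory=PrivacyProfile)
    registry: frozenset = frozenset(REGISTERED_VERBS)
    guard_audit: list = field(default_factory=list)

    def _audit(self, verb: str, check: str, verdict) -> None:
        self.guard_audit.append((verb, check, verdict.code))

    def dispatch(self, msg: CommandMessage) -> ResponsePayload:
        """Run the full server-side lifecycle for one message."""
        # (1) registry: unknown methods are refused before anything runs
        if msg.function_name not in self.registry:
            return ResponsePayload("error", "METHOD_NOT_PERMITTED",
                                   f"function {msg.function_name!r} is not registered on this server")
        if msg.call_type == "assign" and not msg.newobj:
            return ResponsePayload("error", "BAD_MESSAGE", "assign call without newobj")
        if msg.call_type == "aggregate" and msg.function_name not in AGGREGATE_VERBS:
            return ResponsePayload("error", "BAD_MESSAGE",
                                   f"{msg.function_name!r} is not an aggregate-type function")

        # (2) re-parse and re-validate the expression with THIS server's
        # profile: a tampering client gains nothing by skipping its checks
        node = None
        if msg.tidy_expr is not None:
            try:
                node = parse_tidy_expr(msg.tidy_expr)
            except ExprParseError as exc:
                return ResponsePayload("error", "PARSE_ERROR", str(exc))
            report = validate_expression(node, self.profile)
            if not report.ok:
                code, detail = report.violations[0]
                return ResponsePayload("blocked", code, detail)

        # (3) privacy-mode verb blocking
        verdict = check_verb_allowed(msg.function_name, self.profile)
        self._audit(msg.function_name, "verb_mode", verdict)
        if not verdict.allowed:
            return ResponsePayload("blocked", verdict.code, verdict.detail)

        # (4) execute
        try:
            result, n_original = self._execute(msg, node)
        except ObjectNotFoundError as exc:
            return ResponsePayload("error", "OBJECT_NOT_FOUND", str(exc))
        except NamingError as exc:
            return ResponsePayload("error", "NAMING_ERROR", str(exc))
        except FrameError as exc:
            return ResponsePayload("error", "EXECUTION_ERROR", str(exc))

        # (5) output disclosure checks
        if msg.function_name in _SUBSET_VERBS:
            n_new = result.n_rows
            verdict = check_subset(n_original, n_new, self.profile)
            self._audit(msg.function_name, "subset", verdict)
            if not verdict.allowed:
                return ResponsePayload("blocked", verdict.code, verdict.detail)
        if msg.function_name == "group_keys":
            verdict = check_group_keys(result.n_rows, max(n_original, 1), self.profile)
            self._audit(msg.function_name, "group_keys", verdict)
            if not verdict.allowed:
                return ResponsePayload("blocked", verdict.code, verdict.detail)

        # (6) bind or release
        if msg.call_type == "assign":
            self.workspace.assign(msg.newobj, result)
            return ResponsePayload("ok", "OK", f"{msg.newobj!r} created",
                                   schema_echo=_schema_of(result, msg.newobj))
        return ResponsePayload("ok", "OK", "aggregate released",
                               result=_frame_payload(result))

    def _execute(self, msg: CommandMessage, node):
        """Run one verb; returns (result, original row count for guards)."""
        fn = msg.function_name
        extra = msg.extra_args

        if fn in ("bind_rows", "bind_cols"):
            names = extra.get("to_combine") or []
            frames = [verbs.apply_ungroup(self.workspace.get(n)) for n in names]
            out = (verbs.apply_bind_rows if fn == "bind_rows" else verbs.apply_bind_cols)(frames)
            return out, out.n_rows

        if msg.df_name is None:
            raise ObjectNotFoundError(f"{fn} requires df_name")
        obj = self.workspace.get(msg.df_name)
        plain = verbs.apply_ungroup(obj) if isinstance(obj, GroupedFrame) else obj
        n_orig = obj.n_rows if isinstance(obj, (TabularFrame, GroupedFrame)) else len(obj)

        if fn == "select":
            return verbs.apply_select(plain, node), n_orig
        if fn == "rename":
            return verbs.apply_rename(plain, node), n_orig
        if fn == "mutate":
            return verbs.apply_mutate(obj, node), n_orig
        if fn == "filter":
            return verbs.apply_filter(obj, node), n_orig
        if fn == "slice":
            return verbs.apply_slice(obj, _int_positions(node)), n_orig
        if fn == "arrange":
            return verbs.apply_arrange(obj, node), n_orig
        if fn == "group_by":
            return verbs.apply_group_by(obj, _column_names(plain, node)), n_orig
        if fn == "ungroup":
            return verbs.apply_ungroup(obj), n_orig
        if fn == "group_keys":
            if not isinstance(obj, GroupedFrame):
                raise verbs.ArgumentError(f"{msg.df_name!r} is not a grouped frame")
            return verbs.compute_group_keys(obj), n_orig
        if fn == "distinct":
            cols = _column_names(plain, node) if node is not None else []
            keep_all = bool(extra.get("keep_all", False))
            return verbs.apply_distinct(obj, cols, keep_all), n_orig
        if fn == "as_tibble":
            return verbs.to_canonical_frame(obj), n_orig
        if fn == "case_when":
            ctx = verbs.EvalContext.for_frame(obj)
            clauses = node.items if isinstance(node, ExprList) else [node]
            return verbs.eval_case_when(ctx, clauses), n_orig
        if fn == "if_else":
            ctx = verbs.EvalContext.for_frame(obj)
            items = list(node.items) if isinstance(node, ExprList) else [node]
            if len(items) == 1 and isinstance(items[0], Call) and items[0].fn_name == "if_else":
                items = list(items[0].args)
            if len(items) != 3:
                raise verbs.ArgumentError("if_else needs condition, true, false")
            cond, yes, no = (verbs.eval_expr(ctx, it) for it in items)
            return verbs.eval_if_else(cond, yes, no), n_orig
        raise verbs.ArgumentError(f"no executor for verb {fn!r}")


@dataclass
class ClientSession:
    """The analyst's end: client-side checks, fan-out, and a call log."""

    servers: list = field(default_factory=list)
    call_log: list = field(default_factory=list)

    def _fan_out(self, msg: CommandMessage) -> list[ResponsePayload]:
        responses = [srv.dispatch(msg) for srv in self.servers]
        self.call_log.append((msg, responses))
        return responses

    def client_assign(self, function_name: str, df_name: Optional[str],
                      tidy_expr: Optional[str], newobj: str,
                      extra_args: Optional[dict] = None) -> list[ResponsePayload]:
        """Create a named object on every server; responses carry schema only."""
        if function_name not in ASSIGN_VERBS:
            raise ClientError(f"{function_name!r} is not an assign-type function")
        if not is_valid_identifier(newobj):
            raise ClientError(f"invalid newobj name {newobj!r}")
        if df_name is not None and not is_valid_identifier(df_name):
            raise ClientError(f"invalid df_name {df_name!r}")
        if tidy_expr is not None:
            try:
                parse_tidy_expr(tidy_expr)
            except ExprParseError as exc:
                raise ClientError(f"tidy_expr does not parse: {exc}") from exc
        msg = CommandMessage("assign", function_name, df_name, tidy_expr,
                             newobj, dict(extra_args or {}))
        return self._fan_out(msg)

    def client_aggregate(self, function_name: str, df_name: str,
                         extra_args: Optional[dict] = None) -> list[ResponsePayload]:
        """Request a summary; each server releases it only if its guard agrees."""
        if function_name not in AGGREGATE_VERBS:
            raise ClientError(f"{function_name!r} is not an aggregate-type function")
        if not is_valid_identifier(df_name):
            raise ClientError(f"invalid df_name {df_name!r}")
        msg = CommandMessage("aggregate", function_name, df_name,
                             extra_args=dict(extra_args or {}))
        return self._fan_out(msg)

    def run_message(self, msg: CommandMessage) -> list[ResponsePayload]:
        """Fan out an already-built message (script replay path)."""
        return self._fan_out(msg)
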