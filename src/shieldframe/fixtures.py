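"""Synthetic server-side data and the script runner.

Real participant data never leaves a server, so the test bed needs
server-side fixtures it can generate at will.  :func:`generate_fixture`
emits a motor-trend-style table with the classic 11-column schema
(mpg, cyl, disp, hp, drat, wt, qsec, vs, am, gear, carb): only the
schema and plausible ranges are reproduced, not any real table's
values.  Ranges are chosen so that the fuel-efficiency recoding bins
(<15, 15-20, 20-25, >=25 mpg) and the horsepower/weight filter
thresholds (150 hp, 3.5 wt) are all populated.

:func:`boole_sum_recode` is the legacy indicator-sum workaround for
categorising a continuous variable (one >=threshold indicator per
cutoff, summed); it serves as the independent oracle for case_when
recoding throughout the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .federation import ClientSession, CommandMessage, ServerNode
from .frame import ColumnVector, TabularFrame, read_csv
from .guard import PrivacyProfile, builtin_profile

__all__ = ["FixtureSpec", "DEFAULT_SCHEMA", "generate_fixture",
           "boole_sum_recode", "run_script"]

# column -> (dtype, uniform numeric range or category set)
DEFAULT_SCHEMA: dict = {
    "mpg": ("numeric", (10.0, 34.0)),
    "cyl": ("integer", (4, 6, 8)),
    "disp": ("numeric", (70.0, 480.0)),
    "hp": ("integer", (50.0, 340.0)),
    "drat": ("numeric", (2.7, 4.9)),
    "wt": ("numeric", (1.5, 5.5)),
    "qsec": ("numeric", (14.0, 23.0)),
    "vs": ("integer", (0, 1)),
    "am": ("integer", (0, 1)),
    "gear": ("integer", (3, 4, 5)),
    "carb": ("integer", (1, 2, 3, 4, 6, 8)),
}


@dataclass
class FixtureSpec:
    n_rows: int = 32
    seed: int = 0
    schema: dict = field(default_factory=lambda: dict(DEFAULT_SCHEMA))


def generate_fixture(spec: FixtureSpec | None = None, *, n_rows: int | None = None,
                     seed: int | None = None) -> TabularFrame:
    """Draw a reproducible synthetic frame from a fixture spec.

    Numeric columns are uniform over their range (rounded to 3
    decimals so CSV serialization is bit-stable); categorical-style
    integer columns draw uniformly from their value set.
    """
    spec = spec or FixtureSpec()
    if n_rows is not None:
        spec = FixtureSpec(n_rows, spec.seed, spec.schema)
    if seed is not None:
        spec = FixtureSpec(spec.n_rows, seed, spec.schema)
    if spec.n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    rng = np.random.default_rng(spec.seed)
    cols = []
    for name, (dtype, domain) in spec.schema.items():
        if dtype == "numeric":
            lo, hi = domain
            vals = np.round(rng.uniform(lo, hi, spec.n_rows), 3)
            cols.append((name, ColumnVector(vals.tolist(), "numeric")))
        elif dtype == "integer":
            if len(domain) == 2 and domain[0] != 0:  # treat as a range
                lo, hi = domain
                vals = rng.integers(int(lo), int(hi) + 1, spec.n_rows)
            else:
                vals = rng.choice(np.asarray(domain, dtype=np.int64), spec.n_rows)
            cols.append((name, ColumnVector([int(v) for v in vals], "integer")))
        elif dtype in ("string", "categorical", "boolean"):
            vals = rng.choice(np.asarray(domain, dtype=object), spec.n_rows)
            if dtype == "boolean":
                cols.append((name, ColumnVector([bool(v) for v in vals], "boolean")))
            else:
                cols.append((name, ColumnVector([str(v) for v in vals], dtype)))
        else:
            raise ValueError(f"unknown dtype {dtype!r} in fixture schema")
    return TabularFrame(cols)


def boole_sum_recode(v: ColumnVector, thresholds) -> ColumnVector:
    """Indicator-sum categorisation: output[i] = #{t in thresholds : v[i] >= t}.

    This mirrors the multi-step workaround of building one boolean
    vector per cutoff and adding them; missing input propagates.
    Thresholds must be strictly ascending.
    """
    thresholds = list(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly ascending")
    if v.dtype not in ("numeric", "integer"):
        raise TypeError("boole_sum_recode needs a numeric column")
    x = v.values.astype(float)
    counts = np.zeros(len(v), dtype=np.int64)
    for t in thresholds:
        counts += (x >= t).astype(np.int64)
    counts[v.missing] = 0
    return ColumnVector.from_arrays(counts, v.missing.copy(), "integer")


def run_script(script_path, server_csvs, profile_path=None, profile=None,
               log_path=None) -> tuple[int, list[dict]]:
    """Replay a JSON script of command messages against simulated servers.

    Each CSV becomes one server whose workspace holds the table under
    the file's stem name.  Returns (exit_status, log entries); the log
    has one entry per call per server.  A *blocked* response is correct
    disclosure-control behavior, not a failure — only *error* responses
    (or unusable inputs) make the exit status nonzero.
    """
    import os

    if profile is None:
        profile = PrivacyProfile.load(profile_path) if profile_path else builtin_profile("default")
    with open(script_path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise ValueError("script must be a JSON array of command messages")
    messages = [CommandMessage.from_dict(d) for d in raw]

    session = ClientSession()
    for i, csv_path in enumerate(server_csvs):
        name = os.path.splitext(os.path.basename(csv_path))[0]
        node = ServerNode(node_id=f"server{i + 1}", profile=profile)
        node.workspace.assign(name, read_csv(csv_path))
        session.servers.append(node)

    log: list[dict] = []
    any_error = False
    for msg in messages:
        responses = session.run_message(msg)
        for srv, resp in zip(session.servers, responses):
            if resp.status == "error":
                any_error = True
            log.append({"node_id": srv.node_id,
                        "message": json.loads(msg.to_json()),
                        "response": json.loads(resp.to_json())})
    # final workspace schemas, for the caller's record
    for srv in session.servers:
        log.append({"node_id": srv.node_id,
                    "final_schemas": {
                        name: [list(t) for t in obj.schema()] if hasattr(obj, "schema")
                        else [[name, obj.dtype]]
                        for name, obj in srv.workspace.objects.items()}})
    if log_path:
        with open(log_path, "w", encoding="utf-8") as fh:
            for entry in log:
                fh.write(json.dumps(entry) + "\n")
    return (1 if any_error else 0), log
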