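# shieldframe

Simulated federated tidy data manipulation with disclosure control.

In multi-site epidemiology, individual participant data stay on each
site's server: the analyst issues commands from a client and only
non-disclosive results ever travel back. Analysis platforms built this
way have historically made even basic data manipulation painful —
recoding a variable, renaming columns, or subsetting rows takes chains
of awkward calls. `shieldframe` implements the tidy data-manipulation
verbs (`select`, `rename`, `mutate`, `if_else`, `case_when`,
`bind_cols`, `bind_rows`, `filter`, `slice`, `arrange`, `group_by`,
`ungroup`, `group_keys`, `distinct`, tibble conversion) inside a
simulated client–server federation, with every request passing through
the disclosure checks a data owner would demand:

1. **Function allowlist** — expressions sent in `tidy_expr` are parsed
   into a closed DSL; any call to a function outside the permitted set
   (selection helpers, conditionals, elementary maths) is blocked.
2. **Name-length cap** — overlong identifiers, a vehicle for smuggling
   code, are rejected.
3. **Subset screening** — a subset with `0 < n < min_subset_rows` rows,
   or differing from its parent by `0 < d < min_row_difference` rows,
   is blocked: comparing summaries of a frame and a near-identical
   subset would expose the rows in the difference.
4. **Group-count cap** — released group keys may not exceed
   `max_group_fraction × n_rows` distinct groups (one group per row
   would hand back an entire column).
5. **Privacy modes** — data owners bundle thresholds and blocked verbs
   into profiles; the strict `avocado` mode blocks the subsetting verbs
   (`filter`, `slice`, `distinct`) outright.

All but one verb are *assign-type*: they create a named object in the
server workspace and return only its schema, never cell values. The one
*aggregate-type* verb, `group_keys`, releases data (the distinct
grouping combinations) and is guarded by check 4. Servers re-parse and
re-validate everything independently of the client, so a hand-crafted
message that skips client-side checks gains nothing.

## Worked example

Two simulated servers hold synthetic 32-row motor-trend-style tables
(columns `mpg, cyl, disp, hp, drat, wt, qsec, vs, am, gear, carb`); the
first runs the `default` profile, the second the strict `avocado` one.

```python
from shieldframe import (ClientSession, ServerNode, builtin_profile,
                         generate_fixture)

session = ClientSession()
for i, mode in enumerate(["default", "avocado"]):
    node = ServerNode(node_id=f"server{i+1}", profile=builtin_profile(mode))
    node.workspace.assign("mtcars", generate_fixture(n_rows=32, seed=100 + i))
    session.servers.append(node)

# recode miles-per-gallon into four fuel-efficiency categories
responses = session.client_assign(
    "case_when", "mtcars",
    "list(mtcars$mpg < 15 ~ 0, mtcars$mpg >= 15 & mtcars$mpg < 20 ~ 1, "
    "mtcars$mpg >= 20 & mtcars$mpg < 25 ~ 2, mtcars$mpg >= 25 ~ 3)",
    "mpg_category")
for srv, r in zip(session.servers, responses):
    print(srv.node_id, r.status, r.schema_echo)

# subset rows on three conditions in one call
responses = session.client_assign(
    "filter", "mtcars", "cyl > 6 & hp > 150 & wt < 3.5", "filtered_mtcars")
for srv, r in zip(session.servers, responses):
    print(srv.node_id, r.status, r.code, "-", r.detail)
```

prints

```
server1 ok [['mpg_category', 'integer']]
server2 ok [['mpg_category', 'integer']]
server1 ok OK - 'filtered_mtcars' created
server2 blocked VERB_BLOCKED_IN_MODE - verb 'filter' is blocked in privacy mode 'avocado'
```

The recode succeeds on both servers — the response echoes only the new
object's schema. The filter succeeds on the default server but is
blocked on the avocado server, whose mode forbids subsetting verbs;
a *blocked* response is the disclosure control working, not an error.

There is also a small CLI: `shieldframe gen --n 32 --seed 1 --out
mtcars.csv` writes a synthetic server table, and `shieldframe run
--script calls.json --servers mtcars.csv --profile profile.json` replays
a JSON array of command messages against simulated servers, logging one
JSON line per call per server.

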