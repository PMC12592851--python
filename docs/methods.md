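# Methods

## The setting being simulated

`shieldframe` models a federated analysis system: participant-level
tables live in per-server workspaces, the analyst's client sends
commands, and servers answer with metadata (assign calls) or guarded
summaries (aggregate calls). Transport is in-process message passing;
`CommandMessage` and `ResponsePayload` are JSON-serializable so the
message schema is wire-ready, but no network layer, authentication or
session persistence is implemented — sites are simulated as
`ServerNode` objects inside one process. Fan-out to servers is
sequential and failure-isolated: sites are autonomous, so one server
blocking a call neither prevents nor rolls back the others.

Every dispatch runs the same lifecycle regardless of what the client
did: registry check → expression re-parse and allowlist validation
against the *server's* profile → privacy-mode verb check → execution →
output disclosure checks → bind or release. The client performs its own
argument checks (names, parseability) purely for early, local errors;
nothing downstream trusts them.

## The expression DSL

Client expressions travel as text and are parsed server-side into a
closed AST (identifiers, number/string/boolean/missing literals, calls,
infix arithmetic and comparisons, `&`/`|`/`!`, `~` formulas, `:` name
ranges, named arguments, comma lists). Deliberate exclusions, enforced
at parse time: `%op%` operators, `function` definitions, and anything
else that would open the host language. `a$b` is accepted because the
printed call style uses it, and resolves to the plain column `b`: the
evaluation context is always the single frame named in `df_name`.

Validation walks every node: calls outside the profile's permitted set
yield `FORBIDDEN_FUNCTION`; identifiers, call names and argument names
longer than `max_name_length` yield `NAME_TOO_LONG`. The length check
is applied per name rather than to the serialized expression so error
messages can attribute the offending token precisely. The serializer
parenthesizes every compound child, which makes
`parse(serialize(ast)) == ast` a structural identity independent of
operator precedence (property-tested over random ASTs).

## Verb semantics and numerical choices

- **case_when**: first matching clause wins per row; a row matching no
  clause, or whose matching is undecidable, is missing. Clause values
  must share a dtype ({boolean, integer, numeric} unify upward;
  string/categorical unify to string).
- **filter** drops rows whose predicate is missing. On a grouped frame
  the predicate is evaluated on the whole frame and grouping metadata
  is preserved; per-group filtering semantics were an open choice and
  whole-frame evaluation is the simpler, clearly-documented one.
- **arrange** is a stable multi-key sort (via lexicographic key
  stacking); `desc()` is the only ordering modifier; missing values
  sort last under both directions; string ordering is
  codepoint-/bytewise, locale-independent, for cross-machine
  reproducibility. Grouping is ignored for ordering.
- **slice** is 1-based; out-of-range positions drop silently;
  all-negative positions exclude; mixing signs is an error.
- **bind_rows** takes the column union in first-seen order, fills
  absent cells with missing, and unifies {boolean, integer, numeric}
  upward; irreconcilable dtypes (e.g. numeric vs string) are errors.
  **bind_cols** suffixes duplicate names positionally (`name__2`) —
  determinism preferred over rejection.
- **Grouped mutate** supports the permitted reductions (mean, median,
  sd, var, mode, nth) per group with broadcast; a group containing a
  missing value gets a missing reduction (no silent `na.rm`).
  `mode` is the statistical mode (most frequent value, smallest wins
  ties). `scale` is the usual z-score with sample (n−1) denominator.
- **Logical `&`/`|`** propagate missingness from either operand. This
  is slightly stricter than three-valued logic (where `FALSE & NA` is
  `FALSE`); for row filtering the two agree on which rows are kept
  except that we drop a row three-valued logic could also only keep by
  an `|` short-circuit. Documented as a simplification.
- Missing values are explicit per-cell masks, uniform across the five
  dtypes (numeric, integer, boolean, string, categorical). Categorical
  columns are stored as plain strings; no level metadata survives
  operations. Row positions are 1-based everywhere the user sees them.

## Disclosure-control parameters

| parameter | default | meaning |
|---|---|---|
| `permitted_functions` | 36 names | calls allowed inside `tidy_expr` |
| `max_name_length` | 80 chars | per-identifier length cap |
| `min_subset_rows` | 3 rows | block `0 < n_subset <` this |
| `min_row_difference` | 3 rows | block `0 < n_orig − n_subset <` this |
| `max_group_fraction` | 0.33 | cap on groups per row for released keys |
| `blocked_verbs` | ∅ (avocado: filter, slice, distinct) | per-mode verb ban |

The threshold defaults are conservative small values chosen once; data
owners are expected to set their own via profile JSON. Empty subsets
(0 rows) pass: they reveal only that no row matched. Identical subsets
pass: nothing new is released. The group-cap boundary is inclusive
(`n_groups == fraction × n_rows` passes). `bind_rows`/`bind_cols` are
exempt from subset checks since they never shrink data. Three profiles
ship built-in — `permissive`, `default`, `avocado` — giving a testable
lattice of strictness.

The expression allowlist and the server verb registry are distinct
lists on purpose: one governs what may appear *inside* an expression,
the other which top-level methods exist at all.

## Synthetic data

`generate_fixture` emits the classic 11-column motor-trend schema with
uniform draws inside plausible per-column ranges (`mpg` ∈ [10, 34],
`hp` ∈ [50, 340], `wt` ∈ [1.5, 5.5], `cyl` ∈ {4, 6, 8}, …), rounded to
3 decimals so CSV serialization is bit-stable for a given seed. The
ranges are chosen so the four fuel-efficiency bins (<15, 15–20, 20–25,
≥25 mpg) and the 150 hp / 3.5 wt filter thresholds are all populated
at realistic sample sizes. Only schema and ranges are emulated — not
any real table's values, nor real-data features like correlated
columns, skewed distributions, or informative missingness. Passing
tests therefore demonstrate the *mechanics* (verb correctness, guard
behavior, determinism), not robustness to real data pathologies.

The test bed's central oracle is the legacy indicator-sum recode
(`boole_sum_recode`): summing per-threshold `>=` indicators over
cutoffs (15, 20, 25) must equal the four-clause `case_when` recode
elementwise on all non-missing inputs. The two computations share no
code path.

Problem sizes in the suite — 1,000 seeded random vectors for the
recode-equivalence check, 1,000 random 24-row fixtures for the
filter-chaining check, 20-message scripts on 3 servers for the
determinism check — keep the whole suite in seconds while exercising
every code path.

## CSV interchange

Plain CSV carries no dtypes, so `write_csv` emits type-tagged headers
(`mpg:numeric`); `read_csv` accepts both tagged headers (exact round
trip of order, dtypes, values and missing mask) and bare headers (with
dtype inference). Missing is encoded as an empty field in every dtype;
consequently an empty *string* value is not representable distinctly
from missing — a known, documented limitation.

## Known limitations

- No joins, pivots, `summarise`, `across()` or window functions: the
  verb set is intentionally the fifteen listed.
- `where()` supports only the `is.numeric`/`is.character`/`is.logical`
  predicates; `group_cols()` resolves against the current grouping.
- No differential-privacy noise and no query-budget accounting; the
  guard blocks individual queries but does not track an adversary's
  cumulative knowledge across many allowed queries.
- The client/server split is simulated in-process; timing, transport
  failures and credential handling are out of scope.
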