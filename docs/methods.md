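# Methods

## The processing model

A job has three stages, each with a narrow contract.

**Line filtering.** A filter is a function from one TAB-separated line
to zero or more TAB-separated lines; a pipeline is an ordered list of
filters, and running it is the left-to-right fold of the steps over the
document. The contract is streaming: no filter may require the whole
file, so relative output order is inherited from input order and the
only stateful filter (the incrementing-index column) counts the lines
*it* sees — i.e. lines surviving all upstream steps — which is the only
well-defined numbering under streaming.

The TSV dialect is raw: fields are joined by single TABs with no
quoting or escaping, so splitting a serialized line on TAB recovers the
fields exactly. This matches the conventions of the files the tool is
aimed at (BLAST tabular reports, PSM exports, LC-MS feature tables),
where embedded TABs do not occur. Both `\n` and `\r\n` are accepted on
input; `\n` is written. UTF-8 is assumed throughout.

**Loading.** Loading is two-pass: the filtered rows are materialized
and inspected in full before the table is created, so the inferred
schema is fixed and a later row can never narrow a column's type. The
widening rule per column over non-empty values is

    INTEGER  if every value matches [+-]?digits
    REAL     else if every value is a decimal / scientific-notation number
    TEXT     otherwise, and for all-empty columns

Surrounding whitespace is tolerated; `NaN` and `Inf` spellings are
deliberately TEXT so numeric columns always contain finite numbers.
Empty fields load as NULL, which the output stage renders back as the
empty string — this makes the all-TEXT load/select round trip the
identity. Short (ragged) rows are padded with NULL to the widest row
observed, with a warning, because real tool outputs are ragged and a
hard failure would block whole workflows. Header names and explicit
names are sanitized into SQL identifiers (non-alphanumerics to
underscore, leading digit guarded, collisions suffixed `_2`, `_3`, …,
empty names falling back to `c<position>`). Loading into an existing
table name fails unless `replace` is set (drop and recreate): silent
append would be ambiguous.

**Querying.** Query mode is strictly read-only: the file is opened
`mode=ro` and only a single `SELECT` / `WITH … SELECT` statement is
accepted, checked before execution, so a saved database is never
mutated by analysis. The regex functions take `(pattern, subject)` —
`re_replace` takes `(pattern, replacement, subject)` — return SQL
NULL when any argument is NULL, and are registered as deterministic
scalars. No `ORDER BY` is ever injected: callers wanting stable output
must order explicitly, since injecting one would silently change query
semantics. Integers render without a decimal point and reals in
shortest round-trip form (`repr`), chosen so that reloading an output
restores bit-identical values rather than cosmetically rounded ones.

## Configuration

One JSON schema drives all three commands (full job, filter-only,
query-only). Validation is strict — unknown keys are rejected and
errors carry a JSON-pointer to the offending key — implemented with
pydantic models from which the shipped
`tabql/schema/job-config.schema.json` is generated. Exit codes separate
usage errors (2) from runtime errors (1); diagnostics go to stderr so
TSV on stdout stays machine-readable.

## Synthetic data: what it emulates, and what it does not

The generators are all seeded (`numpy.random.default_rng`) and emit
valid engine inputs with no external downloads.

* `gen_psm_table(n, variant_fraction, seed)` — a PSM-report-like table
  (spectrum id, peptide, comma-separated accession list, score).
  Peptide lengths are uniform over 6–36 residues by default so both the
  8- and 30-residue partition boundaries are exercised; 40% of rows
  carry multi-accession lists to exercise normalization. It does not
  emulate score distributions, decoys, modifications or spectrum-level
  structure, so passing tests say nothing about search-engine
  statistics — only about the text/relational mechanics.
* `gen_blast_table(queries, perfect_fraction, seed)` — the conventional
  12-column tabular alignment layout plus an explicit `qlen` column
  (full-length filtering needs the query length; real workflows obtain
  it the same way). A chosen fraction of queries gets one perfect
  full-length gapless hit; all other hits are constructed to violate at
  least one of the three conditions, so ground truth is exact by
  construction. Alignment coordinates and e-values are plausible
  fillers, not modelled.
* `gen_lcms_features(n_low, n_high, relative_shift, noise_sd, seed)` —
  features with true masses drawn without replacement from a 0.5 Da
  grid (80 to <250 Da below the threshold, 250–950 Da above). Low-mass
  features observe `mz = mass·(1 + shift + ε)`, `ε ~ N(0, noise_sd)`;
  high-mass features are exact. Defaults (`shift = 5·10⁻⁴`,
  `noise_sd = 10⁻⁴`, 100 low / 150 high) represent a low-resolution
  instrument miscalibrated for the low-mass range: a ~0.1 Da shift at
  200 Da with ~0.02 Da measurement scatter. The grid guarantees that
  nearest-mass matching to the standards is unambiguous; real data
  would bring isotopes, adducts, charge > 1 and unmatched features,
  none of which are modelled — the scenario demonstrates the inner/
  outer query mechanics and parameter recovery, not instrument physics.

The independent reference for pipeline equivalence
(`tabql.oracle.reference_filter_oracle`) re-implements every filter
naively — whole-document, string-based, driven directly by the JSON
records — and shares no code with the streaming implementation, so
byte-agreement on randomized (document, pipeline) instances is a
meaningful cross-check rather than a tautology.

## Scenario parameters

* Mass threshold 250 Da (the boundary below which the correction
  applies) and a relative matching tolerance of 2·10⁻³, comfortably
  above shift + noise and below the 0.5 Da grid spacing. The average
  is of *relative* errors, and the correction divides by
  `1 + mean error` (the exact inverse of a multiplicative shift).
  With no feature below the threshold the inner aggregate is undefined
  and the scenario raises a clear error rather than emitting NULLs.
* Length partition: "8 to 30" and "30 or greater" overlap at exactly
  30; the 30-residue peptide is assigned to the long output only, so
  the partition is disjoint and exhaustive over peptides ≥ 8 residues.
  Both outputs are `DISTINCT` (a BLAST submission wants each peptide
  once) and explicitly ordered.

## Numerical and edge-case choices

* Noiseless mass correction is tested at relative error < 10⁻⁹ rather
  than exact float equality: the SQL `AVG` reconstructs the common
  shift only to rounding error (observed ~10⁻¹⁶; the test bound leaves
  headroom).
* With noise, the mean residual of the n corrected features is tested
  against `3·noise_sd/√n` — the standard-error bound implied by the
  generator, not a tuned constant.
* A comment line is one whose *first field* starts with a comment
  character; a line starting with a TAB has an empty first field and
  always passes. Empty lines pass for the same reason.
* `normalize` trims surrounding whitespace from each list item
  (`"P1, P2"` lists are ubiquitous in Proteins columns) and pads
  unequal parallel lists with empty strings, with a warning — padding
  keeps row conservation and is recoverable, whereas truncation would
  lose data.
* Column indices past the end of a ragged line read as empty strings
  in `select_columns` and `replace_column` rather than erroring.
* An input that is empty after filtering and has no declared or header
  names is an error (there is nothing to infer a schema from); with
  known names an empty all-TEXT table is created.

## Problem sizes

Tests and the acceptance script run on deliberately small instances —
documents up to 200 lines × 10 columns for oracle equivalence (100
instances), 50-table round trips, 20 staged-vs-single jobs, 200-PSM
scenario sweeps, 250-feature LC-MS tables — sizes at which the
brute-force references are exact and the whole battery completes in a
few seconds. Every property checked is size-independent (byte equality,
set identities, conservation laws), so the small scale costs no
generality for the mechanics being verified; claims about
million-row performance are explicitly not being made.

## Known limitations

* No CSV quoting dialects, no encoding transcoding, no
  skip-leading-N-lines filter.
* No foreign keys, schema migration, concurrent writers or non-SQLite
  backends; no user-defined aggregates beyond SQLite's built-ins.
* Type inference always scans all rows; very large files pay the full
  two-pass cost.
* The filter-error report names the step and the 1-based input line of
  the source document; for lines *derived* by an upstream normalize,
  the reported line is the originating source line.
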