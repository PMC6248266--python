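# tabql

SQL over TAB-separated text for omics workflows.

Multi-step omics pipelines (proteogenomics, metaproteomics,
metabolomics) pass tabular text files between tools, and each handoff
typically needs its own chain of cut/sort/filter/join text-manipulation
steps. `tabql` replaces such chains with one declarative job:

1. **Line filtering** — each input line streams through an ordered
   pipeline of filters, every filter mapping one TAB-separated line to
   zero or more lines: comment removal, regex include/exclude/replace,
   column selection and addition, per-column substitution, and
   first-normal-form *normalization* (one output row per item of a
   comma-separated list field — with several list columns, the i-th
   output row carries the i-th item of each, a parallel zip).
2. **Loading** — the filtered lines are inspected in full, each
   column's SQLite type (`INTEGER`, `REAL` or `TEXT`) is inferred by a
   widening rule, and the rows are loaded into a table of a new or
   existing single-file SQLite database. Default names are `t1, t2, …`
   for tables and `c1, c2, …` for columns; a header row or explicit
   names can override them.
3. **Querying** — a single read-only SQL statement runs against the
   database, with three regex functions registered on the connection —
   `re_search(pattern, subject)`, `re_match(pattern, subject)` and
   `re_replace(pattern, replacement, subject)` — and the result is
   written back out as TAB-separated text.

The query may be omitted when the SQLite database itself is the desired
artifact; it can then be re-queried any number of times without being
mutated.

## Worked example

Collapse a PSM report with comment lines and multi-protein accession
lists into a per-protein summary. With `psms.tsv`:

```
# SearchGUI export 2019-01-09
scan_0001	MLSTAEDFGK	sp|P01234|ALBU_HUMAN, sp|P99999|ALBU_MOUSE	87.2
scan_0002	VVDELTK	sp|Q55501|KRT1_HUMAN	41.0
scan_0003	MLSTAEDFGK	sp|P01234|ALBU_HUMAN	90.5
```

and `job.json`:

```json
{
  "tables": [{
    "file": "psms.tsv",
    "table": "psm",
    "column_names": ["scan", "sequence", "proteins", "score"],
    "filters": [
      {"filter": "exclude_comments"},
      {"filter": "normalize", "columns": [3]}
    ]
  }],
  "query": {
    "sql": "SELECT re_replace('^sp\\|[^|]+\\|', '', proteins) AS protein, count(DISTINCT sequence) AS peptides, max(score) AS best_score FROM psm GROUP BY protein ORDER BY best_score DESC"
  }
}
```

`tabql job.json` prints:

```
protein	peptides	best_score
ALBU_HUMAN	1	90.5
ALBU_MOUSE	1	87.2
KRT1_HUMAN	1	41.0
```

The comment line was dropped, the two-protein list of `scan_0001` was
normalized into one row per accession (so each protein counts its own
distinct peptides — ALBU_HUMAN sees `MLSTAEDFGK` twice but counts it
once), and the regex function stripped the UniProt prefix at query
time.

Two companion commands split the job apart: `tabql-filter` applies a
filter pipeline to one file without any database, and `tabql-query`
runs further read-only queries against a saved database file. Running
the three stages separately is byte-identical to the single job.

## Packaged scenarios

`tabql.scenarios` ships three self-contained jobs (with their SQL under
`tabql/sql/`) that mirror common multi-omic uses, fed by the seeded
generators in `tabql.synthetic`:

* **Proteogenomics variant verification** — keep a PSM only when no
  BLAST hit aligns its peptide perfectly (`pident = 100`), gaplessly
  (`gapopen = 0`) and at full length (`length = qlen`) to a known
  protein (a `NOT EXISTS` anti-join).
* **Metaproteomics length partition** — distinct peptides split into an
  8–29 residue output and a ≥ 30 residue output for separate BLASTP
  analysis; peptides under 8 residues are dropped.
* **Metabolomics mass-error correction** — an inner query averages the
  relative mass error `(mz − mass) / mass` of features below 250 Da
  against known standards; the outer query divides that common error
  out of every below-threshold `mz`, leaving `rt` and `intensity`
  untouched.

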