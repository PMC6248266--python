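"""The three packaged omics scenarios, each a single load + query job.

Each scenario takes tabular text, loads it into a throwaway SQLite
database with :mod:`tabql.loader`, and runs the packaged ``.sql`` asset
through :mod:`tabql.query` — exactly the declarative jobs a user would
write, exercised end to end.

* Proteogenomics variant verification: a putative variant peptide is
  verified when no BLAST hit aligns it perfectly, gaplessly and at full
  length to a known protein.
* Metaproteomics length partition: distinct peptides split into an
  8–29 residue output and a ≥30 residue output (BLASTP wants the two
  length classes analysed separately); peptides under 8 residues are
  dropped.
* Metabolomics mass-error correction: the mean relative mass error of
  below-threshold features against known standards is estimated by an
  inner query and divided out of those features by the outer query.
"""
from __future__ import annotations

import tempfile
from importlib import resources
from pathlib import Path

from .errors import ScenarioError
from .loader import TableSpec, load_job
from .query import execute_query, QueryJob, query_existing_db
from .tabio import parse_document

__all__ = [
    "scenario_sql",
    "scenario_proteogenomics",
    "scenario_metaproteomics_partition",
    "scenario_metabolomics_correction",
]


def scenario_sql(name: str) -> str:
    """Read a packaged scenario query (e.g. ``proteogenomics_verify``)."""
    return (resources.files("tabql") / "sql" / f"{name}.sql").read_text(
        encoding="utf-8")


def _tmp_db() -> Path:
    tmp = tempfile.NamedTemporaryFile(suffix=".sqlite", delete=False)
    tmp.close()
    return Path(tmp.name)


def scenario_proteogenomics(psm_tsv: str, blast_tsv: str) -> str:
    """Verified variant PSMs as TSV (header included).

    *psm_tsv* must carry a header with Spectrum_ID / Sequence /
    Proteins / Score columns; *blast_tsv* is a headerless 13-column
    BLAST report whose last column is the query length.
    """
    db = _tmp_db()
    try:
        load_job(db, [
            TableSpec(source=parse_document(psm_tsv), table_name="psm",
                      first_row_is_header=True),
            TableSpec(source=parse_document(blast_tsv), table_name="blast",
                      column_names=["qseqid", "sseqid", "pident", "length",
                                    "mismatch", "gapopen", "qstart", "qend",
                                    "sstart", "send", "evalue", "bitscore",
                                    "qlen"]),
        ])
        return query_existing_db(db, scenario_sql("proteogenomics_verify"))
    finally:
        db.unlink(missing_ok=True)


def scenario_metaproteomics_partition(psm_tsv: str) -> tuple[str, str]:
    """(short, long) peptide lists as TSV texts with headers.

    Short: distinct peptides of 8–29 residues; long: ≥30 residues;
    peptides under 8 residues appear in neither output.
    """
    db = _tmp_db()
    try:
        load_job(db, [TableSpec(source=parse_document(psm_tsv),
                                table_name="psm", first_row_is_header=True)])
        short = query_existing_db(db, scenario_sql("metaproteomics_short"))
        long = query_existing_db(db, scenario_sql("metaproteomics_long"))
        return short, long
    finally:
        db.unlink(missing_ok=True)


def scenario_metabolomics_correction(features_tsv: str, standards_tsv: str,
                                     mass_threshold: float = 250.0,
                                     tolerance: float = 2e-3) -> str:
    """Corrected (mz, rt, intensity) TSV with header, row order preserved.

    *tolerance* is the relative window for matching a feature to its
    nearest standard when estimating the mean relative mass error.
    Raises :class:`ScenarioError` when no feature lies below the
    threshold (the inner aggregate would be undefined).
    """
    db = _tmp_db()
    params = {"threshold": mass_threshold, "tolerance": tolerance}
    try:
        load_job(db, [
            TableSpec(source=parse_document(features_tsv),
                      table_name="features", first_row_is_header=True),
            TableSpec(source=parse_document(standards_tsv),
                      table_name="standards", first_row_is_header=True),
        ])
        probe = execute_query(QueryJob(
            db=db, sql="SELECT count(*) FROM features WHERE mz < :threshold",
            params={"threshold": mass_threshold}))
        if probe.rows[0][0] == 0:
            raise ScenarioError(
                f"no features below {mass_threshold} Da: the average mass "
                f"error is undefined and no correction can be estimated")
        return query_existing_db(db, scenario_sql("metabolomics_correct"),
                                 params=params)
    finally:
        db.unlink(missing_ok=True)
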