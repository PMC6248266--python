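"""Seeded synthetic fixtures for the packaged omics scenarios.

Three generators emulate the tabular files the tool is routinely
pointed at in proteomics and metabolomics work:

* a PSM (peptide spectrum match) report — spectrum id, peptide
  sequence, a comma-separated protein accession list, and a score;
* a protein BLAST tabular report in the conventional 12-column
  outfmt-6 layout, extended with an explicit query-length column
  (full-length-match filtering needs ``qlen``);
* an LC-MS feature table (mz, rt, intensity) whose low-mass features
  carry a systematic relative mass shift plus optional noise, emulating
  an instrument calibrated for high-mass molecules.

Everything is deterministic for a fixed seed, and a generator's ground
truth is returned alongside the observable table so tests can assert
parameter recovery. There are also generators for random documents and
random filter pipelines used in oracle-equivalence testing.
"""
from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

from .tabio import format_document

__all__ = [
    "gen_psm_table",
    "gen_blast_table",
    "psm_queries",
    "LcmsFixture",
    "gen_lcms_features",
    "gen_random_document",
    "gen_random_pipeline",
]

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

PSM_HEADER = ["Spectrum_ID", "Sequence", "Proteins", "Score"]


def _random_peptide(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(_AMINO_ACIDS, size=n))


def gen_psm_table(n: int, variant_fraction: float = 0.3, seed: int = 0, *,
                  multi_protein_fraction: float = 0.4,
                  length_range: tuple[int, int] = (6, 36)) -> str:
    """A PSM-report-like table as TSV text (header row included).

    ``variant_fraction`` of rows are labelled as putative variant
    peptides (a ``VAR_`` accession); ``multi_protein_fraction`` of rows
    carry a multi-item protein list, exercising 1NF normalization.
    Peptide lengths are uniform over ``length_range``, which spans the
    8 and 30 residue boundaries used in the length-partition scenario.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        seq = _random_peptide(rng, *length_range)
        n_prot = int(rng.integers(2, 5)) if rng.random() < multi_protein_fraction else 1
        accs = [f"PROT{int(rng.integers(1, 500)):04d}" for _ in range(n_prot)]
        if rng.random() < variant_fraction:
            accs[0] = f"VAR_{accs[0]}"
        score = float(np.round(rng.uniform(5.0, 120.0), 3))
        rows.append([f"spectrum_{i + 1:05d}", seq, ",".join(accs), repr(score)])
    return format_document([PSM_HEADER, *rows])


def psm_queries(psm_text: str) -> list[tuple[str, int]]:
    """Distinct (sequence, length) pairs of a PSM table, in first-seen
    order — the query list a BLAST submission would be built from."""
    seen: dict[str, int] = {}
    for line in psm_text.splitlines()[1:]:
        seq = line.split("\t")[1]
        seen.setdefault(seq, len(seq))
    return list(seen.items())


def gen_blast_table(queries: list[tuple[str, int]],
                    perfect_fraction: float = 0.5, seed: int = 0) -> str:
    """A BLASTP-like tabular report (no header), 13 columns:
    qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore qlen.

    A ``perfect_fraction`` share of queries receives one perfect
    full-length hit (pident 100, gapopen 0, length = qlen); every other
    hit is guaranteed to violate at least one of those three conditions.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for qseqid, qlen in queries:
        perfect = rng.random() < perfect_fraction
        n_hits = int(rng.integers(1, 4))
        for h in range(n_hits):
            sseqid = f"sp|{''.join(rng.choice(list(string.ascii_uppercase), 6))}|SUBJ"
            if perfect and h == 0:
                pident, length, mismatch, gapopen = 100.0, qlen, 0, 0
            else:
                # force at least one imperfection
                mode = int(rng.integers(0, 3))
                pident = float(np.round(rng.uniform(55.0, 99.0), 2)) \
                    if mode == 0 else (100.0 if rng.random() < 0.3
                                       else float(np.round(rng.uniform(55.0, 99.0), 2)))
                gapopen = int(rng.integers(1, 3)) if mode == 1 else 0
                length = int(rng.integers(max(1, qlen // 2), qlen)) \
                    if mode == 2 else qlen
                if pident == 100.0 and gapopen == 0 and length == qlen:
                    pident = float(np.round(rng.uniform(55.0, 99.0), 2))
                mismatch = 0 if pident == 100.0 else int(rng.integers(1, 4))
            qstart, qend = 1, length
            sstart = int(rng.integers(1, 200))
            send = sstart + length - 1
            evalue = float(f"{rng.uniform(1e-12, 1e-3):.2e}")
            bitscore = float(np.round(rng.uniform(20.0, 150.0), 1))
            rows.append([qseqid, sseqid, repr(pident), str(length),
                         str(mismatch), str(gapopen), str(qstart), str(qend),
                         str(sstart), str(send), repr(evalue), repr(bitscore),
                         str(qlen)])
    return format_document(rows)


@dataclass(frozen=True)
class LcmsFixture:
    """Observable feature table, the standards reference table, and the
    withheld per-feature ground truth (aligned with the feature rows)."""
    features_tsv: str   # header: mz, rt, intensity
    standards_tsv: str  # header: mass (true masses of low-mass standards)
    true_masses: tuple[float, ...]
    is_low: tuple[bool, ...]


def gen_lcms_features(n_low: int = 100, n_high: int = 150,
                      relative_shift: float = 5e-4, noise_sd: float = 1e-4,
                      seed: int = 0, *,
                      mass_threshold: float = 250.0) -> LcmsFixture:
    """LC-MS features with a systematic mass shift below *mass_threshold*.

    Low-mass features (true mass < threshold) observe
    ``mz = mass * (1 + relative_shift + eps)`` with
    ``eps ~ Normal(0, noise_sd)``; high-mass features are unshifted.
    True masses sit on a 0.5 Da grid so nearest-mass matching to the
    standards is unambiguous. Charge is assumed 1, so mz is numerically
    the molecular mass in Daltons.
    """
    if abs(relative_shift) >= 0.01:
        raise ValueError("relative_shift must be small (|shift| < 0.01)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    low_grid = np.arange(80.0, mass_threshold, 0.5)
    high_grid = np.arange(mass_threshold, 950.0, 0.5)
    if n_low > low_grid.size or n_high > high_grid.size:
        raise ValueError("not enough grid masses for the requested counts")
    low = np.sort(rng.choice(low_grid, size=n_low, replace=False))
    high = np.sort(rng.choice(high_grid, size=n_high, replace=False))
    masses = np.concatenate([low, high])
    is_low = np.concatenate([np.ones(n_low, bool), np.zeros(n_high, bool)])
    eps = rng.normal(0.0, noise_sd, size=masses.size) if noise_sd > 0 else 0.0
    mz = np.where(is_low, masses * (1.0 + relative_shift + eps), masses)
    order = rng.permutation(masses.size)
    rows = []
    for i in order:
        rt = float(np.round(rng.uniform(10.0, 900.0), 2))
        intensity = float(np.round(np.exp(rng.normal(10.0, 1.5)), 1))
        rows.append([repr(float(mz[i])), repr(rt), repr(intensity)])
    features = format_document([["mz", "rt", "intensity"], *rows])
    standards = format_document(
        [["mass"], *([repr(float(m))] for m in low)])
    return LcmsFixture(
        features_tsv=features,
        standards_tsv=standards,
        true_masses=tuple(float(masses[i]) for i in order),
        is_low=tuple(bool(is_low[i]) for i in order),
    )


# ---------------------------------------------------------------------------
# Random documents and pipelines for oracle-equivalence testing

_CELL_POOL = (
    ["", "x", "abc", "chr1", "#tag", "decoy_P1", "A,B", "P1, P2, P3",
     "12/25/2017", "1", "-42", "2.5", "3e-4", "NaN", "a b", "_"]
    + list(string.ascii_lowercase)
)

_PATTERN_POOL = ["^decoy_", "chr", r"\d+", "a", "^#", "P[0-9]", "x|y", "z{3}"]


def gen_random_document(rng: np.random.Generator, *,
                        max_lines: int = 200,
                        max_columns: int = 10) -> list[str]:
    """Random raw TSV lines (cells never contain TAB or newline)."""
    n_lines = int(rng.integers(0, max_lines + 1))
    n_cols = int(rng.integers(1, max_columns + 1))
    lines = []
    for _ in range(n_lines):
        width = n_cols if rng.random() < 0.8 else int(rng.integers(1, n_cols + 1))
        cells = [str(rng.choice(_CELL_POOL)) for _ in range(width)]
        lines.append("\t".join(cells))
    return lines


def gen_random_pipeline(rng: np.random.Generator, *,
                        max_steps: int = 5,
                        max_columns: int = 10) -> list[dict]:
    """A random valid pipeline as JSON filter records."""
    n_steps = int(rng.integers(0, max_steps + 1))
    records = []
    for _ in range(n_steps):
        kind = str(rng.choice(["exclude_comments", "regex_line",
                               "select_columns", "add_column",
                               "replace_column", "normalize"]))
        if kind == "exclude_comments":
            records.append({"filter": kind,
                            "comment_chars": ["#"] if rng.random() < 0.7
                            else ["#", "@"]})
        elif kind == "regex_line":
            action = str(rng.choice(["include", "exclude", "replace"]))
            rec = {"filter": kind,
                   "pattern": str(rng.choice(_PATTERN_POOL)),
                   "action": action}
            if action == "replace":
                rec["replacement"] = str(rng.choice(["", "X", "[\\g<0>]"]))
            records.append(rec)
        elif kind == "select_columns":
            k = int(rng.integers(1, 5))
            records.append({"filter": kind,
                            "columns": [int(rng.integers(1, max_columns + 1))
                                        for _ in range(k)]})
        elif kind == "add_column":
            rec = {"filter": kind,
                   "position": str(rng.choice(["prepend", "append"]))}
            if rng.random() < 0.5:
                rec["text"] = str(rng.choice(["sample1", "", "note"]))
            else:
                rec["start"] = int(rng.integers(0, 10))
            records.append(rec)
        elif kind == "replace_column":
            records.append({"filter": kind,
                            "column": int(rng.integers(1, max_columns + 1)),
                            "pattern": str(rng.choice(_PATTERN_POOL)),
                            "replacement": str(rng.choice(["", "Y", "-"]))})
        else:  # normalize
            k = int(rng.integers(1, 3))
            cols = sorted({int(rng.integers(1, max_columns + 1))
                           for _ in range(k)})
            records.append({"filter": kind, "columns": cols,
                            "separator": ","})
    return records
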