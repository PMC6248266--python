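"""Synthetic generators and the three packaged omics scenarios."""
import math

import numpy as np
import pytest

from tabql.errors import ScenarioError
from tabql.scenarios import (scenario_metabolomics_correction,
                             scenario_metaproteomics_partition,
                             scenario_proteogenomics)
from tabql.synthetic import (gen_blast_table, gen_lcms_features,
                             gen_psm_table, psm_queries)
from tabql.tabio import format_document


def data_rows(tsv: str) -> list[list[str]]:
    return [line.split("\t") for line in tsv.splitlines()[1:]]


# ---------------------------------------------------------------------------
# generators

def test_psm_generator_contract():
    empty = gen_psm_table(0, 0.5, seed=7)
    assert empty.splitlines() == ["Spectrum_ID\tSequence\tProteins\tScore"]
    a = gen_psm_table(100, 0.3, seed=7)
    assert a == gen_psm_table(100, 0.3, seed=7)   # seeded determinism
    assert a != gen_psm_table(100, 0.3, seed=8)
    rows = data_rows(a)
    assert len(rows) == 100
    assert all(set(r[1]) <= set("ACDEFGHIKLMNPQRSTVWY") for r in rows)
    assert all(r[2] for r in rows)                # protein list nonempty
    assert any("," in r[2] for r in rows)         # lists exercise normalize


def perfect_hits(blast_tsv: str) -> set[str]:
    out = set()
    for cells in (ln.split("\t") for ln in blast_tsv.splitlines()):
        pident, length, gapopen, qlen = (float(cells[2]), int(cells[3]),
                                         int(cells[5]), int(cells[12]))
        if pident == 100.0 and gapopen == 0 and length == qlen:
            out.add(cells[0])
    return out


def test_blast_generator_respects_perfect_fraction():
    queries = psm_queries(gen_psm_table(60, 0.3, seed=11))
    all_perfect = gen_blast_table(queries, perfect_fraction=1.0, seed=2)
    assert perfect_hits(all_perfect) == {q for q, _ in queries}
    none_perfect = gen_blast_table(queries, perfect_fraction=0.0, seed=2)
    assert perfect_hits(none_perfect) == set()
    assert gen_blast_table(queries, 0.5, seed=5) == \
        gen_blast_table(queries, 0.5, seed=5)


def test_lcms_generator_contract():
    fx = gen_lcms_features(50, 150, relative_shift=5e-4, noise_sd=0.0,
                           seed=9)
    rows = data_rows(fx.features_tsv)
    assert len(rows) == 200
    assert fx == gen_lcms_features(50, 150, relative_shift=5e-4,
                                   noise_sd=0.0, seed=9)
    for cells, mass, low in zip(rows, fx.true_masses, fx.is_low):
        mz = float(cells[0])
        if low:
            assert math.isclose(mz / mass - 1.0, 5e-4, rel_tol=1e-9)
        else:
            assert mz == mass


# ---------------------------------------------------------------------------
# proteogenomics: verified variants = peptides with no perfect hit

def brute_force_survivors(psm_tsv: str, blast_tsv: str) -> list[list[str]]:
    known = perfect_hits(blast_tsv)
    return [r for r in data_rows(psm_tsv) if r[1] not in known]


@pytest.mark.parametrize("fraction", [0.0, 0.3, 1.0])
def test_proteogenomics_matches_per_row_brute_force(fraction):
    psm = gen_psm_table(80, 0.4, seed=21)
    blast = gen_blast_table(psm_queries(psm), fraction, seed=22)
    result = data_rows(scenario_proteogenomics(psm, blast))
    assert result == brute_force_survivors(psm, blast)
    if fraction == 1.0:
        assert result == []
    if fraction == 0.0:
        assert result == data_rows(psm)


def test_proteogenomics_hand_worked_example():
    """Six hits, two of them perfect full-length: the other four
    queries' PSMs survive verification."""
    psms = [["s1", "AAAAAAAA", "P1", "1.0"],
            ["s2", "CCCCCCCC", "P2", "2.0"],
            ["s3", "DDDDDDDD", "P3", "3.0"],
            ["s4", "EEEEEEEE", "P4", "4.0"],
            ["s5", "FFFFFFFF", "P5", "5.0"],
            ["s6", "GGGGGGGG", "P6", "6.0"]]
    psm_tsv = format_document(
        [["Spectrum_ID", "Sequence", "Proteins", "Score"], *psms])

    def hit(q, pident, length, gapopen, qlen):
        return [q, "sbj", str(pident), str(length), "0", str(gapopen),
                "1", str(length), "1", str(length), "1e-8", "50.0",
                str(qlen)]

    blast_tsv = format_document([
        hit("AAAAAAAA", 100.0, 8, 0, 8),   # perfect -> s1 removed
        hit("CCCCCCCC", 99.9, 8, 0, 8),    # identity < 100
        hit("DDDDDDDD", 100.0, 8, 1, 8),   # gapped
        hit("EEEEEEEE", 100.0, 7, 0, 8),   # not full length
        hit("FFFFFFFF", 100.0, 8, 0, 8),   # perfect -> s5 removed
        hit("GGGGGGGG", 50.0, 4, 2, 8),    # everything wrong
    ])
    result = data_rows(scenario_proteogenomics(psm_tsv, blast_tsv))
    assert [r[0] for r in result] == ["s2", "s3", "s4", "s6"]


# ---------------------------------------------------------------------------
# metaproteomics: length partition at 8 and 30 residues

def test_partition_on_the_five_length_worked_example():
    seqs = ["A" * 7, "C" * 8, "D" * 29, "E" * 30, "F" * 31]
    psm_tsv = format_document(
        [["Spectrum_ID", "Sequence", "Proteins", "Score"],
         *[[f"s{i}", s, "P1", "1.0"] for i, s in enumerate(seqs)]])
    short, long = scenario_metaproteomics_partition(psm_tsv)
    assert {len(r[0]) for r in data_rows(short)} == {8, 29}
    assert {len(r[0]) for r in data_rows(long)} == {30, 31}


def test_partition_is_disjoint_and_exhaustive_over_8_plus():
    psm_tsv = gen_psm_table(120, 0.3, seed=31)
    short, long = scenario_metaproteomics_partition(psm_tsv)
    short_set = {r[0] for r in data_rows(short)}
    long_set = {r[0] for r in data_rows(long)}
    assert not short_set & long_set
    peptides = {r[1] for r in data_rows(psm_tsv)}
    assert short_set | long_set == {p for p in peptides if len(p) >= 8}
    assert all(8 <= len(p) < 30 for p in short_set)
    assert all(len(p) >= 30 for p in long_set)


def test_partition_deduplicates_and_handles_empty_input():
    psm_tsv = format_document(
        [["Spectrum_ID", "Sequence", "Proteins", "Score"],
         ["s1", "PEPTIDES", "P1", "1.0"],
         ["s2", "PEPTIDES", "P2", "2.0"]])
    short, long = scenario_metaproteomics_partition(psm_tsv)
    assert data_rows(short) == [["PEPTIDES"]]
    assert data_rows(long) == []
    empty = format_document([["Spectrum_ID", "Sequence", "Proteins",
                              "Score"]])
    short, long = scenario_metaproteomics_partition(empty)
    assert data_rows(short) == [] and data_rows(long) == []


# ---------------------------------------------------------------------------
# metabolomics: systematic mass-shift correction below 250 Da

def test_noiseless_correction_recovers_true_masses_exactly():
    fx = gen_lcms_features(40, 60, relative_shift=5e-4, noise_sd=0.0,
                           seed=41)
    out = data_rows(scenario_metabolomics_correction(
        fx.features_tsv, fx.standards_tsv))
    for cells, mass, low in zip(out, fx.true_masses, fx.is_low):
        if low:
            assert math.isclose(float(cells[0]), mass, rel_tol=1e-9)


def test_zero_shift_is_a_fixed_point():
    fx = gen_lcms_features(40, 60, relative_shift=0.0, noise_sd=0.0,
                           seed=42)
    out = scenario_metabolomics_correction(fx.features_tsv,
                                           fx.standards_tsv)
    for got, orig in zip(data_rows(out), data_rows(fx.features_tsv)):
        assert math.isclose(float(got[0]), float(orig[0]), rel_tol=1e-12)


def test_noisy_correction_centers_residuals_and_keeps_high_mass_rows():
    n_low = 100
    fx = gen_lcms_features(n_low, 150, relative_shift=5e-4,
                           noise_sd=1e-4, seed=43)
    out = data_rows(scenario_metabolomics_correction(
        fx.features_tsv, fx.standards_tsv))
    residuals = [float(c[0]) / m - 1.0
                 for c, m, low in zip(out, fx.true_masses, fx.is_low)
                 if low]
    assert len(residuals) == n_low
    assert abs(np.mean(residuals)) < 3 * 1e-4 / math.sqrt(n_low)
    # high-mass rows pass through byte-unchanged (rt/intensity too)
    for got, orig, low in zip(out, data_rows(fx.features_tsv), fx.is_low):
        assert got[1:] == orig[1:]
        if not low:
            assert got == orig


def test_no_low_mass_features_is_a_clear_error():
    fx = gen_lcms_features(0, 20, relative_shift=5e-4, noise_sd=0.0,
                           seed=44)
    standards = "mass\n100.0\n"
    with pytest.raises(ScenarioError, match="below 250"):
        scenario_metabolomics_correction(fx.features_tsv, standards)
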