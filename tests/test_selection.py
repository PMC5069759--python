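"""NG86 dN/dS: hand-derived oracles, brute-force pathway enumeration,
alignment back-threading, and estimator symmetry."""

import math
import warnings
from itertools import product

import numpy as np
import pytest

from strainscope.genetics import CODON_TO_AA, SENSE_CODONS, translate
from strainscope.selection import (
    CodonAlignment,
    align_proteins_global,
    backthread_codons,
    classify_selection,
    codon_alignment_from_cds,
    count_differences_ng86,
    count_sites_ng86,
    dnds,
    dnds_from_cds,
    jukes_cantor,
)
from strainscope.synthetic import evolve_ortholog_pair


# --- independent oracle: recursive path enumeration -------------------------


def _oracle_differences(a: str, b: str) -> tuple[float, float]:
    """Enumerate mutational paths recursively; average (sd, nd) uniformly
    over stop-free paths; all-nonsynonymous fallback when none survive."""
    diff = [i for i in range(3) if a[i] != b[i]]
    outcomes: list[tuple[float, float]] = []

    def walk(current: str, remaining: list[int], sd: float, nd: float) -> None:
        if not remaining:
            outcomes.append((sd, nd))
            return
        for pos in remaining:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            if CODON_TO_AA[nxt] == "*":
                continue
            step_syn = CODON_TO_AA[nxt] == CODON_TO_AA[current]
            walk(nxt, [p for p in remaining if p != pos],
                 sd + step_syn, nd + (not step_syn))

    walk(a, diff, 0.0, 0.0)
    if not outcomes:
        return 0.0, float(len(diff))
    return (
        sum(o[0] for o in outcomes) / len(outcomes),
        sum(o[1] for o in outcomes) / len(outcomes),
    )


@pytest.mark.parametrize(
    "codon,expected_s",
    [("TTT", 1 / 3), ("ATG", 0.0), ("CTT", 1.0), ("TGG", 0.0)],
)
def test_site_counts_hand_oracle(codon, expected_s):
    s, n = count_sites_ng86(codon)
    assert s == pytest.approx(expected_s, abs=1e-12)
    assert s + n == pytest.approx(3.0, abs=1e-12)


def test_site_counts_sum_to_three_for_all_sense_codons():
    for codon in SENSE_CODONS:
        s, n = count_sites_ng86(codon)
        assert 0.0 <= s <= 3.0
        assert s + n == pytest.approx(3.0, abs=1e-12)


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("TTT", "TTT", (0.0, 0.0)),
        ("TTT", "TTC", (1.0, 0.0)),
        ("TTT", "TTA", (0.0, 1.0)),
        ("TTT", "GTA", (0.5, 1.5)),  # two stop-free paths, hand enumeration
    ],
)
def test_difference_counts_hand_oracle(a, b, expected):
    assert count_differences_ng86(a, b) == pytest.approx(expected, abs=1e-12)


def test_difference_counts_match_enumeration_on_random_pairs():
    rng = np.random.default_rng(5)
    codons = list(SENSE_CODONS)
    for _ in range(300):
        a, b = rng.choice(codons, size=2)
        got = count_differences_ng86(a, b)
        want = _oracle_differences(a, b)
        assert got == pytest.approx(want, abs=1e-12)
        k = sum(1 for i in range(3) if a[i] != b[i])
        # conservation: sd + nd equals the number of differing positions
        # (the all-nonsynonymous fallback preserves it too)
        assert sum(got) == pytest.approx(k, abs=1e-12)


def test_difference_counts_symmetric():
    rng = np.random.default_rng(6)
    for _ in range(100):
        a, b = rng.choice(list(SENSE_CODONS), size=2)
        ab = count_differences_ng86(a, b)
        ba = count_differences_ng86(b, a)
        assert ab == pytest.approx(ba, abs=1e-12)


def test_stop_codons_rejected():
    with pytest.raises(ValueError):
        count_sites_ng86("TAA")
    with pytest.raises(ValueError):
        count_differences_ng86("TAA", "TTT")


# --- protein alignment and back-threading -----------------------------------


def test_alignment_identical_strings_no_gaps():
    aln = align_proteins_global("MKVLA", "MKVLA")
    assert aln.aligned_a == aln.aligned_b == "MKVLA"
    assert aln.identity == 1.0


def test_alignment_single_gap_column():
    aln = align_proteins_global("MKV", "MV")
    assert sorted((aln.aligned_a, aln.aligned_b)) == ["M-V", "MKV"]


def test_alignment_score_symmetric():
    a, b = "MKVLAWWGH", "MKLAWGH"
    assert align_proteins_global(a, b).score == align_proteins_global(b, a).score


def test_backthread_gapless_and_trailing_stop():
    cds_a = "ATGAAAGTT" + "TAA"  # MKV + stop
    cds_b = "ATGAAAGTC"  # MKV, no stop
    aln = align_proteins_global("MKV", "MKV")
    caln = backthread_codons(aln, cds_a, cds_b)
    assert caln.codons_a == ["ATG", "AAA", "GTT"]  # stop column absent
    assert caln.codons_b == ["ATG", "AAA", "GTC"]


def test_backthread_gap_column_excluded_from_counting():
    aln = align_proteins_global("MKV", "MV")
    caln = backthread_codons(aln, "ATGAAAGTT", "ATGGTT")
    assert "---" in caln.codons_a or "---" in caln.codons_b
    assert len(caln.comparable_columns()) == 2


def test_backthread_translation_mismatch_raises():
    aln = align_proteins_global("MKV", "MKV")
    with pytest.raises(ValueError):
        backthread_codons(aln, "ATGAAAAAA", "ATGAAAGTT")  # MKK != MKV


# --- dN/dS -------------------------------------------------------------------


def test_dnds_identical_sequences_omega_undefined():
    cds = "ATGAAAGTTCTTGGGCAT" * 20
    res = dnds_from_cds(cds, cds)
    assert res.dN == 0.0 and res.dS == 0.0
    assert math.isnan(res.omega)
    assert "dS_zero" in res.flags
    assert classify_selection(res) == "neutral_or_undetermined"


def test_jukes_cantor_zero_and_saturation():
    assert jukes_cantor(0.0) == 0.0
    assert math.isnan(jukes_cantor(0.8))


def test_dnds_symmetric():
    pair = evolve_ortholog_pair(150, 0.4, 60, 1.0, seed=3)
    r1 = dnds_from_cds(pair.cds_a, pair.cds_b)
    r2 = dnds_from_cds(pair.cds_b, pair.cds_a)
    assert r1.dN == pytest.approx(r2.dN, abs=1e-12)
    assert r1.dS == pytest.approx(r2.dS, abs=1e-12)


def test_dnds_site_conservation():
    pair = evolve_ortholog_pair(200, 0.5, 50, 0.0, seed=4)
    res = dnds_from_cds(pair.cds_a, pair.cds_b)
    assert res.S + res.N == pytest.approx(3 * res.n_codons, abs=1e-9)


@pytest.mark.parametrize("omega,expected", [(0.05, "purifying"), (2.0, "positive")])
def test_classification_thresholds(omega, expected):
    pair = evolve_ortholog_pair(300, 0.3, 60, 0.0, seed=8)
    res = dnds_from_cds(pair.cds_a, pair.cds_b)
    res.omega = omega
    assert classify_selection(res) == expected


def test_omega_recovery_midrange():
    """Median NG86 estimate over replicate pairs recovers ω = 0.5."""
    est = []
    for i in range(30):
        p = evolve_ortholog_pair(500, 0.5, 150, 0.0, seed=1000 + i)
        est.append(dnds_from_cds(p.cds_a, p.cds_b).omega)
    assert 0.35 <= float(np.median(est)) <= 0.65


def test_dnds_agrees_with_reference_implementation():
    """Loose cross-check against an independently written NG86 (the two
    differ in stop-codon site bookkeeping, so only near-agreement is
    expected)."""
    from Bio.Align import Alignment
    from Bio.Align.analysis import calculate_dn_ds
    from Bio.Seq import Seq

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(3):
            p = evolve_ortholog_pair(300, 0.3, 80, 0.0, seed=seed)
            n = len(p.cds_a)
            aln = Alignment(
                [Seq(p.cds_a), Seq(p.cds_b)], np.array([[0, n], [0, n]])
            )
            dn_ref, ds_ref = calculate_dn_ds(aln, method="NG86")
            mine = dnds_from_cds(p.cds_a, p.cds_b)
            assert mine.dN == pytest.approx(dn_ref, rel=0.10, abs=5e-3)
            assert mine.dS == pytest.approx(ds_ref, rel=0.15, abs=5e-3)
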