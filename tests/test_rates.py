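"""Ka/Ks estimation, diversity, dating and group-comparison unit tests."""

import itertools
import math

import numpy as np
import pytest

from nlrevo.rates import (
    DatingParams,
    SaturationError,
    classify_pair,
    codon_align,
    compare_groups,
    date_duplication,
    ks_histogram,
    ng86,
    ng86_codons,
    ng86_counts,
    nucleotide_diversity,
    pathway_differences,
    positive_selection_fraction,
    syn_site_fraction,
)
from nlrevo._common import SENSE_CODONS


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

def test_single_codon_synonymous_pair_counts():
    # GAA vs GAG: one synonymous difference; each codon offers exactly one
    # synonymous change (third position, Glu is two-fold degenerate)
    s, n, sd, nd = ng86_counts([("GAA", "GAG")])
    assert s == pytest.approx(1 / 3)
    assert n == pytest.approx(3 - 1 / 3)
    assert sd == 1.0 and nd == 0.0
    # one synonymous difference over a third of a site saturates the
    # Jukes-Cantor correction: a single codon cannot yield a finite Ks
    with pytest.raises(SaturationError):
        ng86_codons([("GAA", "GAG")])


def test_identical_sequences_have_zero_rates():
    cds = "ATGGAAGAGTTTCCA"
    ka, ks, omega = ng86(cds, cds)
    assert ka == 0.0 and ks == 0.0 and omega is None


def test_pathway_averaging_skips_stop_intermediates():
    # TGT -> TAC: direct orders pass through TAT (Tyr) or TGC (Cys);
    # neither is a stop so both orders count
    sd, nd = pathway_differences("TGT", "TAC")
    # both orders give one synonymous step (Cys->Cys or Tyr->Tyr) and one
    # nonsynonymous step; no stop intermediates arise
    assert sd == pytest.approx(1.0) and nd == pytest.approx(1.0)
    # TGT -> AGA: going through TGA (stop) is excluded, so only the order
    # via AGT (Ser) counts
    sd2, nd2 = pathway_differences("TGT", "AGA")
    assert sd2 == 0.0 and nd2 == pytest.approx(2.0)


def test_ng86_symmetry_on_random_sequences():
    rng = np.random.default_rng(11)
    for _ in range(25):
        codons_a = [SENSE_CODONS[i] for i in rng.integers(0, 61, size=40)]
        codons_b = [SENSE_CODONS[i] for i in rng.integers(0, 61, size=40)]
        cols = list(zip(codons_a, codons_b))
        swapped = [(b, a) for a, b in cols]
        ca, cb = ng86_counts(cols), ng86_counts(swapped)
        assert all(abs(x - y) <= 1e-12 for x, y in zip(ca, cb))


def test_jukes_cantor_correction_is_monotone():
    # build column sets with increasing synonymous difference load
    prev = -1.0
    for k in (0, 4, 8, 12):
        cols = [("GAA", "GAG")] * k + [("GAA", "GAA")] * (60 - k)
        _, ks, _ = ng86_codons(cols)
        assert ks > prev
        prev = ks


def test_saturation_raises():
    cols = [("GAA", "GAG")] * 50 + [("GAA", "GAA")] * 10
    with pytest.raises(SaturationError):
        ng86_codons(cols)


# ---------------------------------------------------------------------------
# codon alignment
# ---------------------------------------------------------------------------

def test_codon_align_identical_is_gapless():
    cds = "ATG" + "GAAGTTCCTAAA" * 10
    cols = codon_align(cds, cds)
    assert len(cols) == len(cds) // 3
    assert all(ca == cb and "-" not in ca for ca, cb in cols)


def test_codon_align_single_codon_deletion_gives_one_gap():
    cds = "ATG" + "GAAGTTCCTAAACGT" * 8
    removed = cds[:30] + cds[33:]
    cols = codon_align(cds, removed)
    gap_cols = [(ca, cb) for ca, cb in cols if "-" in ca or "-" in cb]
    assert len(gap_cols) == 1
    assert gap_cols[0][1] == "---"


def test_codon_align_rejects_internal_stop():
    with pytest.raises(ValueError, match="stop"):
        codon_align("ATGTAAGAA", "ATGGAAGAA")


# ---------------------------------------------------------------------------
# pair typing, selection fractions, Pi
# ---------------------------------------------------------------------------

def test_classify_pair_by_species():
    smap = {"a": "Ppersica", "b": "Ppersica", "c": "Pavium"}
    assert classify_pair("a", "b", smap) == "paralog"
    assert classify_pair("a", "c", smap) == "ortholog"
    with pytest.raises(KeyError):
        classify_pair("a", "zzz", smap)


def test_positive_selection_fraction_reporting():
    omegas = [2.0] * 512 + [0.5] * (8438 - 512)
    r = positive_selection_fraction(omegas)
    assert (r["count_gt1"], r["total"], r["percent"]) == (512, 8438, 6.07)
    r2 = positive_selection_fraction([0.3] * 10)
    assert r2["percent"] == 0.00
    assert positive_selection_fraction([])["percent"] is None
    r3 = positive_selection_fraction([1.005, 0.995, 0.5, 1.5])
    assert r3["neutral_candidates"] == 2


def test_nucleotide_diversity_closed_forms():
    fam = {"g1": "ATG" + "GAA" * 33, "g2": "ATG" + "GAA" * 33}
    assert nucleotide_diversity("f", fam).pi == 0.0
    # one difference in 102 compared sites
    a = "ATG" + "GAA" * 33
    b = a[:-1] + "G"  # last codon GAA -> GAG
    pi = nucleotide_diversity("f", {"g1": a, "g2": b}).pi
    assert pi == pytest.approx(1 / 102)


def test_nucleotide_diversity_matches_pairwise_oracle_and_order():
    rng = np.random.default_rng(5)
    members = {}
    base = [SENSE_CODONS[i] for i in rng.integers(0, 61, size=50)]
    for k in range(4):
        cod = list(base)
        for pos in rng.integers(0, 50, size=3 + k):
            cod[pos] = SENSE_CODONS[rng.integers(0, 61)]
        members[f"g{k}"] = "".join(cod)
    pi = nucleotide_diversity("f", members).pi
    # independent oracle: direct hamming proportion over all pairs
    # (sequences are equal-length and indel-free, so alignment is identity)
    props = []
    for x, y in itertools.combinations(sorted(members), 2):
        sx, sy = members[x], members[y]
        props.append(sum(1 for u, v in zip(sx, sy) if u != v) / len(sx))
    assert pi == pytest.approx(np.mean(props), abs=1e-12)
    shuffled = dict(reversed(list(members.items())))
    assert nucleotide_diversity("f", shuffled).pi == pytest.approx(pi)


def test_nucleotide_diversity_single_member_is_nan():
    assert math.isnan(nucleotide_diversity("f", {"g": "ATGGAA"}).pi)


# ---------------------------------------------------------------------------
# dating
# ---------------------------------------------------------------------------

def test_dating_printed_values():
    assert date_duplication(0.1) == 31.65
    assert date_duplication(0.2) == 63.29
    assert date_duplication(0.5) == 158.23
    assert date_duplication(0.0) == 0.0


def test_dating_is_linear_in_ks():
    for k in (0.05, 0.123, 0.4):
        assert date_duplication(2 * k) == pytest.approx(2 * date_duplication(k), abs=0.01)


def test_dating_rejects_negative_and_bad_params():
    with pytest.raises(ValueError):
        date_duplication(-0.1)
    with pytest.raises(ValueError):
        DatingParams(mu=0.0)


# ---------------------------------------------------------------------------
# group comparison and histograms
# ---------------------------------------------------------------------------

def test_compare_groups_identical_degenerate():
    r = compare_groups([0.3, 0.3, 0.3], [0.3, 0.3, 0.3])
    assert r["t_statistic"] == 0.0 and r["p_value"] == 1.0


def test_compare_groups_matches_hand_computed_welch():
    a = [0.5, 0.6, 0.7, 0.8]
    b = [0.1, 0.2, 0.3]
    r = compare_groups(a, b)
    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    t_hand = (ma - mb) / math.sqrt(va / len(a) + vb / len(b))
    assert r["t_statistic"] == pytest.approx(t_hand, abs=1e-12)
    assert r["group_a"]["median"] == pytest.approx(0.65)
    assert r["group_a"]["q1"] == pytest.approx(np.percentile(a, 25))


def test_compare_groups_detects_shifted_distributions():
    rng = np.random.default_rng(3)
    a = rng.normal(0.5, 0.1, 200)
    b = rng.normal(0.2, 0.1, 200)
    assert compare_groups(a, b)["p_value"] < 0.01


def test_ks_histogram_shapes():
    h = ks_histogram([0.15] * 20)
    assert h["counts"][1] == 20 and sum(h["counts"]) == 20
    assert h["modal_bins"] == [1]
    empty = ks_histogram([])
    assert sum(empty["counts"]) == 0 and empty["modal_bins"] == []
    # values at or above the filter cap are ignored
    assert sum(ks_histogram([1.0, 1.5, -0.1])["counts"]) == 0
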