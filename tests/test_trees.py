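"""NJ topology recovery, bootstrap supports, Newick I/O and clade-calling tests."""

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj

from nlrevo.simulate import SimConfig, simulate_family_set
from nlrevo.trees import (
    bootstrap_support,
    classify_clades,
    duplication_proportions,
    jc_distance_matrix,
    nj_tree,
    read_newick,
    write_newick,
)


def random_additive_distances(rng, ids):
    """Random binary topology over ``ids`` with its additive leaf-leaf
    distances, built by recursive partition (independent of any NJ code).

    Returns (non-trivial splits, pairwise distance dict).
    """
    n = len(ids)
    splits = []

    def build(leaves):
        if len(leaves) == 1:
            return {(leaves[0], leaves[0]): 0.0}, {leaves[0]: 0.0}
        k = int(rng.integers(1, len(leaves)))
        left, right = list(leaves[:k]), list(leaves[k:])
        for side in (left, right):
            if 2 <= len(side) <= n - 2:
                splits.append(frozenset(side))
        dl, depl = build(left)
        dr, depr = build(right)
        bl = float(rng.uniform(0.2, 1.0))
        br = float(rng.uniform(0.2, 1.0))
        dep = {x: v + bl for x, v in depl.items()}
        dep.update({x: v + br for x, v in depr.items()})
        dd = dict(dl)
        dd.update(dr)
        for x in depl:
            for y in depr:
                dd[(x, y)] = dd[(y, x)] = depl[x] + bl + depr[y] + br
        return dd, dep

    order = list(ids)
    rng.shuffle(order)
    dd, _ = build(order)
    return splits, dd


def test_additive_distances_recover_topology():
    # classical NJ consistency: on additive matrices the generating splits
    # come back exactly
    rng = np.random.default_rng(42)
    for trial in range(15):
        n = int(rng.integers(4, 9))
        ids = [f"t{i}" for i in range(n)]
        splits, dd = random_additive_distances(rng, ids)
        mat = np.array([[dd.get((a, b), 0.0) for b in ids] for a in ids])
        tree = nj(DistanceMatrix(mat, ids))
        all_leaves = frozenset(ids)
        got = set()
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= n - 2:
                got.add(min(side, all_leaves - side, key=sorted))
        want = {min(s, all_leaves - s, key=sorted) for s in splits}
        assert want <= got


def test_nj_requires_four_sequences():
    with pytest.raises(ValueError):
        nj_tree({"a": "ACGT", "b": "ACGT", "c": "ACGT"})


def test_identical_pair_forms_zero_length_cherry():
    seqs = {
        "a": "ACGTACGTACGTACGTACGT",
        "b": "ACGTACGTACGTACGTACGT",
        "c": "TTTTACGTACGTACGTACGA",
        "d": "TTTTTTTTACGTACGTCCGA",
    }
    tree = nj_tree(seqs)
    ta = tree.find("a")
    tb = tree.find("b")
    assert ta.length == 0.0 and tb.length == 0.0
    assert ta.parent is tb.parent


def test_jc_distance_requires_equal_lengths():
    with pytest.raises(ValueError):
        jc_distance_matrix({"a": "ACGT", "b": "ACGTA"})


def test_bootstrap_support_deterministic_and_bounded():
    cfg = SimConfig(seed=6, n_families=2, genes_per_family=4)
    genes, _, _ = simulate_family_set(cfg)
    s1 = bootstrap_support(genes, 25, seed=3)
    s2 = bootstrap_support(genes, 25, seed=3)
    assert s1.supports == s2.supports
    assert all(0.0 <= v <= 100.0 for v in s1.supports.values())
    one = bootstrap_support(genes, 1, seed=3)
    assert set(one.supports.values()) <= {0.0, 100.0}


def test_separated_clusters_get_high_support():
    # two tight clusters, highly diverged between: the between-cluster
    # bipartition should be near-certain
    cfg = SimConfig(seed=8, n_families=2, genes_per_family=4)
    genes, _, truth = simulate_family_set(cfg)
    sup = bootstrap_support(genes, 100, seed=1)
    fams = {}
    for g, f in truth.gene_family.items():
        fams.setdefault(f, set()).add(g)
    for members in fams.values():
        key = frozenset(members)
        if key in sup.supports:
            assert sup.supports[key] >= 95.0


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def test_read_newick_supports(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((a:1,b:1)90:1,(c:1,d:1)40:1);\n")
    sup = read_newick(p)
    assert sup.supports[frozenset({"a", "b"})] == 90.0
    assert sup.supports[frozenset({"c", "d"})] == 40.0


def test_read_newick_scales_fractional_supports(tmp_path, caplog):
    p = tmp_path / "t.nwk"
    p.write_text("((a:1,b:1)0.9:1,(c:1,d:1)0.4:1);\n")
    with caplog.at_level("WARNING"):
        sup = read_newick(p)
    assert sup.supports[frozenset({"a", "b"})] == 90.0


def test_read_newick_parse_error(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((a:1,b:1)90:1,(c:1,d:1)40:1;\n")
    with pytest.raises(Exception):
        read_newick(p)


def test_newick_round_trip(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((a:1.5,b:2.5)90:1,(c:1,d:1)40:2);\n")
    sup = read_newick(p)
    text = write_newick(sup)
    p2 = tmp_path / "t2.nwk"
    p2.write_text(text)
    sup2 = read_newick(p2)
    assert sup.supports == sup2.supports
    t1 = {frozenset(t.name for t in n.tips()) for n in sup.tree.non_tips(include_self=False)}
    t2 = {frozenset(t.name for t in n.tips()) for n in sup2.tree.non_tips(include_self=False)}
    assert t1 == t2
    for name in "abcd":
        assert sup.tree.find(name).length == pytest.approx(sup2.tree.find(name).length, abs=1e-9)


# ---------------------------------------------------------------------------
# clade calling
# ---------------------------------------------------------------------------

def _manual_tree(newick, supports, tmp_path):
    p = tmp_path / "m.nwk"
    p.write_text(newick)
    sup = read_newick(p)
    if supports:
        sup.supports.update(supports)
    return sup


def test_single_species_supported_clade_called(tmp_path):
    sup = _manual_tree("(((X|1:1,X|2:1)90:1,X|3:1)90:2,(Y|1:1,Y|2:3)90:1);", {}, tmp_path)
    calls = classify_clades(sup)
    by_type = {c.call: c for c in calls}
    ss = [c for c in calls if c.call == "species_specific"]
    assert {frozenset(c.genes) for c in ss} == {
        frozenset({"X|1", "X|2", "X|3"}),
        frozenset({"Y|1", "Y|2"}),
    }
    assert all(c.n_genes >= 2 for c in calls)


def test_mixed_clade_with_duplication_is_lineage_specific(tmp_path):
    sup = _manual_tree("((X|1:1,(X|2:1,Y|1:1)60:1)80:1,(Z|1:1,W|1:1)90:1);", {}, tmp_path)
    calls = classify_clades(sup)
    assert len(calls) == 1
    c = calls[0]
    assert c.call == "lineage_specific"
    assert c.species_set == frozenset({"X", "Y"})
    assert c.n_genes == 3


def test_pure_speciation_clade_not_called(tmp_path):
    # {X1, Y1} has support but no within-species pair: speciation, not
    # duplication; nothing in this tree qualifies
    sup = _manual_tree("((X|1:1,Y|1:1)95:1,(Z|1:1,W|1:1)95:1);", {}, tmp_path)
    assert classify_clades(sup) == []


def test_leaf_only_tree_yields_no_calls(tmp_path):
    sup = _manual_tree("(X|a:1,Y|b:1);", {}, tmp_path)
    assert classify_clades(sup) == []


def test_maximality_no_gene_in_two_calls(tmp_path):
    sup = _manual_tree(
        "(((X|1:1,X|2:1)99:1,(X|3:1,X|4:1)99:1)99:1,(Y|1:1,Y|2:1)99:1);", {}, tmp_path
    )
    calls = classify_clades(sup)
    seen = []
    for c in calls:
        seen.extend(c.genes)
    assert len(seen) == len(set(seen))
    # the maximal X clade absorbs its two supported sub-cherries
    assert frozenset({"X|1", "X|2", "X|3", "X|4"}) in {frozenset(c.genes) for c in calls}


def test_support_threshold_monotonicity(tmp_path):
    sup = _manual_tree(
        "(((X|1:1,X|2:1)55:1,X|3:1)45:1,((Y|1:1,Y|2:1)75:1,Z|1:1)65:1);", {}, tmp_path
    )
    prev = None
    for thr in (40, 50, 60, 70, 80):
        n = len(classify_clades(sup, min_support=thr))
        if prev is not None:
            assert n <= prev
        prev = n


def test_duplication_proportions_printed_style():
    calls = []
    assert duplication_proportions(calls, 435)["species_specific"]["percent"] == 0.0
    with pytest.raises(ValueError):
        duplication_proportions(calls, 0)
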