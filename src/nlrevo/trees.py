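"""Neighbor-joining trees with bootstrap supports and duplicated-clade calls.

Trees are built by neighbor joining on Jukes–Cantor-corrected nucleotide
distances (pairwise deletion), supports by column-resampling bootstrap
(support = percentage of replicate trees containing the bipartition).
External trees with supports on internal nodes can be read from Newick.

A supported clade (bootstrap > 50 by default, >= 2 genes) is called
*species-specific* when all its genes come from one species, and
*lineage-specific* when it spans two or more species AND contains a
within-species gene pair (a two-species clade with one gene per species
evidences speciation, not duplication, and is not called).  Calls are
maximal: descendants of a called clade are not re-called, so every gene
is counted in at most one clade.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from ._common import percent, seq_to_ints

logger = logging.getLogger(__name__)

__all__ = [
    "SupportedTree",
    "CladeCall",
    "jc_distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "classify_clades",
    "duplication_proportions",
    "read_newick",
    "write_newick",
]

#: JC distance assigned to saturated pairs (p >= 3/4); far beyond any
#: resolvable divergence, keeps the matrix finite
SATURATION_DISTANCE = 5.0


@dataclass
class SupportedTree:
    """A rooted tree whose internal nodes carry bootstrap supports.

    Supports live in ``supports`` keyed by each internal node's leaf-name
    frozenset; the root (and nodes without an estimate) have no entry.
    """

    tree: TreeNode
    supports: dict[frozenset[str], float]

    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]


@dataclass(frozen=True)
class CladeCall:
    clade_id: str
    call: str  # "species_specific" or "lineage_specific"
    species_set: frozenset[str]
    genes: tuple[str, ...]
    support: float

    @property
    def n_genes(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# distances and NJ
# ---------------------------------------------------------------------------

def jc_distance_matrix(seqs: Mapping[str, str]) -> DistanceMatrix:
    """Jukes–Cantor distances over equal-length sequences (pairwise deletion).

    Saturated pairs (p >= 3/4) get :data:`SATURATION_DISTANCE`.
    """
    ids = sorted(seqs)
    lengths = {len(seqs[i]) for i in ids}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    mat = np.stack([seq_to_ints(seqs[i]) for i in ids])
    valid = mat < 4  # non-gap, ACGT only
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            compared = int(both.sum())
            if compared == 0:
                dist = SATURATION_DISTANCE
            else:
                p = float((mat[i][both] != mat[j][both]).mean())
                if p >= 0.75:
                    dist = SATURATION_DISTANCE
                else:
                    dist = -0.75 * np.log1p(-4.0 * p / 3.0)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(d, ids)


def nj_tree(seqs: Mapping[str, str]) -> TreeNode:
    """Neighbor-joining tree (unrooted) with negative branch lengths clamped to 0."""
    if len(seqs) < 4:
        raise ValueError("neighbor joining needs at least 4 sequences")
    tree = nj(jc_distance_matrix(seqs))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def _bipartitions(tree: TreeNode, all_leaves: frozenset[str]) -> set[frozenset[str]]:
    """Canonical non-trivial bipartitions of a tree (side not holding the
    lexicographically first leaf), so rooted and unrooted encodings agree."""
    ref = min(all_leaves)
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        parts.add(side if ref not in side else all_leaves - side)
    return parts


def _clade_sets(rooted: TreeNode) -> dict[frozenset[str], TreeNode]:
    out = {}
    for node in rooted.non_tips(include_self=False):
        out[frozenset(t.name for t in node.tips())] = node
    return out


def bootstrap_support(
    seqs: Mapping[str, str], n_reps: int, seed: int
) -> SupportedTree:
    """NJ tree with column-resampling bootstrap supports, midpoint-rooted.

    Support of an internal node is the percentage of replicate trees (of
    ``n_reps``) containing the node's bipartition.  Deterministic for a
    fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base = nj_tree(seqs)
    all_leaves = frozenset(seqs)
    rng = np.random.default_rng(seed)
    ids = sorted(seqs)
    mat = np.stack([seq_to_ints(seqs[i]) for i in ids])
    n_cols = mat.shape[1]
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        resampled = {ids[k]: "".join("ACGT"[v] for v in mat[k][cols]) for k in range(len(ids))}
        rep_tree = nj_tree(resampled)
        for part in _bipartitions(rep_tree, all_leaves):
            counts[part] = counts.get(part, 0) + 1
    rooted = base.root_at_midpoint()
    ref = min(all_leaves)
    supports: dict[frozenset[str], float] = {}
    for clade, node in _clade_sets(rooted).items():
        if len(clade) < 2 or len(all_leaves - clade) < 2:
            continue  # trivial bipartition: no support estimate
        canon = clade if ref not in clade else all_leaves - clade
        supports[clade] = 100.0 * counts.get(canon, 0) / n_reps
    return SupportedTree(rooted, supports)


# ---------------------------------------------------------------------------
# clade classification
# ---------------------------------------------------------------------------

def _species_of(leaf: str, species_map: Mapping[str, str]) -> str:
    if leaf in species_map:
        return species_map[leaf]
    if "|" in leaf:
        return leaf.split("|", 1)[0]
    raise KeyError(f"leaf {leaf!r} has no species assignment")


def classify_clades(
    sup: SupportedTree,
    species_map: Mapping[str, str] | None = None,
    min_support: float = 50.0,
) -> list[CladeCall]:
    """Maximal supported duplicated clades, labelled by event type.

    Traverses from the root (never itself called); a node is called when
    its support exceeds ``min_support``, it holds >= 2 genes, and it either
    contains genes of exactly one species (species-specific) or spans
    several species with at least one within-species duplicate pair
    (lineage-specific).  Children of called nodes are not revisited.
    """
    species_map = species_map or {}
    tree = sup.tree
    if len(tree.children) > 2:
        logger.info("unrooted input tree: midpoint-rooting before clade calling")
        rooted = tree.root_at_midpoint()
        sup = SupportedTree(rooted, dict(sup.supports))
        tree = rooted
    calls: list[CladeCall] = []

    def visit(node: TreeNode) -> None:
        if node.is_tip():
            return
        leaves = [t.name for t in node.tips()]
        clade = frozenset(leaves)
        support = sup.supports.get(clade)
        if support is not None and support > min_support and len(leaves) >= 2:
            species = [_species_of(g, species_map) for g in leaves]
            uniq = frozenset(species)
            has_dup = len(species) > len(uniq)
            if len(uniq) == 1:
                calls.append(
                    CladeCall(
                        f"clade{len(calls):04d}",
                        "species_specific",
                        uniq,
                        tuple(sorted(leaves)),
                        support,
                    )
                )
                return
            if has_dup:
                calls.append(
                    CladeCall(
                        f"clade{len(calls):04d}",
                        "lineage_specific",
                        uniq,
                        tuple(sorted(leaves)),
                        support,
                    )
                )
                return
        for child in node.children:
            visit(child)

    for child in tree.children:
        visit(child)
    return calls


def duplication_proportions(
    calls: Sequence[CladeCall], class_total: int
) -> dict[str, dict[str, float | int]]:
    """Percent of a gene class involved in each duplication type."""
    if class_total <= 0:
        raise ValueError("class_total must be positive")
    out = {}
    for kind in ("species_specific", "lineage_specific"):
        genes = sum(c.n_genes for c in calls if c.call == kind)
        out[kind] = {
            "genes": genes,
            "clades": sum(1 for c in calls if c.call == kind),
            "total": class_total,
            "percent": percent(genes, class_total),
        }
    return out


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> SupportedTree:
    """Read a Newick tree whose internal-node labels are bootstrap supports.

    Fractional supports (all labels <= 1) are auto-scaled to percent with a
    warning.  Unrooted (trifurcating) trees are midpoint-rooted.
    """
    tree = TreeNode.read(str(path), convert_underscores=False)
    raw: dict[TreeNode, float] = {}
    for node in tree.non_tips(include_self=False):
        if node.name not in (None, ""):
            try:
                raw[node] = float(node.name)
            except ValueError:
                logger.warning("ignoring non-numeric internal label %r", node.name)
    if raw and all(v <= 1.0 for v in raw.values()):
        logger.warning("fractional bootstrap supports detected: scaling by 100")
        raw = {n: v * 100.0 for n, v in raw.items()}
    support_by_clade = {
        frozenset(t.name for t in node.tips()): v for node, v in raw.items()
    }
    if len(tree.children) > 2:
        logger.info("unrooted Newick input: midpoint-rooting")
        tree = tree.root_at_midpoint()
        all_leaves = frozenset(t.name for t in tree.tips())
        ref = min(all_leaves)
        canon_support = {
            (c if ref not in c else all_leaves - c): v for c, v in support_by_clade.items()
        }
        support_by_clade = {}
        for clade in _clade_sets(tree):
            canon = clade if ref not in clade else all_leaves - clade
            if canon in canon_support:
                support_by_clade[clade] = canon_support[canon]
    return SupportedTree(tree, support_by_clade)


def write_newick(sup: SupportedTree, path: str | Path | None = None) -> str:
    """Serialise a supported tree, supports as internal-node labels."""
    tree = sup.tree.copy()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if clade in sup.supports:
            v = sup.supports[clade]
            node.name = f"{v:g}"
    buf = io.StringIO()
    tree.write(buf)
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text
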