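"""Gene-family clustering from pairwise identity and coverage.

TNL and non-TNL genes are clustered separately.  An edge between two genes
is kept at stringency level L in {70, 80, 90} when BOTH its percent
identity and its percent coverage strictly exceed L; families are the
connected components of the kept-edge graph (single linkage), genes with
no kept edge being singletons.  Coverage uses the shorter sequence of the
pair as denominator.  Edges come either from an internal local aligner
(BLASTN-like scoring: match +1, mismatch -2, gap open -5, gap extend -2)
or from a supplied BLAST tabular (outfmt 6) file, best HSP per pair,
reciprocal hits merged keeping the maximum identity and coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio.Align import PairwiseAligner

from ._common import percent, round_half_up

__all__ = [
    "CLUSTER_LEVELS",
    "SimilarityEdge",
    "GeneFamily",
    "BlastTableError",
    "pairwise_similarity",
    "all_vs_all_edges",
    "read_blast_tab",
    "build_families",
    "family_summary",
]

CLUSTER_LEVELS = (70, 80, 90)


@dataclass(frozen=True)
class SimilarityEdge:
    """Undirected pairwise similarity measurement between two genes."""

    query_id: str
    subject_id: str
    identity_pct: float
    coverage_pct: float

    def __post_init__(self) -> None:
        if self.query_id == self.subject_id:
            raise ValueError(f"self edge for {self.query_id!r}")
        for v, name in ((self.identity_pct, "identity"), (self.coverage_pct, "coverage")):
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}_pct {v} outside [0, 100]")

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.query_id, self.subject_id)))  # type: ignore[return-value]


@dataclass(frozen=True)
class GeneFamily:
    family_id: str
    members: frozenset[str]
    subclass_scope: str  # "TNL" or "NON_TNL"
    avg_identity_pct: float  # NaN for singletons (no member-pair edges)

    @property
    def is_multi(self) -> bool:
        return len(self.members) >= 2


class BlastTableError(ValueError):
    """Malformed BLAST tabular input."""


def _nucleotide_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


def pairwise_similarity(
    query_id: str, subject_id: str, cds_a: str, cds_b: str
) -> SimilarityEdge | None:
    """Best local alignment between two sequences as a similarity edge.

    identity = matches / aligned columns (gaps included) x 100; coverage =
    aligned residues of the shorter sequence / its length x 100.  Returns
    None when no positive-scoring local alignment exists.
    """
    if not cds_a or not cds_b:
        raise ValueError("empty sequence")
    aligner = _nucleotide_aligner()
    alignments = aligner.align(cds_a.upper(), cds_b.upper())
    try:
        aln = alignments[0]
    except IndexError:
        return None
    if aln.score <= 0:
        return None
    row_a, row_b = aln[0], aln[1]
    columns = len(row_a)
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    shorter_is_a = len(cds_a) <= len(cds_b)
    aligned_on_shorter = sum(
        1 for c in (row_a if shorter_is_a else row_b) if c != "-"
    )
    shorter_len = min(len(cds_a), len(cds_b))
    return SimilarityEdge(
        query_id,
        subject_id,
        identity_pct=100.0 * matches / columns,
        coverage_pct=100.0 * aligned_on_shorter / shorter_len,
    )


def all_vs_all_edges(cds: Mapping[str, str]) -> list[SimilarityEdge]:
    """Internal all-versus-all similarity over a gene set (no self hits)."""
    ids = sorted(cds)
    edges = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            e = pairwise_similarity(a, b, cds[a], cds[b])
            if e is not None:
                edges.append(e)
    return edges


def read_blast_tab(
    path: str | Path, seq_lengths: Mapping[str, int]
) -> list[SimilarityEdge]:
    """Similarity edges from a 12-column BLAST tabular (outfmt 6) file.

    Self hits are dropped; for each unordered pair the best HSP (highest
    bitscore) per direction is considered and reciprocal hits are merged
    keeping the maximum identity and maximum coverage.  Coverage is the
    HSP alignment length over the shorter sequence's length (from
    ``seq_lengths``), capped at 100%.
    """
    # best HSP (highest bitscore) per direction, then reciprocal directions
    # merged keeping max identity and max coverage
    best: dict[tuple[str, str], tuple[float, float, float]] = {}  # (q,s) -> (bits, ident, cov)
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise BlastTableError(
                    f"{path} line {line_no}: expected 12 tab-separated columns, got {len(fields)}"
                )
            q, s = fields[0], fields[1]
            if q == s:
                continue
            try:
                ident = float(fields[2])
                aln_len = int(fields[3])
                bits = float(fields[11])
            except ValueError as exc:
                raise BlastTableError(f"{path} line {line_no}: malformed numeric field") from exc
            for g in (q, s):
                if g not in seq_lengths:
                    raise BlastTableError(
                        f"{path} line {line_no}: sequence length unknown for {g!r}"
                    )
            shorter = min(seq_lengths[q], seq_lengths[s])
            cov = min(100.0, 100.0 * aln_len / shorter)
            if bits > best.get((q, s), (float("-inf"),))[0]:
                best[(q, s)] = (bits, ident, cov)
    merged: dict[tuple[str, str], tuple[float, float]] = {}
    for (q, s), (_, ident, cov) in best.items():
        key = (q, s) if q < s else (s, q)
        prev = merged.get(key)
        merged[key] = (
            (ident, cov) if prev is None else (max(prev[0], ident), max(prev[1], cov))
        )
    return [
        SimilarityEdge(a, b, identity_pct=i, coverage_pct=c)
        for (a, b), (i, c) in sorted(merged.items())
    ]


def build_families(
    edges: Iterable[SimilarityEdge],
    genes_in_scope: Iterable[str],
    level: int,
    scope: str = "NON_TNL",
) -> list[GeneFamily]:
    """Single-linkage families at one stringency level.

    Edges with identity AND coverage strictly above ``level`` connect
    genes; families are connected components, remaining genes singletons.
    ``avg_identity_pct`` is the mean identity over the family's supplied
    edges (threshold-passing or not) between members; NaN for singletons.
    """
    scope_set = set(genes_in_scope)
    g = nx.Graph()
    g.add_nodes_from(scope_set)
    edge_identity: dict[tuple[str, str], float] = {}
    for e in edges:
        for gid in (e.query_id, e.subject_id):
            if gid not in scope_set:
                raise ValueError(f"edge gene {gid!r} is not in the clustering scope")
        edge_identity[e.key] = max(edge_identity.get(e.key, 0.0), e.identity_pct)
        if e.identity_pct > level and e.coverage_pct > level:
            g.add_edge(e.query_id, e.subject_id)
    families = []
    for i, comp in enumerate(sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])):
        members = frozenset(comp)
        idents = [
            v
            for (a, b), v in edge_identity.items()
            if a in members and b in members
        ]
        avg = sum(idents) / len(idents) if idents else float("nan")
        families.append(
            GeneFamily(f"{scope}_L{level}_f{i:04d}", members, scope, avg)
        )
    return families


def family_summary(
    families_by_level: Mapping[int, Sequence[GeneFamily]],
    species_map: Mapping[str, str],
    species_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per level x scope summary of single/multi gene counts and identities.

    One row per (level, scope, species) plus a "Total" species row per
    (level, scope): single-gene count, multi-gene count, multi-gene
    proportion (%, 2 decimals), and at the Total level the family count
    and mean family average identity (singletons excluded as NA).
    """
    rows = []
    for level in sorted(families_by_level):
        fams = families_by_level[level]
        by_scope: dict[str, list[GeneFamily]] = {}
        for f in fams:
            by_scope.setdefault(f.subclass_scope, []).append(f)
        for scope in sorted(by_scope):
            sfams = by_scope[scope]
            genes = [g for f in sfams for g in f.members]
            if species_order is None:
                order = sorted({species_map[g] for g in genes})
            else:
                order = list(species_order)
            multi_genes = {g for f in sfams if f.is_multi for g in f.members}
            for sp in [*order, "Total"]:
                in_sp = [g for g in genes if sp == "Total" or species_map[g] == sp]
                n_multi = sum(1 for g in in_sp if g in multi_genes)
                n_single = len(in_sp) - n_multi
                row = {
                    "level": level,
                    "scope": scope,
                    "species": sp,
                    "single_genes": n_single,
                    "multi_genes": n_multi,
                    "multi_pct": percent(n_multi, len(in_sp)) if in_sp else float("nan"),
                }
                if sp == "Total":
                    multi_fams = [f for f in sfams if f.is_multi]
                    idents = [
                        f.avg_identity_pct
                        for f in multi_fams
                        if f.avg_identity_pct == f.avg_identity_pct  # not NaN
                    ]
                    row["n_families"] = len(multi_fams)
                    row["mean_family_identity"] = (
                        round_half_up(sum(idents) / len(idents)) if idents else float("nan")
                    )
                rows.append(row)
    return pd.DataFrame(rows)
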