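"""NBS-LRR architecture classification from protein-domain annotations.

A gene is an NBS-LRR (NLR) candidate when it carries at least one NB-ARC
domain and at least one LRR region.  The N-terminal domain then fixes the
subclass: TIR gives TNL; among non-TNLs a coiled-coil (CC) gives CNL'
(RPW8-CNL when RPW8 is also present) and its absence gives XNL' (RPW8-XNL
with RPW8).  "N-terminal" means the qualifying domain starts before the
first NB-ARC hit.  Genes carrying both TIR and CC are classified TNL and
flagged ambiguous for the QC report, TIR being the subgroup-defining
domain.

Coordinates are 1-based inclusive amino-acid positions throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "KNOWN_DOMAINS",
    "DomainHit",
    "NLRClass",
    "DomainTableError",
    "parse_domain_tsv",
    "is_nbs_lrr",
    "classify_architecture",
    "classify_genes",
    "tabulate_classes",
]

KNOWN_DOMAINS = frozenset({"TIR", "CC", "RPW8", "NB-ARC", "LRR", "OTHER"})


class NLRClass(str, Enum):
    """The five architecture subclasses."""

    TNL = "TNL"
    CNL_PRIME = "CNL'"
    RPW8_CNL = "RPW8-CNL"
    XNL_PRIME = "XNL'"
    RPW8_XNL = "RPW8-XNL"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: derived groupings (disjoint unions)
CNL_GROUP = frozenset({NLRClass.CNL_PRIME, NLRClass.RPW8_CNL})
XNL_GROUP = frozenset({NLRClass.XNL_PRIME, NLRClass.RPW8_XNL})
RNL_GROUP = frozenset({NLRClass.RPW8_CNL, NLRClass.RPW8_XNL})
NON_TNL_GROUP = CNL_GROUP | XNL_GROUP


@dataclass(frozen=True)
class DomainHit:
    gene_id: str
    domain: str  # one of KNOWN_DOMAINS
    aa_start: int  # 1-based inclusive
    aa_end: int
    source: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.aa_start <= self.aa_end):
            raise ValueError(
                f"{self.gene_id}: invalid coordinates {self.aa_start}..{self.aa_end}"
            )
        if self.domain not in KNOWN_DOMAINS:
            raise ValueError(f"{self.gene_id}: unknown domain label {self.domain!r}")


class DomainTableError(ValueError):
    """Malformed domain table (missing column or invalid row)."""


_REQUIRED = ("gene_id", "domain", "aa_start", "aa_end")


def parse_domain_tsv(path: str | Path) -> list[DomainHit]:
    """Read a domain table (TSV with header) into hits.

    Requires columns gene_id, domain, aa_start, aa_end; extra columns (as
    emitted by InterProScan-style annotators) are ignored.  Unknown domain
    labels map to OTHER with a warning; a row whose aa_end precedes its
    aa_start raises an error naming the line.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise DomainTableError(f"{path}: missing column(s) {missing}")
    hits: list[DomainHit] = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # header is line 1
        domain = str(row["domain"]).strip()
        if domain not in KNOWN_DOMAINS:
            logger.warning("%s line %d: unknown domain %r mapped to OTHER", path, line_no, domain)
            domain = "OTHER"
        try:
            start, end = int(row["aa_start"]), int(row["aa_end"])
        except (TypeError, ValueError) as exc:
            raise DomainTableError(f"{path} line {line_no}: non-integer coordinates") from exc
        if not (1 <= start <= end):
            raise DomainTableError(
                f"{path} line {line_no}: aa_end {end} precedes aa_start {start}"
            )
        hits.append(
            DomainHit(str(row["gene_id"]), domain, start, end, str(row.get("source", "") or ""))
        )
    return hits


def is_nbs_lrr(hits_for_gene: Iterable[DomainHit]) -> bool:
    """True iff the gene has at least one NB-ARC hit and at least one LRR hit."""
    domains = {h.domain for h in hits_for_gene}
    return "NB-ARC" in domains and "LRR" in domains


def classify_architecture(
    hits_for_gene: Sequence[DomainHit],
) -> tuple[NLRClass, bool]:
    """Subclass of one NBS-LRR gene from its hits; returns (class, ambiguous).

    The qualifying N-terminal domain must start before the first NB-ARC hit
    (smallest aa_start among NB-ARC hits).  ``ambiguous`` is True when both
    TIR and CC qualify — the gene is still TNL but belongs in the QC report.
    """
    if not is_nbs_lrr(hits_for_gene):
        raise ValueError("classify_architecture requires an NBS-LRR gene (NB-ARC + LRR)")
    nbarc_start = min(h.aa_start for h in hits_for_gene if h.domain == "NB-ARC")

    def n_terminal(domain: str) -> bool:
        return any(
            h.domain == domain and h.aa_start < nbarc_start for h in hits_for_gene
        )

    tir, cc, rpw8 = n_terminal("TIR"), n_terminal("CC"), n_terminal("RPW8")
    if tir:
        return NLRClass.TNL, cc
    if cc and rpw8:
        return NLRClass.RPW8_CNL, False
    if cc:
        return NLRClass.CNL_PRIME, False
    if rpw8:
        return NLRClass.RPW8_XNL, False
    return NLRClass.XNL_PRIME, False


def classify_genes(
    hits: Iterable[DomainHit], species_map: Mapping[str, str]
) -> pd.DataFrame:
    """Per-gene classification table for all genes passing the NBS-LRR rule.

    Columns: gene_id, species, nlr_class, ambiguous.  Genes lacking NB-ARC
    or LRR are silently excluded (they are not NBS-LRR candidates).
    """
    by_gene: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, []).append(h)
    rows = []
    for gid in sorted(by_gene):
        if not is_nbs_lrr(by_gene[gid]):
            continue
        if gid not in species_map:
            raise KeyError(f"gene {gid!r} has no species assignment")
        cls, ambiguous = classify_architecture(by_gene[gid])
        rows.append(
            {
                "gene_id": gid,
                "species": species_map[gid],
                "nlr_class": cls.value,
                "ambiguous": ambiguous,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "species", "nlr_class", "ambiguous"])


def tabulate_classes(
    classified: pd.DataFrame, species_order: Sequence[str] | None = None
) -> pd.DataFrame:
    """Species x subclass count table with derived groupings and totals.

    Rows: NBS-LRR (total), TNL, Non-TNL, CNL, CNL', RPW8-CNL, XNL, XNL',
    RPW8-XNL.  Columns: one per species plus "Total".  Per species,
    TNL + Non-TNL equals the NBS-LRR total.
    """
    if species_order is None:
        species_order = sorted(classified["species"].unique()) if len(classified) else []
    counts = pd.DataFrame(0, index=list(species_order), columns=[c.value for c in NLRClass])
    for _, row in classified.iterrows():
        if row["species"] not in counts.index:
            raise KeyError(f"gene {row['gene_id']!r}: unknown species {row['species']!r}")
        counts.loc[row["species"], row["nlr_class"]] += 1

    def group(cols: Iterable[NLRClass]) -> pd.Series:
        return counts[[c.value for c in cols]].sum(axis=1)

    table = pd.DataFrame(
        {
            "NBS-LRR": counts.sum(axis=1),
            "TNL": counts[NLRClass.TNL.value],
            "Non-TNL": group(NON_TNL_GROUP),
            "CNL": group(CNL_GROUP),
            "CNL'": counts[NLRClass.CNL_PRIME.value],
            "RPW8-CNL": counts[NLRClass.RPW8_CNL.value],
            "XNL": group(XNL_GROUP),
            "XNL'": counts[NLRClass.XNL_PRIME.value],
            "RPW8-XNL": counts[NLRClass.RPW8_XNL.value],
        }
    ).T
    table["Total"] = table.sum(axis=1)
    table.index.name = "letter_code"
    return table
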