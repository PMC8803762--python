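"""Synthetic data with known ground truth for the NBS-LRR analysis pipeline.

Three generators cover everything the downstream stages consume:

``simulate_diverged_pair``
    A pair of coding sequences diverged from a common ancestor to a
    controlled synonymous rate (Ks) and Ka/Ks ratio (omega).  Divergence is
    produced by a proposal/acceptance process: random single-nucleotide
    changes are proposed across the two copies and accepted while the
    synonymous or nonsynonymous event budget remains, rejecting any change
    that would create a stop codon.  Budgets are event counts per site
    (Ks · synonymous sites, Ka · nonsynonymous sites), so multiple hits can
    land on one site and the estimator's Jukes–Cantor correction is what
    recovers the target on average.

``simulate_family_set``
    A multi-species gene set organised into families, each carrying one
    planted duplication event: *species-specific* families hold recent
    duplicates (low pairwise Ks) of a single species; *lineage-specific*
    families hold two anciently duplicated lineages (high Ks) each carried
    by two or more species.  Every gene also gets an unambiguous domain
    table assigning one of the five NBS-LRR architectures (TNL, CNL',
    RPW8-CNL, XNL', RPW8-XNL).

``simulate_expression``
    A two-genotype ("resistant" / "susceptible") time-course FPKM matrix
    over hours 0–72 with planted differentially expressed genes: in the
    resistant genotype planted genes rise monotonically to a late plateau
    (24–72 h); in the susceptible genotype they follow a waved profile.
    A companion logFC/p/FDR table makes exactly the planted set pass the
    |logFC| >= 2, p < 0.05, FDR < 0.05 screen.

All generators draw from named sub-streams of one root seed, so outputs are
byte-identical for a fixed config and adding a generator does not perturb
the others.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._common import (
    CODON_AA,
    NUCLEOTIDES,
    SENSE_CODONS,
    child_rng,
    validate_cds,
)
from .rates import pathway_differences, syn_site_fraction

__all__ = [
    "SimConfig",
    "SimTruth",
    "DEFAULT_SPECIES",
    "simulate_diverged_pair",
    "simulate_family_set",
    "simulate_expression",
    "random_cds",
    "records_to_fasta",
    "domain_rows_to_tsv",
]

#: six peach-relative species tags used by default (ids are "<species>|<gene>")
DEFAULT_SPECIES = (
    "Pyedoensis",
    "Pdomestica",
    "Pavium",
    "Pdulcis",
    "Ppersica",
    "Pnudiflora",
)

ARCHITECTURES = ("TNL", "CNL_PRIME", "RPW8_CNL", "XNL_PRIME", "RPW8_XNL")


@dataclass
class SimConfig:
    """Study conditions for the simulators.

    Defaults mirror the structure of the six-genome NBS-LRR survey this
    package models: six species, the two Ks divergence peaks (recent ~0.15
    and ancient ~0.6), mostly purifying selection (omega 0.25), eight
    infection time points, and 48 planted DEGs among 318 expression genes.
    """

    seed: int = 0
    n_species: int = 6
    n_families: int = 6
    genes_per_family: int = 4
    codons_per_gene: int = 300
    target_ks: tuple[float, ...] = (0.15, 0.6)
    omega: tuple[float, ...] = (0.25, 0.25)
    event_types: tuple[str, ...] = ("species_specific", "lineage_specific")
    timepoints_h: tuple[int, ...] = (0, 3, 6, 9, 12, 24, 48, 72)
    n_deg: int = 48
    n_expr_genes: int = 318

    def __post_init__(self) -> None:
        if self.codons_per_gene < 50:
            raise ValueError("codons_per_gene must be >= 50")
        if any(k < 0 for k in self.target_ks):
            raise ValueError("target_ks entries must be >= 0")
        if any(w < 0 for w in self.omega):
            raise ValueError("omega entries must be >= 0")
        if len(self.omega) != len(self.target_ks):
            raise ValueError("omega must have one entry per target_ks event")
        unknown = set(self.event_types) - {"species_specific", "lineage_specific"}
        if unknown:
            raise ValueError(f"unknown event types: {sorted(unknown)}")
        if not (1 <= self.n_species <= len(DEFAULT_SPECIES)):
            raise ValueError(f"n_species must be in 1..{len(DEFAULT_SPECIES)}")
        if self.n_deg > self.n_expr_genes:
            raise ValueError("n_deg cannot exceed n_expr_genes")
        if not self.timepoints_h:
            raise ValueError("timepoints_h must be non-empty")


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated data."""

    pair_rates: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    #: family_id -> (event label, species set)
    clade_events: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)
    gene_subclass: dict[str, str] = field(default_factory=dict)
    gene_family: dict[str, str] = field(default_factory=dict)
    gene_species: dict[str, str] = field(default_factory=dict)
    deg_genes: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# coding-sequence divergence
# ---------------------------------------------------------------------------

def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random coding sequence: ATG start then random sense codons."""
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 1)
    return "ATG" + "".join(SENSE_CODONS[i] for i in body)


def _jc(p: float) -> float:
    if p >= 0.75:
        return float("inf")
    return -0.75 * float(np.log1p(-4.0 * p / 3.0)) if p > 0 else 0.0


class _DivergenceTracker:
    """Incremental NG86 bookkeeping between two codon lists.

    Keeps running synonymous/nonsynonymous site and difference totals so a
    proposal loop can steer the realized (JC-corrected) Ks and Ka directly
    onto their targets, updating only the touched codon per accepted event.
    """

    def __init__(self, codons_a: list[str], codons_b: list[str]):
        self.seqs = [codons_a, codons_b]
        self.s_sites = [
            sum(syn_site_fraction(c) for c in codons_a),
            sum(syn_site_fraction(c) for c in codons_b),
        ]
        self.sd = 0.0
        self.nd = 0.0
        self._col_diffs = [
            pathway_differences(ca, cb) for ca, cb in zip(codons_a, codons_b)
        ]
        for sdd, ndd in self._col_diffs:
            self.sd += sdd
            self.nd += ndd
        self.n_codons = len(codons_a)

    def apply(self, which: int, ci: int, alt: str) -> None:
        old = self.seqs[which][ci]
        self.s_sites[which] += syn_site_fraction(alt) - syn_site_fraction(old)
        self.seqs[which][ci] = alt
        new_diffs = pathway_differences(self.seqs[0][ci], self.seqs[1][ci])
        old_diffs = self._col_diffs[ci]
        self.sd += new_diffs[0] - old_diffs[0]
        self.nd += new_diffs[1] - old_diffs[1]
        self._col_diffs[ci] = new_diffs

    @property
    def realized(self) -> tuple[float, float]:
        """(ks, ka) as the NG86+JC estimator would measure them now."""
        s = (self.s_sites[0] + self.s_sites[1]) / 2.0
        n = 3.0 * self.n_codons - s
        ks = _jc(self.sd / s) if s > 0 else 0.0
        ka = _jc(self.nd / n) if n > 0 else 0.0
        return ks, ka


def _mutate_to_target(
    codons_a: list[str],
    codons_b: list[str],
    mutable: tuple[int, ...],
    target_ks: float,
    target_ka: float,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Propose/accept point mutations until realized Ks and Ka reach targets.

    A proposal is accepted when it does not create a stop codon and the
    realized statistic of its class (synonymous or nonsynonymous, judged
    against the codon being edited) is still below target.  Returns the
    realized (ks, ka).
    """
    tracker = _DivergenceTracker(codons_a, codons_b)
    n_codons = tracker.n_codons
    eps = 1e-12

    def drive(synonymous_phase: bool, target: float, other_target: float) -> None:
        # events of one class leak into the other class's difference count
        # through NG86 pathway averaging, so each class is driven in its own
        # phase and any event pushing the other statistic past its own
        # target is rolled back
        guard = 3000 * (n_codons + 30)
        while guard > 0:
            ks, ka = tracker.realized
            if (ks if synonymous_phase else ka) >= target - eps:
                break
            guard -= 1
            which = mutable[rng.integers(len(mutable))]
            ci = int(rng.integers(n_codons))
            pos = int(rng.integers(3))
            codon = tracker.seqs[which][ci]
            nt = NUCLEOTIDES[rng.integers(4)]
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if CODON_AA[alt] == "*":
                continue
            if (CODON_AA[alt] == CODON_AA[codon]) != synonymous_phase:
                continue
            other_before = ka if synonymous_phase else ks
            tracker.apply(which, ci, alt)
            ks2, ka2 = tracker.realized
            other_after = ka2 if synonymous_phase else ks2
            if other_after > other_target + eps and other_after > other_before:
                tracker.apply(which, ci, codon)  # roll back

    # Ka first (it perturbs Ks the most), then Ks, then one touch-up round
    drive(False, target_ka, target_ks)
    drive(True, target_ks, target_ka)
    drive(False, target_ka, target_ks)
    drive(True, target_ks, target_ka)
    return tracker.realized


def simulate_diverged_pair(
    ancestor_cds: str,
    target_ks: float,
    omega: float,
    seed: int | np.random.Generator,
) -> tuple[str, str, SimTruth]:
    """Diverge two copies of an ancestor to a target Ks and omega.

    Returns (cds_a, cds_b, truth); truth records the realized per-site
    synonymous and nonsynonymous event rates for the pair (a, b).
    """
    anc = validate_cds(ancestor_cds, "ancestor")
    if target_ks < 0:
        raise ValueError("target_ks must be >= 0")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codons = [anc[i : i + 3] for i in range(0, len(anc), 3)]
    ca, cb = list(codons), list(codons)
    real_ks, real_ka = _mutate_to_target(
        ca, cb, (0, 1), target_ks, omega * target_ks, rng
    )
    truth = SimTruth()
    truth.pair_rates[("a", "b")] = (real_ks, real_ka)
    return "".join(ca), "".join(cb), truth


# ---------------------------------------------------------------------------
# family sets with planted duplication events
# ---------------------------------------------------------------------------

def _domain_rows(gene_id: str, subclass: str, aa_len: int) -> list[dict]:
    """Unambiguous domain architecture for one gene (1-based aa coordinates)."""
    nbarc_start = max(120, aa_len // 2 - 40)
    lrr_start = min(aa_len - 20, nbarc_start + 120)
    rows = []
    if subclass == "TNL":
        rows.append(("TIR", 5, min(110, nbarc_start - 10)))
    elif subclass == "CNL_PRIME":
        rows.append(("CC", 5, 60))
    elif subclass == "RPW8_CNL":
        rows.append(("RPW8", 5, 50))
        rows.append(("CC", 60, 110))
    elif subclass == "RPW8_XNL":
        rows.append(("RPW8", 5, 50))
    rows.append(("NB-ARC", nbarc_start, lrr_start - 10))
    rows.append(("LRR", lrr_start, aa_len - 5))
    return [
        {"gene_id": gene_id, "domain": d, "aa_start": s, "aa_end": e, "source": "sim"}
        for d, s, e in rows
    ]


def _diverge_copy(
    ancestor_codons: list[str], target_ks: float, omega: float, rng: np.random.Generator
) -> list[str]:
    """One descendant of an ancestor, diverged by target_ks along its own branch.

    The ancestor stays fixed; only the copy accumulates mutations, so the
    realized divergence is measured copy-vs-ancestor.
    """
    copy = list(ancestor_codons)
    _mutate_to_target(
        list(ancestor_codons), copy, (1,), target_ks, omega * target_ks, rng
    )
    return copy


def simulate_family_set(
    config: SimConfig,
) -> tuple[dict[str, str], list[dict], SimTruth]:
    """Families of duplicated genes across species, with domains and truth.

    Returns (cds by gene id, domain-table rows, truth).  Gene ids follow
    ``<species>|<gene>``.  Family event types cycle through
    ``config.event_types``; within-event Ks is drawn from [0.05, 0.3] for
    species-specific and [0.5, 0.9] for lineage-specific events (event
    timing is encoded purely through Ks magnitude).
    """
    rng = child_rng(config.seed, "family_set")
    species = DEFAULT_SPECIES[: config.n_species]
    genes: dict[str, str] = {}
    domain_rows: list[dict] = []
    truth = SimTruth()
    orth_ks = 0.02  # small post-speciation drift for ortholog copies

    for fi in range(config.n_families):
        fam_id = f"fam{fi:03d}"
        event = config.event_types[fi % len(config.event_types)]
        subclass = ARCHITECTURES[fi % len(ARCHITECTURES)]
        ei = fi % len(config.target_ks)
        omega = config.omega[ei]
        anc = [random_cds(rng, config.codons_per_gene)[i : i + 3]
               for i in range(0, 3 * config.codons_per_gene, 3)]

        members: list[tuple[str, str]] = []  # (gene_id, cds)
        if event == "species_specific":
            sp = species[fi % len(species)]
            ks_event = float(rng.uniform(0.05, 0.3))
            n = max(2, config.genes_per_family)
            for gi in range(n):
                cds = "".join(_diverge_copy(anc, ks_event / 2.0, omega, rng))
                members.append((f"{sp}|{fam_id}_g{gi}", cds))
            truth.clade_events[fam_id] = (event, frozenset({sp}))
        else:  # lineage_specific: ancient duplication carried by >= 2 species
            if len(species) < 2:
                raise ValueError("lineage_specific events need n_species >= 2")
            sp_a = species[fi % len(species)]
            sp_b = species[(fi + 1) % len(species)]
            ks_event = float(rng.uniform(0.5, 0.9))
            n_lineages = max(2, config.genes_per_family // 2)
            for li in range(n_lineages):
                lineage = _diverge_copy(anc, ks_event / 2.0, omega, rng)
                for sp in (sp_a, sp_b):
                    cds = "".join(_diverge_copy(lineage, orth_ks, omega, rng))
                    members.append((f"{sp}|{fam_id}_L{li}", cds))
            truth.clade_events[fam_id] = (event, frozenset({sp_a, sp_b}))

        for gid, cds in members:
            genes[gid] = cds
            sp = gid.split("|", 1)[0]
            truth.gene_family[gid] = fam_id
            truth.gene_species[gid] = sp
            truth.gene_subclass[gid] = subclass
            domain_rows.extend(_domain_rows(gid, subclass, config.codons_per_gene))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                gi, gj = members[i][0], members[j][0]
                if event == "lineage_specific":
                    same_lineage = gi.rsplit("_", 1)[1] == gj.rsplit("_", 1)[1]
                    ks_pair = 2 * orth_ks if same_lineage else ks_event + 2 * orth_ks
                else:
                    ks_pair = ks_event
                truth.pair_rates[(gi, gj)] = (ks_pair, omega * ks_pair)
    return genes, domain_rows, truth


# ---------------------------------------------------------------------------
# expression time courses
# ---------------------------------------------------------------------------

def _resistant_ramp(t: float) -> float:
    """Monotone rise to a late plateau (log2 units)."""
    if t <= 12:
        return 0.04 * t  # shallow early drift, max 0.48 at 12 h
    if t <= 24:
        return 3.5
    if t <= 48:
        return 3.9
    return 4.0


def _susceptible_wave(t: float, phase: float) -> float:
    """Waved profile: oscillation with no sustained late plateau."""
    return 1.5 * np.sin(2.0 * np.pi * (t / 24.0) + phase)


def simulate_expression(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """FPKM matrix, DEG summary table and truth for a two-genotype time course.

    The FPKM frame is genes x samples with sample ids
    ``<genotype>_<t>h``; the DEG frame has columns gene_id, logFC, p, FDR.
    Exactly the planted DEGs satisfy |logFC| >= 2, p < 0.05 and FDR < 0.05.
    """
    rng = child_rng(config.seed, "expression")
    n = config.n_expr_genes
    gene_ids = [f"Ppersica|expr_g{i:04d}" for i in range(n)]
    deg_idx = rng.choice(n, size=config.n_deg, replace=False)
    deg_set = {gene_ids[i] for i in sorted(deg_idx)}

    base = rng.normal(4.0, 1.5, size=n)
    phases = rng.uniform(0, 2 * np.pi, size=n)
    cols: dict[str, np.ndarray] = {}
    for genotype in ("resistant", "susceptible"):
        for t in config.timepoints_h:
            log2v = base + rng.normal(0.0, 0.15, size=n)
            for i in range(n):
                if gene_ids[i] in deg_set:
                    if genotype == "resistant":
                        log2v[i] += _resistant_ramp(t)
                    else:
                        log2v[i] += _susceptible_wave(t, phases[i])
            cols[f"{genotype}_{t}h"] = np.maximum(np.exp2(log2v) - 1.0, 0.0)
    fpkm = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))

    logfc = np.empty(n)
    pval = np.empty(n)
    fdr = np.empty(n)
    for i in range(n):
        if gene_ids[i] in deg_set:
            logfc[i] = rng.choice([-1.0, 1.0]) * rng.uniform(2.0, 6.0)
            pval[i] = 10.0 ** rng.uniform(-8.0, -3.0)
            fdr[i] = min(pval[i] * 5.0, 0.049)
        else:
            # non-DEGs fail at least one criterion; some fail only one of the
            # three so the conjunction is actually exercised
            mode = rng.integers(3)
            if mode == 0:
                logfc[i] = rng.uniform(-1.9, 1.9)
                pval[i] = rng.uniform(0.06, 1.0)
                fdr[i] = rng.uniform(0.1, 1.0)
            elif mode == 1:  # big fold change, insignificant
                logfc[i] = rng.choice([-1.0, 1.0]) * rng.uniform(2.0, 4.0)
                pval[i] = rng.uniform(0.06, 1.0)
                fdr[i] = rng.uniform(0.1, 1.0)
            else:  # significant p but weak fold change
                logfc[i] = rng.uniform(-1.9, 1.9)
                pval[i] = rng.uniform(1e-4, 0.04)
                fdr[i] = rng.uniform(0.001, 0.04)
    deg_table = pd.DataFrame(
        {"gene_id": gene_ids, "logFC": logfc, "p": pval, "FDR": fdr}
    )
    truth = SimTruth(deg_genes=deg_set)
    for g in gene_ids:
        truth.gene_species[g] = "Ppersica"
    return fpkm, deg_table, truth


# ---------------------------------------------------------------------------
# serialisation helpers (plain-text interchange)
# ---------------------------------------------------------------------------

def records_to_fasta(genes: Mapping[str, str]) -> str:
    """FASTA text, one record per gene, ids as given, 70-column wrap."""
    out = io.StringIO()
    for gid in genes:
        out.write(f">{gid}\n")
        seq = genes[gid]
        for i in range(0, len(seq), 70):
            out.write(seq[i : i + 70] + "\n")
    return out.getvalue()


def domain_rows_to_tsv(rows: list[dict]) -> str:
    """Domain table text with the canonical column order."""
    header = "gene_id\tdomain\taa_start\taa_end\tsource"
    lines = [header]
    for r in rows:
        lines.append(
            f"{r['gene_id']}\t{r['domain']}\t{r['aa_start']}\t{r['aa_end']}\t{r.get('source', '')}"
        )
    return "\n".join(lines) + "\n"
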