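"""End-to-end orchestration: simulate/ingest, classify, cluster, rates,
trees/clades, expression — with a checksum manifest and a rendered summary.

Outputs are plain text with fixed decimal formatting and LF line endings so
manifests are byte-stable across runs and platforms for a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._common import sha256_text
from . import domains, expression, families, rates, simulate, trees

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "render_summary"]

STAGES = ("classify", "cluster", "rates", "clades", "expression")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    With no input paths the synthetic generators provide the data (their
    conditions are fixed by :class:`~nlrevo.simulate.SimConfig`).
    """

    out_dir: str = "nlrevo_out"
    seed: int = 0
    fasta: str | None = None
    domains_tsv: str | None = None
    blast_tsv: str | None = None
    newick: str | None = None
    fpkm_tsv: str | None = None
    deg_tsv: str | None = None
    levels: tuple[int, ...] = families.CLUSTER_LEVELS
    max_ks: float = rates.KS_FILTER_MAX
    min_support: float = 50.0
    bootstrap_reps: int = 100
    mu: float = 9.48e-9
    gen_years: float = 3.0
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)

    def validate(self) -> None:
        for name in ("fasta", "domains_tsv", "blast_tsv", "newick", "fpkm_tsv", "deg_tsv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config.{name}: no such file {p!r}")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["sim"] = asdict(self.sim)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        sim = d.pop("sim", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})
        if sim is not None:
            cfg.sim = simulate.SimConfig(
                **{k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()}
            )
        return cfg


def _write(path: Path, text: str) -> str:
    path.write_text(text)
    return sha256_text(text)


def _df_tsv(df: pd.DataFrame, path: Path, float_fmt: str = "%.6f") -> str:
    text = df.to_csv(sep="\t", index=False, float_format=float_fmt, lineterminator="\n")
    return _write(path, text)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "checksums": {}}
    sim_cfg = simulate.SimConfig(**{**asdict(config.sim), "seed": config.seed})

    # ---- inputs: load or simulate --------------------------------------
    if config.fasta:
        from Bio import SeqIO

        cds = {r.id: str(r.seq).upper() for r in SeqIO.parse(config.fasta, "fasta")}
        hits = domains.parse_domain_tsv(config.domains_tsv) if config.domains_tsv else []
    else:
        cds, domain_rows, _truth = simulate.simulate_family_set(sim_cfg)
        _write(out / "genes.fasta", simulate.records_to_fasta(cds))
        _write(out / "domains.tsv", simulate.domain_rows_to_tsv(domain_rows))
        hits = domains.parse_domain_tsv(out / "domains.tsv")
    species_map = {g: g.split("|", 1)[0] for g in cds}

    # ---- stage 1: classify ---------------------------------------------
    classified = domains.classify_genes(hits, species_map)
    table1 = domains.tabulate_classes(classified)
    manifest["checksums"]["classification.tsv"] = _df_tsv(classified, out / "classification.tsv")
    manifest["checksums"]["class_counts.tsv"] = _write(
        out / "class_counts.tsv",
        table1.to_csv(sep="\t", lineterminator="\n"),
    )
    manifest["stages"]["classify"] = {"genes_in": len(cds), "nbs_lrr": len(classified)}

    # ---- stage 2: cluster ----------------------------------------------
    tnl_ids = set(classified.loc[classified["nlr_class"] == "TNL", "gene_id"])
    scopes = {
        "TNL": {g: cds[g] for g in tnl_ids},
        "NON_TNL": {g: cds[g] for g in classified["gene_id"] if g not in tnl_ids},
    }
    fams_by_level: dict[int, list[families.GeneFamily]] = {lv: [] for lv in config.levels}
    membership_rows = []
    seq_lengths = {g: len(s) for g, s in cds.items()}
    for scope, scoped_cds in scopes.items():
        if config.blast_tsv:
            edges = [
                e
                for e in families.read_blast_tab(config.blast_tsv, seq_lengths)
                if e.query_id in scoped_cds and e.subject_id in scoped_cds
            ]
        else:
            edges = families.all_vs_all_edges(scoped_cds)
        for level in config.levels:
            fams = families.build_families(edges, scoped_cds, level, scope)
            fams_by_level[level].extend(fams)
            for f in fams:
                for g in sorted(f.members):
                    membership_rows.append(
                        {"gene_id": g, "family_id": f.family_id, "level": level, "scope": scope}
                    )
    membership = pd.DataFrame(membership_rows)
    summary2 = families.family_summary(fams_by_level, species_map)
    manifest["checksums"]["families.tsv"] = _df_tsv(membership, out / "families.tsv")
    manifest["checksums"]["family_summary.tsv"] = _df_tsv(summary2, out / "family_summary.tsv")
    manifest["stages"]["cluster"] = {
        "levels": list(config.levels),
        "families_at_70": sum(1 for f in fams_by_level[config.levels[0]]),
    }

    # ---- stage 3: rates -------------------------------------------------
    base_level = config.levels[0]
    fam_members = {
        f.family_id: sorted(f.members)
        for f in fams_by_level[base_level]
        if f.is_multi
    }
    dating = rates.DatingParams(config.mu, config.gen_years)
    pair_stats = rates.family_pair_stats(fam_members, cds, species_map, config.max_ks, dating)
    pi_rows = [
        {"family_id": fid, "pi": rates.nucleotide_diversity(fid, {g: cds[g] for g in members}).pi}
        for fid, members in sorted(fam_members.items())
    ]
    hist = rates.ks_histogram(pair_stats["ks"].dropna().tolist())
    hist_df = pd.DataFrame(
        {
            "bin_start": hist["edges"][:-1],
            "bin_end": hist["edges"][1:],
            "count": hist["counts"],
        }
    )
    manifest["checksums"]["pair_stats.tsv"] = _df_tsv(pair_stats, out / "pair_stats.tsv")
    manifest["checksums"]["family_pi.tsv"] = _df_tsv(pd.DataFrame(pi_rows), out / "family_pi.tsv")
    manifest["checksums"]["ks_histogram.tsv"] = _df_tsv(hist_df, out / "ks_histogram.tsv")
    sel = rates.positive_selection_fraction(
        [w for w in pair_stats["omega"] if w == w]  # drop NaN
    )
    comparisons = {"positive_selection": sel, "ks_modal_bins": hist["modal_ranges"]}
    tnl_ks = pair_stats.loc[pair_stats["family"].str.startswith("TNL"), "ks"].dropna()
    non_ks = pair_stats.loc[pair_stats["family"].str.startswith("NON_TNL"), "ks"].dropna()
    if len(tnl_ks) >= 2 and len(non_ks) >= 2:
        comparisons["tnl_vs_non_tnl_ks"] = rates.compare_groups(tnl_ks, non_ks)
    manifest["checksums"]["comparisons.json"] = _write(
        out / "comparisons.json", json.dumps(comparisons, indent=2, default=float) + "\n"
    )
    manifest["stages"]["rates"] = {
        "pairs": int(len(pair_stats)),
        "families_with_pi": len(pi_rows),
    }

    # ---- stage 4: trees + clades ----------------------------------------
    # one tree per subclass scope, as TNL and non-TNL histories are analysed
    # separately; an external Newick (if any) is classified as a single tree
    call_rows = []
    props: dict[str, dict] = {}
    n_calls = genes_called = 0
    if config.newick:
        scope_trees = {"ALL": trees.read_newick(config.newick)}
    else:
        scope_trees = {}
        for scope, scoped_cds in scopes.items():
            if len(scoped_cds) >= 4:
                sup = trees.bootstrap_support(scoped_cds, config.bootstrap_reps, config.seed)
                _write(out / f"tree_{scope}.nwk", trees.write_newick(sup))
                scope_trees[scope] = sup
    for scope, sup in scope_trees.items():
        calls = trees.classify_clades(sup, species_map, config.min_support)
        for c in calls:
            call_rows.append(
                {
                    "scope": scope,
                    "clade_id": f"{scope}_{c.clade_id}",
                    "type": c.call,
                    "support": c.support,
                    "n_genes": c.n_genes,
                    "species_list": ",".join(sorted(c.species_set)),
                    "gene_list": ",".join(c.genes),
                }
            )
        total_genes = len(sup.leaf_names())
        if total_genes:
            props[scope] = trees.duplication_proportions(calls, total_genes)
        n_calls += len(calls)
        genes_called += sum(c.n_genes for c in calls)
    manifest["checksums"]["clade_calls.tsv"] = _df_tsv(
        pd.DataFrame(
            call_rows,
            columns=["scope", "clade_id", "type", "support", "n_genes", "species_list", "gene_list"],
        ),
        out / "clade_calls.tsv",
    )
    manifest["checksums"]["clade_proportions.json"] = _write(
        out / "clade_proportions.json", json.dumps(props, indent=2, default=float) + "\n"
    )
    manifest["stages"]["clades"] = {"calls": n_calls, "genes_called": genes_called}

    # ---- stage 5: expression --------------------------------------------
    if config.fpkm_tsv:
        fpkm = pd.read_csv(config.fpkm_tsv, sep="\t", index_col="gene_id")
        deg_table = pd.read_csv(config.deg_tsv, sep="\t") if config.deg_tsv else None
    else:
        fpkm, deg_table, _etruth = simulate.simulate_expression(sim_cfg)
        _write(
            out / "fpkm.tsv",
            fpkm.to_csv(sep="\t", float_format="%.4f", lineterminator="\n"),
        )
        manifest["checksums"]["fpkm.tsv"] = sha256_text((out / "fpkm.tsv").read_text())
        _df_tsv(deg_table, out / "deg_table.tsv")
    meta = expression.sample_metadata(list(fpkm.columns))
    degs = sorted(expression.screen_degs(deg_table)) if deg_table is not None else []
    clusters = {
        g: expression.cluster_timepoints(fpkm, meta, g)["groups"]
        for g in expression.GENOTYPES
        if (meta["genotype"] == g).any()
    }
    contrast = expression.genotype_contrast(fpkm, meta) if len(clusters) == 2 else None
    expr_report = {
        "degs": degs,
        "n_degs": len(degs),
        "timepoint_groups": clusters,
        "aggregate_contrast": contrast["aggregate"] if contrast else None,
    }
    manifest["checksums"]["expression.json"] = _write(
        out / "expression.json", json.dumps(expr_report, indent=2, default=float) + "\n"
    )
    manifest["stages"]["expression"] = {"samples": int(fpkm.shape[1]), "degs": len(degs)}

    manifest_text = json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    (out / "manifest.json").write_text(manifest_text)
    return manifest


def render_summary(out_dir: str | Path) -> str:
    """Human-readable digest of a completed run's report files."""
    out = Path(out_dir)
    lines: list[str] = ["# NBS-LRR pipeline summary", ""]
    counts = pd.read_csv(out / "class_counts.tsv", sep="\t", index_col=0)
    lines.append("## Gene counts by subclass (columns: species, Total)")
    lines.append(counts.to_string())
    lines.append("")
    summary = pd.read_csv(out / "family_summary.tsv", sep="\t")
    totals = summary[summary["species"] == "Total"]
    lines.append("## Multi-gene proportions by stringency level")
    for _, r in totals.iterrows():
        lines.append(
            f"level >{int(r['level'])}% {r['scope']}: {int(r['multi_genes'])} multi-genes "
            f"({r['multi_pct']:.2f}%), {int(r['n_families'])} multi-gene families"
        )
    lines.append("")
    comp = json.loads((out / "comparisons.json").read_text())
    sel = comp["positive_selection"]
    if sel["total"]:
        lines.append(
            f"## Positive selection: {sel['count_gt1']}/{sel['total']} pairs with Ka/Ks > 1 "
            f"({sel['percent']:.2f}%); {sel['neutral_candidates']} near-neutral"
        )
    dp = rates.DatingParams()
    for lo, hi in comp.get("ks_modal_bins", []):
        lines.append(
            f"Ks modal bin [{lo:.1f},{hi:.1f}): duplications dated "
            f"{rates.date_duplication(lo, dp):.2f}-{rates.date_duplication(hi, dp):.2f} MY"
        )
    lines.append("")
    props = json.loads((out / "clade_proportions.json").read_text())
    for scope, by_kind in props.items():
        for kind, d in by_kind.items():
            lines.append(
                f"## {scope} {kind} duplications: {d['genes']}/{d['total']} genes "
                f"({d['percent']:.2f}%) in {d['clades']} clades"
            )
    expr = json.loads((out / "expression.json").read_text())
    lines.append(f"## DEG screen: {expr['n_degs']} genes pass |logFC|>=2, p<0.05, FDR<0.05")
    for g, groups in expr["timepoint_groups"].items():
        lines.append(f"{g} time-point groups (h): {groups}")
    return "\n".join(lines) + "\n"
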