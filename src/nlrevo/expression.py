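"""Differential-expression screening and time-point clustering for NLR genes.

The screen keeps genes whose precomputed contrast satisfies |logFC| >= 2,
p < 0.05 and FDR < 0.05 (conjunctively; logFC is log2).  Time-point
structure per genotype is summarised by hierarchical clustering of samples
on log2(FPKM+1) profiles with correlation distance (1 - Pearson) and
average linkage, cut into two groups — the infection time courses this
models split cleanly into an early (0-12 h) and a late (24-72 h) phase.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

__all__ = [
    "DEGCriteria",
    "screen_degs",
    "cluster_timepoints",
    "genotype_contrast",
    "sample_metadata",
]

GENOTYPES = ("resistant", "susceptible")


@dataclass(frozen=True)
class DEGCriteria:
    """Conjunctive thresholds for differential expression."""

    min_abs_logfc: float = 2.0  # inclusive
    max_p: float = 0.05  # exclusive
    max_fdr: float = 0.05  # exclusive


def screen_degs(deg_table: pd.DataFrame, criteria: DEGCriteria = DEGCriteria()) -> set[str]:
    """Gene ids passing |logFC| >= 2 AND p < 0.05 AND FDR < 0.05.

    Boundary semantics: |logFC| exactly at the threshold passes, p or FDR
    exactly at theirs fails.
    """
    for col in ("gene_id", "logFC", "p", "FDR"):
        if col not in deg_table.columns:
            raise ValueError(f"DEG table missing column {col!r}")
    keep = (
        (deg_table["logFC"].abs() >= criteria.min_abs_logfc)
        & (deg_table["p"] < criteria.max_p)
        & (deg_table["FDR"] < criteria.max_fdr)
    )
    return set(deg_table.loc[keep, "gene_id"])


def sample_metadata(columns: list[str]) -> pd.DataFrame:
    """Parse ``<genotype>_<t>h`` sample ids into genotype/timepoint metadata."""
    rows = []
    for c in columns:
        m = re.fullmatch(r"(resistant|susceptible)_(\d+)h", c)
        if not m:
            raise ValueError(f"sample id {c!r} does not follow <genotype>_<t>h")
        rows.append({"sample": c, "genotype": m.group(1), "timepoint_h": int(m.group(2))})
    return pd.DataFrame(rows)


def _log_matrix(fpkm: pd.DataFrame) -> pd.DataFrame:
    if (fpkm.values < 0).any():
        raise ValueError("FPKM values must be non-negative")
    return np.log2(fpkm + 1.0)


def cluster_timepoints(
    fpkm: pd.DataFrame,
    meta: pd.DataFrame,
    genotype: str,
    n_groups: int = 2,
) -> dict:
    """Hierarchically cluster one genotype's samples and cut into groups.

    Returns the linkage matrix, the ordered sample list, and the flat
    groups as lists of time points (hours).  Constant gene rows are
    dropped with a warning before computing correlations.
    """
    samples = meta.loc[meta["genotype"] == genotype, "sample"].tolist()
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to cluster")
    sub = _log_matrix(fpkm[samples])
    constant = sub.std(axis=1) == 0
    if constant.any():
        logger.warning("dropping %d constant gene rows before correlation", int(constant.sum()))
        sub = sub.loc[~constant]
    dist = pdist(sub.T.values, metric="correlation")
    link = average(dist)
    flat = fcluster(link, t=n_groups, criterion="maxclust")
    tp = dict(zip(meta["sample"], meta["timepoint_h"]))
    groups: dict[int, list[int]] = {}
    for s, g in zip(samples, flat):
        groups.setdefault(int(g), []).append(tp[s])
    return {
        "samples": samples,
        "linkage": link,
        "groups": [sorted(v) for _, v in sorted(groups.items())],
    }


def genotype_contrast(
    fpkm: pd.DataFrame,
    meta: pd.DataFrame,
    early_max_h: int = 12,
    late_min_h: int = 24,
) -> dict:
    """Early- vs late-phase expression per genotype, with Welch tests.

    Per gene and per genotype: mean log2(FPKM+1) over early (<= 12 h) and
    late (>= 24 h) samples.  Per phase, a Welch t-test contrasts the two
    genotypes' per-gene means; aggregate means are also reported.
    """
    for g in GENOTYPES:
        if not (meta["genotype"] == g).any():
            raise ValueError(f"genotype {g!r} missing from metadata")
    log = _log_matrix(fpkm)
    phases = {
        "early": meta[meta["timepoint_h"] <= early_max_h],
        "late": meta[meta["timepoint_h"] >= late_min_h],
    }
    per_gene = {}
    result: dict = {"per_gene": per_gene, "aggregate": {}, "tests": {}}
    for phase, m in phases.items():
        cols = {g: m.loc[m["genotype"] == g, "sample"].tolist() for g in GENOTYPES}
        means = {g: log[cols[g]].mean(axis=1) for g in GENOTYPES}
        per_gene[phase] = pd.DataFrame(means)
        result["aggregate"][phase] = {g: float(means[g].mean()) for g in GENOTYPES}
        a, b = means["resistant"].values, means["susceptible"].values
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(a, b, equal_var=False)
        result["tests"][phase] = {"t_statistic": float(t), "p_value": float(p)}
    return result
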