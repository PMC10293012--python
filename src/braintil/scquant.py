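"""Single-cell quantification and pTRT-cluster classification.

Clustering/embedding itself is upstream (labels arrive with the cells); this
module owns the quantitative readouts built on those labels: cell-level QC,
the marker-gene selection rule, per-sample cluster abundance, and the
abundance-threshold classification of tumors into pTRT-high (>30% of CD8+
cells in the pTRT cluster) versus pTRT-low (<15%).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

CELL_COLUMNS = ("cell_id", "patient", "compartment", "lineage", "cluster_id",
                "n_features", "mito_frac")


def qc_cells(
    cells: pd.DataFrame,
    max_mito: float = 0.10,
    min_features: int = 250,
    max_features: int = 3000,
) -> pd.DataFrame:
    """Keep cells with mito fraction < max_mito (strict) and total detected
    features in [min_features, max_features] (inclusive bounds)."""
    keep = (
        (cells["mito_frac"] < max_mito)
        & (cells["n_features"] >= min_features)
        & (cells["n_features"] <= max_features)
    )
    return cells.loc[keep]


def lognormalize(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """log1p of depth-normalized counts (counts per ``scale`` per cell)."""
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("cell with zero counts")
    return np.log1p(counts.div(totals, axis=1) * scale)


def cluster_markers(
    expr: pd.DataFrame,
    clusters: pd.Series,
    fc_cut: float = 0.25,
    min_pct: float = 0.25,
    min_cluster_size: int = 3,
    lognorm: bool = True,
) -> pd.DataFrame:
    """Per-cluster marker genes, cluster vs rest.

    ``expr`` is gene x cell counts (log-normalized internally unless
    ``lognorm=False``). A gene is a marker for a cluster when its mean
    log-normalized expression exceeds the rest by more than ``fc_cut``, it is
    detected (count > 0) in at least ``min_pct`` of the cluster's cells, and
    it gets a Wilcoxon rank-sum p-value with BH adjustment within the
    cluster. Clusters smaller than ``min_cluster_size`` are skipped.
    """
    clusters = clusters.loc[expr.columns]
    if clusters.nunique() < 2:
        raise ValueError("need at least two clusters")
    ln = lognormalize(expr) if lognorm else expr
    detected = expr > 0
    rows = []
    for cl in sorted(clusters.unique(), key=str):
        in_cl = clusters == cl
        if in_cl.sum() < min_cluster_size:
            warnings.warn(f"cluster {cl!r} has <{min_cluster_size} cells; skipped")
            continue
        X_in = ln.loc[:, in_cl.to_numpy()]
        X_out = ln.loc[:, (~in_cl).to_numpy()]
        logfc = X_in.mean(axis=1) - X_out.mean(axis=1)
        pct = detected.loc[:, in_cl.to_numpy()].mean(axis=1)
        cand = ln.index[(logfc > fc_cut) & (pct >= min_pct)]
        if len(cand) == 0:
            continue
        pvals = [
            sps.ranksums(X_in.loc[g], X_out.loc[g]).pvalue for g in cand
        ]
        fdr = bh_adjust(pvals)
        for g, p, q in zip(cand, pvals, fdr):
            rows.append((cl, g, logfc[g], pct[g], p, q))
    return pd.DataFrame(
        rows, columns=["cluster", "gene", "log_fc", "pct_detected", "p", "fdr"]
    )


def cluster_abundance(cells: pd.DataFrame) -> pd.DataFrame:
    """Cluster fractions per patient x compartment, normalized within lineage.

    Returns a long table (patient, compartment, lineage, cluster_id,
    n_cells, fraction); fractions sum to 1 within each
    patient x compartment x lineage unit. Units with zero cells simply do not
    appear (the fraction is undefined, hence missing).
    """
    counts = (
        cells.groupby(["patient", "compartment", "lineage", "cluster_id"], observed=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    totals = counts.groupby(["patient", "compartment", "lineage"], observed=True)[
        "n_cells"
    ].transform("sum")
    counts["fraction"] = counts["n_cells"] / totals
    return counts


def ptrt_fraction(
    cells: pd.DataFrame, ptrt_cluster: str, compartment: str = "tumor",
    lineage: str = "CD8",
) -> pd.Series:
    """Per-patient fraction of CD8+ cells in the pTRT cluster, one
    compartment. Patients with no cells in the unit are absent."""
    ab = cluster_abundance(cells)
    unit = ab[(ab["compartment"] == compartment) & (ab["lineage"] == lineage)]
    frac = unit[unit["cluster_id"] == ptrt_cluster].set_index("patient")["fraction"]
    patients = unit["patient"].unique()
    return frac.reindex(patients, fill_value=0.0).rename("ptrt_fraction")


def classify_by_cluster_fraction(
    fraction: float, high_cut: float = 0.30, low_cut: float = 0.15
) -> str:
    """pTRT label from the pTRT-cluster share of CD8+ cells.

    > high_cut -> "high"; < low_cut -> "low"; otherwise "indeterminate"
    (the band between the two published cutoffs, unobserved in practice, is
    reported explicitly rather than forced into a binary call).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction outside [0, 1]")
    if fraction > high_cut:
        return "high"
    if fraction < low_cut:
        return "low"
    return "indeterminate"
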