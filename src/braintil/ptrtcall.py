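"""Integrative pTRT-high/low calling across modalities.

Each modality yields a per-patient label — single-cell pTRT-cluster
fraction, bulk signature clustering, CD39+CCR7low flow gate fraction, or
pTRT cell density by IF — and the consensus combines them: unanimity wins,
any disagreement is surfaced as "discordant", and a cohort-level concordance
rate summarizes how often independent modalities agreed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage

LABELS = ("high", "low", "indeterminate")


@dataclass
class BulkClassification:
    labels: pd.Series  # sample -> {high, low}
    scores: pd.Series  # sample -> mean z over signature genes
    fallback_used: bool = False


def signature_mean_z(log_cpm: pd.DataFrame, genes: list[str]) -> tuple[pd.DataFrame, pd.Series]:
    """(z-scored signature submatrix genes x samples, per-sample mean z)."""
    present = [g for g in genes if g in log_cpm.index]
    if len(present) < 2:
        raise ValueError("need at least two signature genes present")
    sub = log_cpm.loc[present]
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).all():
        raise ValueError("all signature genes constant across samples")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd.replace(0, np.nan), axis=0).dropna()
    return z, z.mean(axis=0)


def bulk_signature_classifier(
    log_cpm: pd.DataFrame, signature_genes: list[str]
) -> BulkClassification:
    """Hierarchical-clustering classification of bulk CD8 profiles.

    Signature genes are z-scored across samples; samples are clustered on
    those z-vectors (Euclidean distance, complete linkage) and the tree is
    cut at k = 2. The cluster with the higher mean z is labeled pTRT-high.
    If the cut leaves a singleton cluster the classifier falls back to
    thresholding each sample's mean z at 0, with a warning.
    """
    if log_cpm.shape[1] < 4:
        raise ValueError("need at least four samples to cluster")
    z, mean_z = signature_mean_z(log_cpm, signature_genes)
    X = z.to_numpy().T  # samples x genes
    if np.allclose(X, X[0]):
        raise ValueError("degenerate clustering: all samples identical")
    # deterministic tie-break: order samples by ID before linkage
    order = np.argsort(np.asarray(log_cpm.columns, dtype=object))
    samples = log_cpm.columns[order]
    Z = linkage(X[order], method="complete", metric="euclidean")
    assign = fcluster(Z, t=2, criterion="maxclust")
    sizes = pd.Series(assign).value_counts()
    fallback = False
    if sizes.min() <= 1:
        warnings.warn("k=2 cut produced a singleton cluster; thresholding mean z at 0")
        labels = pd.Series(
            np.where(mean_z.loc[samples] > 0, "high", "low"), index=samples
        )
        fallback = True
    else:
        g1 = samples[assign == 1]
        g2 = samples[assign == 2]
        high_group = g1 if mean_z.loc[g1].mean() >= mean_z.loc[g2].mean() else g2
        labels = pd.Series(
            ["high" if s in set(high_group) else "low" for s in samples], index=samples
        )
    return BulkClassification(labels.loc[log_cpm.columns], mean_z, fallback)


@dataclass
class CorrelationReport:
    r: float
    r2: float
    p: float
    n_pairs: int
    n_dropped: int


def impute_vs_measured(
    scores: pd.Series, measured_fractions: pd.Series
) -> CorrelationReport:
    """Pearson correlation between bulk signature scores and directly
    measured pTRT fractions, over patients with both values."""
    paired = pd.concat(
        [scores.rename("score"), measured_fractions.rename("measured")], axis=1
    )
    n_total = len(paired)
    paired = paired.dropna()
    if len(paired) < 3:
        raise ValueError("need at least three paired samples")
    if paired["measured"].nunique() == 1 or paired["score"].nunique() == 1:
        raise ValueError("correlation undefined: a paired vector is constant")
    res = sps.pearsonr(paired["score"], paired["measured"])
    return CorrelationReport(
        float(res.statistic), float(res.statistic) ** 2, float(res.pvalue),
        len(paired), n_total - len(paired),
    )


@dataclass
class PtrtCallSet:
    """Per-patient modality evidence, labels, consensus, and concordance."""

    calls: pd.DataFrame  # per-modality label columns + consensus
    concordance_rate: float = field(default=np.nan)
    n_multi_modality: int = 0


def _consensus_one(labels: list[str]) -> str:
    informative = [l for l in labels if l in ("high", "low")]
    if not informative:
        return "insufficient"
    if len(set(informative)) == 1:
        return informative[0]
    return "discordant"


def consensus_call(calls: pd.DataFrame) -> PtrtCallSet:
    """Combine per-modality labels into a consensus per patient.

    ``calls``: patients x modalities, entries in {high, low, indeterminate}
    or NaN (modality absent). Unanimous informative labels give the
    consensus; any high/low disagreement is "discordant";
    indeterminate-only is "insufficient". The concordance rate is computed
    over patients with >= 2 informative modalities.
    """
    out = calls.copy()
    consensus, multi, agree = [], 0, 0
    for _, row in calls.iterrows():
        labels = [str(v) for v in row.dropna() if str(v) in LABELS]
        c = _consensus_one(labels)
        consensus.append(c)
        informative = [l for l in labels if l in ("high", "low")]
        if len(informative) >= 2:
            multi += 1
            if len(set(informative)) == 1:
                agree += 1
    out["consensus"] = consensus
    rate = agree / multi if multi else np.nan
    return PtrtCallSet(out, rate, multi)
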