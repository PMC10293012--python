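"""Bulk sorted-population RNA-seq processing.

Sorted immune populations (CD4 / CD8 T cells, CD45-negative tumor cells,
microglia, monocyte-derived macrophages) profiled by low-input bulk RNA-seq
need four things before any biology can be read off: library-depth QC,
removal of tumor-cell transcripts that contaminate sorted T cell profiles,
composition-aware normalization (TMM), and a calibrated two-group
differential-expression test. All four live here.

Counts are held as a gene x sample :class:`ExpressionMatrix` with per-sample
metadata (patient, compartment blood/tumor, sorted population, disease
group).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, squeeze_variances

logger = logging.getLogger(__name__)

META_COLUMNS = ("patient", "compartment", "population", "disease")


@dataclass
class ExpressionMatrix:
    """Gene x sample count matrix with sample metadata.

    counts: DataFrame indexed by gene ID, columns are sample IDs,
        non-negative values.
    sample_meta: DataFrame indexed by sample ID with at least the columns
        patient, compartment ({blood, tumor}), population
        ({CD4, CD8, CD45neg, MG, MDM}) and disease.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene IDs")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample IDs")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"sample metadata missing for {sorted(missing)}")
        self.sample_meta = self.sample_meta.loc[list(self.counts.columns)]

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(self.counts[ids], self.sample_meta.loc[ids])

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.counts.loc[list(gene_ids)], self.sample_meta)

    def drop_genes(self, gene_ids) -> "ExpressionMatrix":
        keep = self.counts.index.difference(pd.Index(gene_ids), sort=False)
        return ExpressionMatrix(self.counts.loc[keep], self.sample_meta)


def qc_min_counts(m: ExpressionMatrix, min_total: int = 1_000_000) -> ExpressionMatrix:
    """Drop samples with fewer than ``min_total`` total counts (strict <)."""
    totals = m.counts.sum(axis=0)
    keep = totals[totals >= min_total].index
    excluded = [s for s in m.sample_ids if s not in set(keep)]
    if excluded:
        logger.info("qc_min_counts excluded %d samples: %s", len(excluded), excluded)
    if len(keep) == 0:
        raise ValueError("all samples excluded by the minimum-count filter")
    return m.subset_samples(keep)


def tmm_factors(
    m: ExpressionMatrix | pd.DataFrame,
    log_ratio_trim: float = 0.3,
    abs_intensity_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean across samples. For every other sample, the factor is
    2 to the precision-weighted mean of gene-wise log2 ratios (M values)
    against the reference, after discarding the most extreme 30% of M values
    and 5% of average log intensities (A values). Factors are rescaled to
    geometric mean 1, so they carry composition, not depth.
    """
    counts = m.counts if isinstance(m, ExpressionMatrix) else m
    X = counts.to_numpy(dtype=float)
    n_samples = X.shape[1]
    if n_samples < 2:
        raise ValueError("TMM needs at least two samples")
    lib = X.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("all-zero sample")

    q75 = np.array(
        [np.quantile(X[:, j][X[:, j] > 0] if (X[:, j] > 0).any() else X[:, j], 0.75)
         for j in range(n_samples)]
    ) / lib
    ref = int(np.argmin(np.abs(q75 - q75.mean())))

    factors = np.ones(n_samples)
    for j in range(n_samples):
        if j == ref:
            factors[j] = _tmm_pair(X[:, j], X[:, ref], lib[j], lib[ref],
                                   log_ratio_trim, abs_intensity_trim)
        else:
            factors[j] = _tmm_pair(X[:, j], X[:, ref], lib[j], lib[ref],
                                   log_ratio_trim, abs_intensity_trim)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _tmm_pair(obs, ref, lib_obs, lib_ref, log_ratio_trim, abs_intensity_trim) -> float:
    """One sample's TMM factor against the reference (edgeR conventions)."""
    ok = (obs > 0) & (ref > 0)
    if ok.sum() == 0:
        return 1.0
    po = obs[ok] / lib_obs
    pr = ref[ok] / lib_ref
    M = np.log2(po / pr)
    A = 0.5 * (np.log2(po) + np.log2(pr))
    # asymptotic (delta-method) precision of each M value
    w = (lib_obs - obs[ok]) / (lib_obs * obs[ok]) + (lib_ref - ref[ok]) / (lib_ref * ref[ok])
    fin = np.isfinite(M) & np.isfinite(A)
    M, A, w = M[fin], A[fin], w[fin]
    if M.size == 0 or np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = M.size
    lo_m, hi_m = np.floor(n * log_ratio_trim) + 1, n - np.floor(n * log_ratio_trim)
    lo_a, hi_a = np.floor(n * abs_intensity_trim) + 1, n - np.floor(n * abs_intensity_trim)
    rank_m = sps.rankdata(M)
    rank_a = sps.rankdata(A)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def log_cpm(
    m: ExpressionMatrix | pd.DataFrame,
    factors: pd.Series | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2 counts-per-million on TMM-effective library sizes.

    log2((count + prior_count) / (library * factor) * 1e6). With
    ``factors=None`` all factors are 1 (plain depth normalization).
    """
    counts = m.counts if isinstance(m, ExpressionMatrix) else m
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero library size")
    if factors is None:
        eff = lib.astype(float)
    else:
        eff = lib * factors.loc[counts.columns]
    return np.log2((counts + prior_count).div(eff, axis=1) * 1e6)


def filter_by_expression(
    m: ExpressionMatrix,
    groups: pd.Series | None = None,
    min_count: int = 10,
    min_total: int = 15,
) -> pd.Index:
    """Genes worth testing: count >= min_count in at least min-group-size
    samples and row total >= min_total.

    Emulates the standard expression filter used before DEA (published
    defaults 10 / 15); ``groups`` gives the group label per sample, and the
    per-gene support requirement is the size of the smallest group.
    """
    if groups is None:
        groups = pd.Series("all", index=m.sample_ids)
    groups = groups.loc[m.sample_ids]
    sizes = groups.value_counts()
    if sizes.empty:
        raise ValueError("empty groups")
    n_needed = int(sizes.min())
    enough = (m.counts >= min_count).sum(axis=1) >= n_needed
    total_ok = m.counts.sum(axis=1) >= min_total
    return m.gene_ids[enough & total_ok]


@dataclass
class DeaResult:
    """Per-gene two-group differential expression summary."""

    table: pd.DataFrame  # log2fc, p, fdr, mean_a, mean_b, passed
    group_a: str
    group_b: str
    fc_cut: float = 2.0
    fdr_cut: float = 0.05
    prior_df: float = field(default=np.nan)

    @property
    def passed(self) -> pd.Index:
        return self.table.index[self.table["passed"]]


def dea_two_group(
    m: ExpressionMatrix,
    group_a,
    group_b,
    fc_cut: float = 2.0,
    fdr_cut: float = 0.05,
    factors: pd.Series | None = None,
) -> DeaResult:
    """Moderated-t differential expression between two sample groups.

    Works on log2-CPM (TMM-normalized when ``factors`` given). Per-gene
    variances are shrunk toward a pooled prior fitted by method of moments on
    log variances; the moderated t gets the prior degrees of freedom added.
    A gene passes when |log2FC| > log2(fc_cut) and BH-FDR < fdr_cut.
    log2FC is group_a minus group_b.
    """
    ids_a, ids_b = list(group_a), list(group_b)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("each group needs at least two samples")
    na, nb = len(ids_a), len(ids_b)
    df_resid = na + nb - 2
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")

    sub = m.subset_samples(ids_a + ids_b)
    if factors is None:
        factors = tmm_factors(sub)
    lc = log_cpm(sub, factors)
    Xa = lc[ids_a].to_numpy()
    Xb = lc[ids_b].to_numpy()
    mean_a = Xa.mean(axis=1)
    mean_b = Xb.mean(axis=1)
    diff = mean_a - mean_b
    ss = ((Xa - mean_a[:, None]) ** 2).sum(axis=1) + ((Xb - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid
    s2_post, d0, _ = squeeze_variances(s2, df_resid)
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    df_total = df_resid + d0 if np.isfinite(d0) else np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    p = np.where(se == 0, np.where(diff == 0, 1.0, 0.0), p)
    fdr = bh_adjust(p)
    passed = (np.abs(diff) > np.log2(fc_cut)) & (fdr < fdr_cut)
    table = pd.DataFrame(
        {
            "log2fc": diff,
            "t": t,
            "p": p,
            "fdr": fdr,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "passed": passed,
        },
        index=sub.gene_ids,
    )
    return DeaResult(table, "A", "B", fc_cut, fdr_cut, prior_df=d0)


def top_variable_genes(log_expr: pd.DataFrame, n: int = 250) -> list[str]:
    """The n genes with the largest across-sample variance of log expression.

    Ties are broken lexicographically by gene ID so the selection is
    deterministic.
    """
    if n > log_expr.shape[0]:
        raise ValueError("n exceeds gene count")
    var = log_expr.var(axis=1, ddof=1)
    order = sorted(log_expr.index, key=lambda g: (-var[g], g))
    return order[:n]


@dataclass
class ContaminationResult:
    removed_genes: list[str]
    per_group: dict  # disease group -> removed gene list
    filtered: ExpressionMatrix


def _coarse_disease(d: str) -> str:
    return "BrM" if str(d).startswith("BrM") else str(d)


def contamination_filter(
    t_cells: ExpressionMatrix,
    cd45neg: ExpressionMatrix,
    n_top: int = 250,
    fc_cut: float = 3.0,
    fdr_cut: float = 0.001,
) -> ContaminationResult:
    """Four-step tumor-contamination gene filter for sorted T cell profiles.

    Per disease group: (1) the ``n_top`` genes with highest mean log2-CPM in
    CD45-negative (tumor) samples; (2) DEA of CD45-negative vs all T cells,
    blood and tumor pooled; (3) genes higher in CD45-negative with
    fold change > fc_cut (i.e. log2FC > log2(fc_cut)) and FDR < fdr_cut;
    (4) the intersection of (1) and (3). The union over disease groups is
    removed from the T cell matrix.
    """
    shared = t_cells.gene_ids.intersection(cd45neg.gene_ids)
    if len(shared) == 0:
        raise ValueError("no shared gene universe")
    t_cells = t_cells.subset_genes(shared)
    cd45neg = cd45neg.subset_genes(shared)

    groups = sorted(
        set(t_cells.sample_meta["disease"].map(_coarse_disease))
        | set(cd45neg.sample_meta["disease"].map(_coarse_disease))
    )
    per_group: dict[str, list[str]] = {}
    for g in groups:
        t_ids = t_cells.sample_ids[t_cells.sample_meta["disease"].map(_coarse_disease) == g]
        c_ids = cd45neg.sample_ids[cd45neg.sample_meta["disease"].map(_coarse_disease) == g]
        if len(c_ids) == 0 or len(t_ids) < 2 or len(c_ids) < 2:
            warnings.warn(f"disease group {g!r}: missing CD45neg or T cell samples; skipped")
            continue
        combined = ExpressionMatrix(
            pd.concat([cd45neg.counts[c_ids], t_cells.counts[t_ids]], axis=1),
            pd.concat([cd45neg.sample_meta.loc[c_ids], t_cells.sample_meta.loc[t_ids]]),
        )
        lc = log_cpm(combined, tmm_factors(combined))
        mean_cd45 = lc[list(c_ids)].mean(axis=1)
        step1 = set(sorted(shared, key=lambda gn: (-mean_cd45[gn], gn))[:n_top])
        kept = filter_by_expression(
            combined,
            pd.Series(["cd45neg"] * len(c_ids) + ["t"] * len(t_ids), index=list(c_ids) + list(t_ids)),
        )
        dea = dea_two_group(combined.subset_genes(kept), list(c_ids), list(t_ids),
                            fc_cut=fc_cut, fdr_cut=fdr_cut)
        step3 = set(dea.table.index[(dea.table["log2fc"] > np.log2(fc_cut))
                                    & (dea.table["fdr"] < fdr_cut)])
        per_group[g] = sorted(step1 & step3)

    removed = sorted(set().union(*per_group.values())) if per_group else []
    return ContaminationResult(removed, per_group, t_cells.drop_genes(removed))
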