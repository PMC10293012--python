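"""Gene-signature machinery.

Three readouts of signature activity, at three resolutions:

* :func:`module_score` — per-cell signature score against expression-matched
  control genes (the standard single-cell module-score construction: genes are
  binned by average expression and controls drawn from the matching bins, so
  the score is centred at zero for an uninformative signature).
* :func:`preranked_gsea` — weighted Kolmogorov-Smirnov running-sum enrichment
  of a gene set in a ranked list (e.g. moderated-t statistics), with a
  gene-label permutation p-value.
* :func:`per_sample_signature_enrichment` — mean z-score of the set genes per
  sample, a monotone per-sample set score used for group comparisons and as
  the bulk pTRT evidence channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import bh_adjust


@dataclass
class SignatureSet:
    """Named gene lists with optional provenance notes."""

    sets: dict[str, list[str]]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"signature {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"signature {name!r} has duplicate genes")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gmt(path) -> SignatureSet:
    """Read a GMT file (name, description, genes... per tab-separated line)."""
    sets, prov = {}, {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        sets[name] = genes
        prov[name] = desc
    return SignatureSet(sets, prov)


def write_gmt(sigs: SignatureSet, path) -> None:
    lines = [
        "\t".join([name, sigs.provenance.get(name, "")] + list(genes))
        for name, genes in sigs.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def module_score(
    expr: pd.DataFrame,
    signature: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Per-cell signature score minus expression-bin-matched control score.

    ``expr`` is gene x cell. All genes are binned into ``n_bins``
    equal-frequency bins by average expression; for each signature gene,
    ``n_ctrl`` control genes are drawn (with replacement) from its bin. The
    score is mean signature expression minus mean pooled-control expression,
    per cell.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if expr.shape[0] < n_bins:
        raise ValueError("fewer genes than bins")
    sig = [g for g in dict.fromkeys(signature) if g in expr.index]
    if not sig:
        raise ValueError("signature has no overlap with the expression matrix")
    avg = expr.mean(axis=1)
    # equal-frequency bins on the rank of average expression
    ranks = avg.rank(method="first")
    bins = np.ceil(ranks / (len(ranks) / n_bins)).clip(1, n_bins).astype(int)
    by_bin = {b: expr.index[bins == b] for b in range(1, n_bins + 1)}
    ctrl_genes: list[str] = []
    for g in sig:
        pool = by_bin[int(bins[g])]
        ctrl_genes.extend(rng.choice(pool, size=n_ctrl, replace=True))
    sig_mean = expr.loc[sig].mean(axis=0)
    ctrl_mean = expr.loc[ctrl_genes].mean(axis=0)
    return (sig_mean - ctrl_mean).rename("module_score")


def _es_from_positions(
    pos: np.ndarray, weights: np.ndarray, n: int
) -> np.ndarray:
    """Running-sum extrema for hit positions (rows = instances).

    ``pos`` is (m, k) of sorted 0-based hit positions in a ranking of length
    n; ``weights`` the matching |stat|^w values. Returns the signed extremum
    of each running sum. The extremum of the running sum over the whole list
    occurs immediately after a hit (maximum candidates) or immediately before
    one (minimum candidates), so only hit positions need evaluating.
    """
    m, k = pos.shape
    miss = 1.0 / (n - k)
    W = weights.sum(axis=1, keepdims=True)
    flat = W[:, 0] == 0
    if flat.any():  # all-zero statistics: fall back to unweighted hits
        weights = weights.copy()
        weights[flat] = 1.0
        W = weights.sum(axis=1, keepdims=True)
    cw = np.cumsum(weights, axis=1) / W
    j = np.arange(k)
    after = cw - (pos - j) * miss
    before = np.concatenate([np.zeros((m, 1)), cw[:, :-1]], axis=1) - (pos - j) * miss
    top = after.max(axis=1)
    bot = np.minimum(before.min(axis=1), 0.0)
    return np.where(top >= -bot, top, bot)


@dataclass
class EnrichmentResult:
    """Per-set preranked enrichment summary."""

    table: pd.DataFrame  # es, nes, p, fdr, size, excluded


def preranked_gsea(
    ranks: pd.Series,
    sets: SignatureSet,
    min_size: int = 15,
    max_size: int = 500,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> EnrichmentResult:
    """Preranked gene-set enrichment with a gene-permutation p-value.

    ``ranks`` maps gene -> ranking statistic (e.g. a moderated t). Hits step
    the running sum up in proportion to |statistic|**weight, misses step it
    down uniformly; the enrichment score is the signed extremum. The p-value
    compares against random same-size gene sets (same-sign tail), floored at
    1/(n_perm+1); BH adjustment runs across retained sets. Sets whose overlap
    with the ranked genes falls outside [min_size, max_size] are excluded and
    flagged, not errors.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if ranks.index.has_duplicates:
        raise ValueError("duplicate genes in ranking")
    if not np.isfinite(ranks.to_numpy()).all():
        raise ValueError("non-finite ranking statistics")
    order = ranks.sort_values(ascending=False, kind="mergesort")
    stat = np.abs(order.to_numpy()) ** weight
    index = {g: i for i, g in enumerate(order.index)}
    n = len(order)

    rows = []
    for name, genes in sets.items():
        pos = np.sort([index[g] for g in genes if g in index])
        size = len(pos)
        if size < min_size or size > max_size or size == n:
            rows.append((name, np.nan, np.nan, np.nan, size, True))
            continue
        es = float(_es_from_positions(pos[None, :], stat[pos][None, :], n)[0])
        perm_pos = np.empty((n_perm, size), dtype=np.intp)
        for i in range(n_perm):
            perm_pos[i] = np.sort(rng.choice(n, size=size, replace=False))
        perm_es = _es_from_positions(perm_pos, stat[perm_pos], n)
        if es >= 0:
            tail = perm_es[perm_es >= 0]
            exceed = int((tail >= es).sum())
        else:
            tail = perm_es[perm_es < 0]
            exceed = int((tail <= es).sum())
        p = max(exceed, 1) / (len(tail) + 1) if len(tail) else 1.0 / (n_perm + 1)
        p = max(p, 1.0 / (n_perm + 1))
        denom = np.abs(tail).mean() if len(tail) else np.abs(perm_es).mean()
        nes = es / denom if denom > 0 else np.nan
        rows.append((name, es, nes, p, size, False))

    table = pd.DataFrame(
        rows, columns=["set", "es", "nes", "p", "size", "excluded"]
    ).set_index("set")
    table["fdr"] = np.nan
    kept = ~table["excluded"]
    if kept.any():
        table.loc[kept, "fdr"] = bh_adjust(table.loc[kept, "p"])
    return EnrichmentResult(table[["es", "nes", "p", "fdr", "size", "excluded"]])


def per_sample_signature_enrichment(
    log_expr: pd.DataFrame, sets: SignatureSet
) -> pd.DataFrame:
    """Sample x set matrix of mean z-scores.

    Each gene is z-scored across samples; a sample's score for a set is the
    mean z over the set's genes present in the matrix. Requires >= 2 samples
    (z undefined otherwise).
    """
    if log_expr.shape[1] < 2:
        raise ValueError("z-scores need at least two samples")
    mu = log_expr.mean(axis=1)
    sd = log_expr.std(axis=1, ddof=1)
    if (sd == 0).all():
        raise ValueError("all genes constant across samples")
    z = log_expr.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0)
    out = {}
    for name, genes in sets.items():
        present = [g for g in genes if g in z.index]
        if not present:
            raise ValueError(f"signature {name!r} has no overlap with the matrix")
        out[name] = z.loc[present].mean(axis=0)
    return pd.DataFrame(out)
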