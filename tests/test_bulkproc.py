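"""Bulk RNA-seq processing: QC, TMM, log-CPM, expression filter, DEA, and the
four-step contamination filter."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from braintil import bulkproc
from braintil.bulkproc import ExpressionMatrix
from braintil.stats import bh_adjust


def make_matrix(counts: np.ndarray, populations=None, diseases=None,
                prefix: str = "s") -> ExpressionMatrix:
    n_genes, n_samples = counts.shape
    genes = [f"g{i:03d}" for i in range(n_genes)]
    samples = [f"{prefix}{i:02d}" for i in range(n_samples)]
    meta = pd.DataFrame(
        {
            "patient": [f"p{i}" for i in range(n_samples)],
            "compartment": "tumor",
            "population": populations or ["CD8"] * n_samples,
            "disease": diseases or ["glioma"] * n_samples,
        },
        index=samples,
    )
    return ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=samples), meta)


class TestQcMinCounts:
    def test_boundaries(self):
        counts = np.zeros((2, 3), dtype=int)
        counts[0] = [999_999, 1_000_000, 2_000_000]
        m = bulkproc.qc_min_counts(make_matrix(counts))
        # strict <: 999,999 excluded, exactly 1,000,000 retained
        assert list(m.sample_ids) == ["s01", "s02"]

    def test_counting(self):
        counts = np.zeros((1, 3), dtype=int)
        counts[0] = [2_000_000, 500_000, 1_500_000]
        assert bulkproc.qc_min_counts(make_matrix(counts)).counts.shape[1] == 2

    def test_all_excluded_raises(self):
        with pytest.raises(ValueError):
            bulkproc.qc_min_counts(make_matrix(np.ones((3, 2), dtype=int)))


class TestTmm:
    def test_identical_samples(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(50, 80)
        f = bulkproc.tmm_factors(make_matrix(np.column_stack([col, col])))
        assert np.allclose(f, 1.0)

    def test_pure_depth_difference(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(100, 100) + 1
        f = bulkproc.tmm_factors(make_matrix(np.column_stack([col, 2 * col])))
        assert np.allclose(f, 1.0)

    def test_matches_edger_frozen(self):
        """Frozen cross-check against edgeR::calcNormFactors(method='TMM')."""
        rng = np.random.default_rng(42)
        X = rng.negative_binomial(5, 0.01, size=(200, 4)).astype(float)
        X[:10, 1] *= 10
        f = bulkproc.tmm_factors(make_matrix(X.astype(int)))
        expected = [1.06736119, 0.80332756, 1.07497980, 1.08491478]
        assert np.allclose(f, expected, atol=1e-7)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(3)
        X = rng.negative_binomial(3, 0.02, size=(150, 5))
        f = bulkproc.tmm_factors(make_matrix(X))
        assert np.isclose(np.exp(np.mean(np.log(f))), 1.0)


class TestLogCpm:
    def test_closed_forms(self):
        counts = pd.DataFrame({"s": [0.0, 999.5, 1_000_000 - 999.5 - 0.5 + 0.5]})
        counts.loc[2, "s"] = 1_000_000 - counts["s"].iloc[:2].sum()
        lc = bulkproc.log_cpm(counts, prior_count=0.5)
        assert np.isclose(lc.iloc[0, 0], np.log2(0.5))
        assert np.isclose(lc.iloc[1, 0], np.log2(1000.0), atol=1e-6)

    def test_depth_invariance(self):
        rng = np.random.default_rng(0)
        c = pd.DataFrame(rng.poisson(100, size=(50, 2)).astype(float))
        a = bulkproc.log_cpm(c, prior_count=0.0).to_numpy()
        b = bulkproc.log_cpm(2 * c, prior_count=0.0).to_numpy()
        assert np.allclose(a, b)


class TestFilterByExpression:
    def test_all_zero_removed(self):
        counts = np.vstack([np.zeros(6, dtype=int), np.full(6, 20)])
        m = make_matrix(counts)
        kept = bulkproc.filter_by_expression(m)
        assert list(kept) == ["g001"]

    def test_rule_arithmetic(self):
        # count 10 in every sample of the smaller group (3 of 6+3), total 90
        counts = np.zeros((1, 9), dtype=int)
        counts[0, 6:] = 10
        counts[0, :6] = 5
        m = make_matrix(counts)
        groups = pd.Series(["a"] * 6 + ["b"] * 3, index=m.sample_ids)
        assert list(bulkproc.filter_by_expression(m, groups)) == ["g000"]

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(4, size=(100, 8))
        m = make_matrix(counts)
        groups = pd.Series(["a"] * 5 + ["b"] * 3, index=m.sample_ids)
        kept = set(bulkproc.filter_by_expression(m, groups))
        expected = {
            g for i, g in enumerate(m.gene_ids)
            if (counts[i] >= 10).sum() >= 3 and counts[i].sum() >= 15
        }
        assert kept == expected


class TestDea:
    @staticmethod
    def _sim(rng, n_genes=300, n=6, lfc_gene=None):
        mu = rng.lognormal(3, 1, n_genes)
        X = rng.poisson(np.tile(mu[:, None], (1, 2 * n)))
        if lfc_gene is not None:
            X[lfc_gene, :n] *= 8
        return X

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(7)
        X = self._sim(rng, lfc_gene=0)
        m = make_matrix(X)
        res = bulkproc.dea_two_group(m, list(m.sample_ids[:6]), list(m.sample_ids[6:]))
        assert res.table.iloc[0]["passed"]
        assert res.table.iloc[0]["log2fc"] > 2

    def test_antisymmetry(self):
        rng = np.random.default_rng(8)
        X = self._sim(rng)
        m = make_matrix(X)
        a, b = list(m.sample_ids[:6]), list(m.sample_ids[6:])
        f = bulkproc.tmm_factors(m)
        r1 = bulkproc.dea_two_group(m, a, b, factors=f)
        r2 = bulkproc.dea_two_group(m, b, a, factors=f)
        assert np.allclose(r1.table["log2fc"], -r2.table["log2fc"])
        assert np.allclose(r1.table["p"], r2.table["p"])

    def test_fc_cut_one_is_fdr_only(self):
        rng = np.random.default_rng(9)
        X = self._sim(rng, lfc_gene=1)
        m = make_matrix(X)
        res = bulkproc.dea_two_group(
            m, list(m.sample_ids[:6]), list(m.sample_ids[6:]), fc_cut=1
        )
        expected = (res.table["fdr"] < 0.05) & (res.table["log2fc"].abs() > 0)
        assert (res.table["passed"] == expected).all()

    def test_small_group_raises(self):
        m = make_matrix(np.ones((10, 3), dtype=int) * 100)
        with pytest.raises(ValueError):
            bulkproc.dea_two_group(m, [m.sample_ids[0]], list(m.sample_ids[1:]))


class TestBh:
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_textbook_step_up(self, pvals):
        """BH equals the direct step-up definition q_(i) = min_{j>=i} p_(j)*n/j."""
        p = np.array(pvals)
        ours = bh_adjust(p)
        n = len(p)
        order = np.argsort(p, kind="mergesort")
        q = p[order] * n / np.arange(1, n + 1)
        q = np.minimum.accumulate(q[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(q, 1.0)
        assert np.allclose(ours, expected, atol=1e-12)


class TestTopVariableGenes:
    def test_tie_break_and_ranking(self):
        rng = np.random.default_rng(2)
        lc = pd.DataFrame(rng.normal(size=(30, 5)),
                          index=[f"g{i:02d}" for i in range(30)])
        top = bulkproc.top_variable_genes(lc, n=10)
        var = lc.var(axis=1, ddof=1)
        expected = sorted(lc.index, key=lambda g: (-var[g], g))[:10]
        assert top == expected

    def test_constant_matrix_id_order(self):
        lc = pd.DataFrame(np.ones((5, 4)), index=["e", "d", "c", "b", "a"])
        assert bulkproc.top_variable_genes(lc, n=3) == ["a", "b", "c"]

    def test_single_variable_gene(self):
        lc = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"))
        lc.loc["c"] = [0, 10, 0, 10]
        assert bulkproc.top_variable_genes(lc, n=1) == ["c"]


class TestContaminationFilter:
    @staticmethod
    def _toy(rng, n_genes=300, contam_fold=500.0, contam_rank_ok=True):
        genes = n_genes
        base = rng.lognormal(3, 0.6, genes)
        t = rng.poisson(np.tile(base[:, None], (1, 6)))
        c_mean = base.copy()
        if contam_rank_ok:
            c_mean[0] = base.max() * contam_fold / 10
        else:
            c_mean[0] = np.quantile(base, 0.05)  # highly DE but lowly expressed
        t[0] = rng.poisson(max(c_mean[0] / contam_fold, 0.5), 6)
        c = rng.poisson(np.tile(c_mean[:, None], (1, 4)))
        tm = make_matrix(t)
        cm = make_matrix(c, populations=["CD45neg"] * 4, prefix="c")
        return tm, cm

    def test_planted_contaminant_removed(self):
        rng = np.random.default_rng(21)
        tm, cm = self._toy(rng)
        res = bulkproc.contamination_filter(tm, cm, n_top=50)
        assert "g000" in res.removed_genes
        assert "g000" not in res.filtered.gene_ids

    def test_housekeeping_retained(self):
        rng = np.random.default_rng(22)
        tm, cm = self._toy(rng)
        res = bulkproc.contamination_filter(tm, cm, n_top=50)
        # equally expressed genes fail the DE step and stay
        assert "g010" in res.filtered.gene_ids

    def test_low_rank_contaminant_retained(self):
        rng = np.random.default_rng(23)
        tm, cm = self._toy(rng, contam_rank_ok=False)
        res = bulkproc.contamination_filter(tm, cm, n_top=20)
        assert "g000" not in res.removed_genes

    def test_removed_set_bounded(self, small_cohort):
        bulk = small_cohort.bulk
        is_t = bulk.sample_meta["population"].isin(["CD4", "CD8"])
        t = bulk.subset_samples(bulk.sample_ids[is_t])
        c = bulk.subset_samples(
            bulk.sample_ids[bulk.sample_meta["population"] == "CD45neg"])
        res = bulkproc.contamination_filter(t, c, n_top=50)
        n_groups = len(res.per_group)
        assert len(res.removed_genes) <= 50 * n_groups
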