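"""Shared fixtures.

``small_cohort`` is a fast desk-scale cohort for unit tests. ``seed_metrics``
simulates the default 24-patient cohort for 20 seeds, runs the full pipeline
on each, and collects the per-seed recovery metrics; it is session-scoped so
the many 20-seed recovery properties share one set of simulations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from braintil import SimConfig, analyze_cohort, simulate_cohort
from braintil.scquant import classify_by_cluster_fraction
from braintil.flowgate import classify_by_gate_fraction

N_SEEDS = 20


def small_config(**kw) -> SimConfig:
    base = dict(
        n_patients=6,
        n_genes=400,
        n_signature_genes=15,
        n_contamination_genes=8,
        n_cells_per_sample=120,
        n_events_per_sample=400,
        n_spatial_cells=300,
        n_clones_tumor=60,
        n_clones_blood=80,
        seed=11,
    )
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def seed_metrics():
    """Per-seed recovery metrics of the full pipeline on the default cohort."""
    rows = []
    for seed in range(N_SEEDS):
        cohort = simulate_cohort(SimConfig(seed=seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = analyze_cohort(cohort, seed=seed, run_gsea=False)
        truth = cohort.truth.patients
        planted = set(cohort.truth.contamination_genes)
        removed = set(res.removed_contaminants)

        consensus = res.calls.calls["consensus"].reindex(truth.index)
        correct = (consensus == truth["ptrt_label"]).sum()

        # sc-label agreement for patients whose true fraction is decidable
        sc_est = res.sc_fraction.reindex(truth.index)
        outside = truth.index[(truth["true_fraction"] < 0.15)
                              | (truth["true_fraction"] > 0.30)]
        sc_ok = sum(
            classify_by_cluster_fraction(sc_est[p]) == truth.loc[p, "ptrt_label"]
            for p in outside if not np.isnan(sc_est.get(p, np.nan))
        )

        flow_outside = truth.index[(truth["true_fraction"] < 0.25)
                                   | (truth["true_fraction"] > 0.35)]
        flow_ok = sum(
            classify_by_gate_fraction(res.flow_fractions[p]) == truth.loc[p, "ptrt_label"]
            for p in flow_outside if p in res.flow_fractions.index
        )

        rows.append({
            "seed": seed,
            "n_patients": len(truth),
            "contam_recovered": len(planted & removed),
            "contam_planted": len(planted),
            "contam_false": len(removed - planted),
            "consensus_correct": int(correct),
            "concordance_rate": res.calls.concordance_rate,
            "n_multi": res.calls.n_multi_modality,
            "validation_r": np.nan if res.validation is None else res.validation.r,
            "sc_ok": sc_ok,
            "sc_total": len(outside),
            "flow_ok": flow_ok,
            "flow_total": len(flow_outside),
        })
    return pd.DataFrame(rows)
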