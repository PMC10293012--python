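"""End-to-end analysis of a multi-modal cohort.

Chains the full workflow on a :class:`~braintil.simdata.Cohort` (simulated
or loaded from disk): single-cell QC and pTRT-cluster quantification, bulk
decontamination / DEA / enrichment, bulk hierarchical-cluster
classification, TCR repertoire statistics, flow gating, spatial analysis,
and the integrative consensus pTRT call with the imputed-vs-measured
validation correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bulkproc, enrich, flowgate, ptrtcall, scquant, spatial, tcr
from .simdata import Cohort, FLOW_MARKERS, PTRT_CLUSTER


@dataclass
class PipelineResult:
    sc_fraction: pd.Series
    sc_labels: pd.Series
    removed_contaminants: list
    dea: bulkproc.DeaResult
    gsea: enrich.EnrichmentResult
    signature_genes: list
    bulk_labels: pd.Series
    bulk_scores: pd.Series
    tcr_summary: pd.DataFrame
    flow_fractions: pd.Series
    flow_labels: pd.Series
    if_density: pd.Series
    if_labels: pd.Series
    calls: ptrtcall.PtrtCallSet
    validation: ptrtcall.CorrelationReport | None
    extras: dict = field(default_factory=dict)


def derive_signature(markers: pd.DataFrame, cluster: str = PTRT_CLUSTER,
                     min_log_fc: float = 0.5, top_n: int = 50) -> list[str]:
    """pTRT signature = strongest markers of the pTRT cluster, by log FC."""
    sub = markers[(markers["cluster"] == cluster) & (markers["log_fc"] > min_log_fc)]
    sub = sub.sort_values(["log_fc", "gene"], ascending=[False, True])
    return list(sub["gene"].head(top_n))


def analyze_cohort(
    cohort: Cohort,
    seed: int = 0,
    if_density_cut: float = 10.0,
    run_gsea: bool = True,
) -> PipelineResult:
    rng = np.random.default_rng(seed)

    # ---- single cell: QC, markers, abundance, classification -------------
    cells = scquant.qc_cells(cohort.sc_cells)
    expr = cohort.sc_counts[cells.index]
    tumor_cd8 = cells[(cells["compartment"] == "tumor") & (cells["lineage"] == "CD8")]
    markers = scquant.cluster_markers(
        expr[tumor_cd8.index], tumor_cd8["cluster_id"]
    )
    signature_genes = derive_signature(markers)
    sc_fraction = scquant.ptrt_fraction(cells, PTRT_CLUSTER)
    sc_labels = sc_fraction.map(scquant.classify_by_cluster_fraction)

    # ---- bulk: QC, decontamination, DEA, enrichment, classification ------
    bulk = bulkproc.qc_min_counts(cohort.bulk)
    is_t = bulk.sample_meta["population"].isin(["CD4", "CD8"])
    t_cells = bulk.subset_samples(bulk.sample_ids[is_t])
    cd45neg = bulk.subset_samples(
        bulk.sample_ids[bulk.sample_meta["population"] == "CD45neg"]
    )
    decon = bulkproc.contamination_filter(t_cells, cd45neg)
    t_clean = decon.filtered

    cd8 = t_clean.subset_samples(
        t_clean.sample_ids[t_clean.sample_meta["population"] == "CD8"]
    )
    tumor_ids = list(cd8.sample_ids[cd8.sample_meta["compartment"] == "tumor"])
    blood_ids = list(cd8.sample_ids[cd8.sample_meta["compartment"] == "blood"])
    groups = pd.Series(
        ["tumor" if s in set(tumor_ids) else "blood" for s in cd8.sample_ids],
        index=cd8.sample_ids,
    )
    kept = bulkproc.filter_by_expression(cd8, groups)
    dea = bulkproc.dea_two_group(cd8.subset_genes(kept), tumor_ids, blood_ids)

    gsea_res = None
    if run_gsea:
        sig_in_rank = [g for g in signature_genes if g in dea.table.index]
        sets = {"pTRT_signature": sig_in_rank} if len(sig_in_rank) >= 15 else {}
        for k in range(3):  # random control sets alongside the signature
            sets[f"random_{k}"] = list(
                rng.choice(dea.table.index, size=50, replace=False)
            )
        gsea_res = enrich.preranked_gsea(
            dea.table["t"], enrich.SignatureSet(sets), seed=rng
        )

    cd8_tumor = cd8.subset_samples(tumor_ids)
    lc = bulkproc.log_cpm(cd8_tumor, bulkproc.tmm_factors(cd8_tumor))
    bulk_cls = ptrtcall.bulk_signature_classifier(lc, signature_genes)
    pat_of = cd8_tumor.sample_meta["patient"]
    bulk_labels = bulk_cls.labels.rename(index=pat_of)
    bulk_scores = bulk_cls.scores.rename(index=pat_of)

    # ---- TCR repertoire ---------------------------------------------------
    clono = tcr.qc_repertoire(tcr.validate_clonotypes(cohort.clonotypes))
    units = {(p, c): counts for p, c, counts in tcr.repertoire_units(clono)}
    tcr_rows = []
    for pat in sorted({p for p, _ in units}):
        tum = units.get((pat, "tumor"))
        blood = units.get((pat, "blood"))
        row = {"patient": pat}
        if tum is not None:
            row["chao1_tumor"] = tcr.chao1(tum)
            _, _, row["expanded_cell_frac_tumor"] = tcr.clone_size_categories(tum)
        if blood is not None:
            row["chao1_blood"] = tcr.chao1(blood)
        if tum is not None and blood is not None:
            row["morisita"] = tcr.morisita_overlap(blood, tum)
            prop, k = tcr.top_expanded_tumor_exclusive(blood, tum)
            row["top15_tumor_exclusive"] = prop
            cls = tcr.expansion_classes(blood, tum)
            row["n_tumor_only_expanded"] = int((cls["class"] == "tumor-only expanded").sum())
        tcr_rows.append(row)
    tcr_summary = pd.DataFrame(tcr_rows).set_index("patient")
    viral_matches = tcr.match_antigen_db(clono, cohort.antigen_db)

    # ---- flow cytometry ---------------------------------------------------
    ev = flowgate.transform_events(cohort.events, list(FLOW_MARKERS))
    ev = flowgate.qc_and_downsample(ev, seed=rng)
    gate = [
        flowgate.GatePredicate("CD39", *_gate(cohort.truth.gate_thresholds["CD39"])),
        flowgate.GatePredicate("CCR7", *_gate(cohort.truth.gate_thresholds["CCR7"])),
    ]
    fr = flowgate.gate_fraction(ev, gate)
    tumor_rows = fr.index.str.endswith(":tumor")
    flow_fractions = fr.loc[tumor_rows, "fraction"]
    flow_fractions.index = [s.split(":")[0] for s in fr.index[tumor_rows]]
    flow_labels = flow_fractions.map(flowgate.classify_by_gate_fraction)

    # ---- spatial ----------------------------------------------------------
    if_density, pvn_rows = {}, []
    for scene in cohort.scenes:
        sc_q = spatial.qc_cells_spatial(scene)
        if not spatial.qc_scene(sc_q):
            continue
        area_mm2 = ((scene.window[2] - scene.window[0])
                    * (scene.window[3] - scene.window[1])) / 1e6
        n_ptrt = int((sc_q.cells["phenotype"] == "pTRT").sum())
        if_density[scene.scene_id] = n_ptrt / area_mm2
        summ = spatial.scene_pvn_summary(sc_q)
        if "pTRT" in summ.index:
            pvn_rows.append((scene.scene_id, summ.loc["pTRT", "pvn_fraction"]))
    if_density = pd.Series(if_density, dtype=float)
    if_labels = pd.Series(
        np.where(if_density > if_density_cut, "high", "low"), index=if_density.index
    ) if len(if_density) else pd.Series(dtype=object)
    pvn_fraction = pd.DataFrame(pvn_rows, columns=["scene", "ptrt_pvn_fraction"])

    # ---- integrative call -------------------------------------------------
    calls = pd.DataFrame({
        "sc": sc_labels, "bulk": bulk_labels, "flow": flow_labels, "if": if_labels,
    })
    callset = ptrtcall.consensus_call(calls)
    validation = None
    if len(sc_fraction) >= 3:
        try:
            validation = ptrtcall.impute_vs_measured(bulk_scores, sc_fraction)
        except ValueError:
            validation = None

    return PipelineResult(
        sc_fraction=sc_fraction,
        sc_labels=sc_labels,
        removed_contaminants=decon.removed_genes,
        dea=dea,
        gsea=gsea_res,
        signature_genes=signature_genes,
        bulk_labels=bulk_labels,
        bulk_scores=bulk_scores,
        tcr_summary=tcr_summary,
        flow_fractions=flow_fractions,
        flow_labels=flow_labels,
        if_density=if_density,
        if_labels=if_labels,
        calls=callset,
        validation=validation,
        extras={"markers": markers, "viral_matches": viral_matches,
                "pvn_fraction": pvn_fraction},
    )


def _gate(spec) -> tuple[str, float]:
    op, thr = spec
    return op, float(thr)
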