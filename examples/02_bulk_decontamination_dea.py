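"""Bulk RNA-seq processing: QC, the four-step tumor-contamination filter,
and tumor-vs-blood differential expression on sorted CD8 profiles.

Sorted T cell bulk profiles carry a contamination fraction of tumor-cell
(CD45-negative) transcripts; the filter intersects the CD45-negative
highest-expressed genes with those strongly enriched over T cells
(FC > 3, FDR < 0.001) and removes the union across disease groups.
"""

import pandas as pd

from braintil import SimConfig, simulate_cohort, bulkproc

cohort = simulate_cohort(SimConfig(n_patients=10, seed=5))
bulk = bulkproc.qc_min_counts(cohort.bulk)  # drop samples under 1e6 counts

is_t = bulk.sample_meta["population"].isin(["CD4", "CD8"])
t_cells = bulk.subset_samples(bulk.sample_ids[is_t])
cd45neg = bulk.subset_samples(
    bulk.sample_ids[bulk.sample_meta["population"] == "CD45neg"])

decon = bulkproc.contamination_filter(t_cells, cd45neg)
planted = set(cohort.truth.contamination_genes)
print(f"removed {len(decon.removed_genes)} contamination genes "
      f"({len(planted & set(decon.removed_genes))}/{len(planted)} planted ones)")

cd8 = decon.filtered.subset_samples(
    decon.filtered.sample_ids[decon.filtered.sample_meta["population"] == "CD8"])
# compare tumor vs blood within pTRT-high patients, where the signature is
# strongest (pooling pTRT-low patients dilutes the tumor-side enrichment)
high = set(cohort.truth.patients.index[
    cohort.truth.patients["ptrt_label"] == "high"])
cd8 = cd8.subset_samples(cd8.sample_ids[cd8.sample_meta["patient"].isin(high)])
tumor = list(cd8.sample_ids[cd8.sample_meta["compartment"] == "tumor"])
blood = list(cd8.sample_ids[cd8.sample_meta["compartment"] == "blood"])
groups = pd.Series(["tumor" if s in set(tumor) else "blood" for s in cd8.sample_ids],
                   index=cd8.sample_ids)
kept = bulkproc.filter_by_expression(cd8, groups)
dea = bulkproc.dea_two_group(cd8.subset_genes(kept), tumor, blood)
n_pass = int(dea.table["passed"].sum())
print(f"{len(dea.table)} genes tested, {n_pass} pass |FC|>2 & FDR<0.05")
print(dea.table.sort_values("p").head(5)[["log2fc", "p", "fdr", "passed"]])
# positive log2fc = higher in tumor CD8 cells; the top rows are the pTRT
# signature genes planted in tumor-infiltrating cells
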