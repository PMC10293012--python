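"""Simulate a small multi-modal brain-tumor cohort and write it to disk.

Every downstream example starts from a cohort like this one: matched
single-cell and bulk sorted-population counts, TCR beta repertoires, flow
events, and spatial scenes, with the planted pTRT-high/low ground truth
carried alongside.
"""

from braintil import SimConfig, simulate_cohort, write_cohort

config = SimConfig(n_patients=8, n_genes=800, n_cells_per_sample=200, seed=7)
cohort = simulate_cohort(config)

truth = cohort.truth.patients
print(truth)
print(f"\n{len(cohort.sc_counts.columns)} single cells, "
      f"{cohort.bulk.counts.shape[1]} bulk samples, "
      f"{len(cohort.clonotypes)} clonotype records, "
      f"{len(cohort.events)} flow events, {len(cohort.scenes)} spatial scenes")
# ptrt_label is the planted truth; true_fraction is each patient's share of
# CD8+ cells in the pTRT cluster (bimodal: <15% or >30%)

manifest = write_cohort(cohort, "scratch/example_cohort")
print(f"\nwrote {len(manifest)} files (see scratch/example_cohort/manifest.tsv)")
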