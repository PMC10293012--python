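# Methods

This note records the models, parameter choices, and numerical conventions
behind `braintil`, and what the synthetic-cohort tests do and do not
establish.

## The stratification problem

The package stratifies brain tumors by the abundance of potentially
tumor-reactive T (pTRT) cells — CD8⁺ TILs marked by *CXCL13*/CD39 expression,
exhaustion features, and local clonal expansion — among all CD8⁺ T cells.
Four assays yield the same quantity through different measurements:

1. **scRNA-seq**: fraction of CD8⁺ cells in the pTRT cluster; >30% → high,
   <15% → low, the band in between → `indeterminate` (observed cohorts are
   bimodal with an empty band, so the three-way return makes the unexpected
   case explicit instead of forcing a binary rule).
2. **bulk RNA-seq**: hierarchical clustering (Euclidean distance, complete
   linkage, tree cut at k=2) of sorted-CD8 samples on z-scored pTRT-signature
   genes; the cluster with the higher mean z is called high. If the cut
   yields a singleton cluster the classifier falls back to thresholding each
   sample's mean z at 0 and warns — real cohorts never produced this case.
3. **flow cytometry**: fraction of CD8⁺ events in the CD39⁺CCR7^low gate
   after arcsinh transform (cofactor 150); >30% → high (strict).
4. **spatial IF**: density of CD103⁺PD1⁺CD8⁺ cells per mm², thresholded at a
   configurable cutoff (default 10/mm², chosen to sit an order of magnitude
   between the simulated low (~1.5/mm²) and high (~25/mm²) regimes).

The consensus is unanimity over informative labels: any high/low disagreement
is reported as `discordant`, indeterminate-only as `insufficient`. The
concordance rate counts patients with ≥2 informative modalities whose labels
all agree.

"Imputed pTRT frequency" from bulk data has no published closed form; it is
operationalized as the mean z-score over signature genes and validated only
through its monotone association (Pearson r) with directly measured
fractions, which is the readout the approach is used for.

## Synthetic cohort (`simdata`)

The generator states a world; its defaults are fixed and none of them were
adjusted after seeing test results.

* **Cohort**: 24 patients, glioma:BrM mix 3:7/4:7 (matching a 36:48 cohort),
  BrM patients pTRT-high with probability 0.5, gliomas never high.
* **pTRT fractions**: Beta(4, 76) for low (mean 0.05) and Beta(36, 44) for
  high (mean 0.45), truncated outside the 15–30% band by resampling — the
  observed distribution is bimodal with no sample between the two cutoffs.
* **Single-cell counts**: negative binomial (gamma–Poisson, dispersion 0.5)
  around cluster-specific mean vectors; the pTRT cluster (C3) overexpresses
  30 planted signature genes by 2 log₂ units; two background clusters carry
  10 planted marker genes each (×4). Per-cell depth is log-normal around
  3,000 counts over 2,000 genes. Blood compartments contain ~1% pTRT cells.
* **Bulk profiles**: the CD8 profile is the literal sum of that patient's
  simulated CD8 cells; tumor-sorted CD8 additionally receives a binomial
  thinning (rate = `contamination_rate`, default 0.1) of the patient's
  CD45⁻ profile. Twenty planted contamination genes are silent in T cells
  and ~50× the median in CD45⁻ cells, so they are both top-ranked by CD45⁻
  expression and strongly differential — exactly the genes the four-step
  filter is built to remove. CD4/MG/MDM/CD45⁻ profiles are direct bulk NB
  draws (dispersion 0.05) at ~1.3M library size, safely above the 10⁶ QC cut.
* **TCR**: Zipf clone sizes (exponent 1.5) over 120 tumor / 200 blood
  clonotypes per patient. In pTRT-high patients the 10 largest tumor clones
  are absent from blood (local expansion); in pTRT-low patients the top
  clones are planted into blood at half size (dual expansion) and 2–4 viral
  clonotypes from the synthetic antigen database are planted in both
  compartments. The database carries score-0 decoys that must never match.
* **Flow**: each marker is a two-component log-normal mixture (positive
  ~900, negative ~20, σ=0.4 on the log scale); pTRT events are CD39⁺ (97%)
  and CCR7⁻ (97%). The generator emits its own gate thresholds (the
  geometric-midpoint intensity, arcsinh-transformed) so gating tests are
  closed-loop; spillover/compensation is not modeled (acquisition-side).
* **Spatial**: 1 mm² scenes with 8 disc vessels (radius 10–30 µm); pTRT
  cells are placed by rejection sampling with `pvn_enrichment` (default 3)
  odds of landing within the 15-µm perivascular buffer; all other phenotypes
  are uniform. Diameters ~N(8.5, 1.8) µm and detection probabilities
  ~Beta(8, 2) deliberately straddle the QC cuts.
* **Seeding**: one global seed expands through `SeedSequence.spawn` into
  per-modality substreams (patients, genes, scRNA, bulk, TCR, flow,
  spatial), so identical configs give bit-identical cohorts and changing one
  modality's parameters leaves the others' draws untouched.

What a green recovery test establishes: the pipeline's statistics recover
structure of exactly the kind and magnitude planted. What it does not:
robustness to transcriptome-wide gene–gene correlation, batch structure,
doublets, segmentation errors, spectral spillover, or clonotype sequencing
error — none of which the generator emulates.

## Numerical conventions

* **TMM**: reference sample = 75th-percentile count fraction closest to the
  mean; M/A computed on genes positive in both samples; 30% two-sided trim on
  M, 5% on A; inverse delta-method variance weights; factors normalized to
  geometric mean 1. Verified against edgeR's `calcNormFactors` to 1e-7 on a
  frozen instance.
* **log-CPM**: `log2((count + 0.5) / (libsize × factor) × 1e6)`.
* **Expression filter**: count ≥10 in at least min-group-size samples and
  row total ≥15 (the cited filter's published defaults; the source states
  none).
* **Moderated t**: per-gene two-group OLS on log-CPM; variances shrunk via a
  scaled inverse-chi-square prior fitted by method of moments on log
  variances (digamma/trigamma inversion); t referred to `df_resid + d0`
  (normal when d0 = ∞). This is a calibration-level emulation of the
  standard empirical-Bayes pipeline, not a precision-weighted (voom)
  reimplementation; its contract is a null pass rate at or below the nominal
  FDR and planted-effect recovery.
* **Contamination filter**: FC > 3 is interpreted as log₂FC > log₂3 (the
  scale is unstated in the source description); "highest absolute
  expression" uses mean log₂-CPM; step 2 pools blood and tumor T cells;
  disease groups are the coarse glioma/BrM labels.
* **GSEA**: hit increments ∝ |stat|^weight (weight 1 by default), uniform
  miss decrements; ES = signed extremum of the running sum, ties toward the
  positive peak; p-value against random same-size gene sets (same-sign
  tail), floored at 1/(n_perm+1); NES = ES over the mean |ES| of same-sign
  permutations; sets outside [15, 500] after intersection are flagged
  excluded. The extremum is evaluated only at hit positions (where the
  running sum's local extrema live), which makes the permutation null
  vectorizable; a gene-by-gene brute-force oracle checks exactness.
* **Module score**: 24 equal-frequency bins on average expression, 100
  control genes per signature gene drawn with replacement from the gene's
  bin (the cited scoring function's published defaults).
* **Boundaries**: every published exclusion threshold keeps its quoted
  strictness — sample counts <10⁶ excluded, mito <10% strict, features
  250–3,000 inclusive (the en-dash range is read as closed), <20 unique
  clonotypes excluded, <100 events excluded, <30 CD8 cells excluded,
  spatial diameter/probability strict, PVN boundary inclusive (a 15-µm
  expansion is a closed buffer), abundance cutoffs strict (>30%, <15%).
* **Ties**: top-N gene selections break ties lexicographically by gene ID;
  tumor clone ranking breaks count ties by junction string; linkage input is
  ordered by sample ID.
* **Distances**: centroid-to-centroid Euclidean; KD-tree acceleration is
  used for neighborhoods but must (and does, by test) equal brute force.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `contamination_rate` | 0.1 | fraction of CD45⁻ transcripts admixed into tumor-sorted CD8 bulk |
| `signature_log2fc` | 2.0 | planted pTRT signature effect; recovery properties assume ≥1.5 |
| `clone_zipf_exponent` | 1.5 | clone-size power law; larger → flatter repertoires |
| `pvn_enrichment` | 3.0 | odds multiplier for pTRT placement within 15 µm of vessels |
| `noise_dispersion` | 0.5 | single-cell NB dispersion (1/shape) |
| `expand_min_count` | 2 | count threshold defining "expanded" in a compartment (unstated in the source; surfaced as a parameter) |
| GSEA `n_perm` | 1000 | permutation count; p floor 1/(n_perm+1) |

## Known limitations

* Clustering/embedding of single cells is out of scope: cluster labels are
  inputs (ground truth in simulation, user-supplied otherwise).
* The bulk DEA has no batch covariates or multi-factor designs.
* Vessels are discs; polygonal vessel support would require only replacing
  `vessel_distance`.
* Clonotype identity is the CDR3β amino-acid junction; V/J genes are carried
  as annotation but do not enter matching or overlap.
* The five published neoantigen-reactivity signatures live in supplementary
  material not shipped here; signature sets are user inputs (GMT/TSV), and
  the pipeline derives its working signature from the simulated pTRT
  cluster's own markers.
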