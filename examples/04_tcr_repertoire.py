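"""TCR beta repertoire statistics for one patient pair of compartments.

Chao1 estimates a lower bound on total clonotype richness; the clone-size
categories and blood/tumor expansion classes describe how concentrated the
repertoire is and where expansion happened; Morisita-Horn measures
abundance-weighted blood-tumor overlap.
"""

from braintil import SimConfig, simulate_cohort, tcr

cohort = simulate_cohort(SimConfig(n_patients=8, seed=9))
table = tcr.qc_repertoire(tcr.validate_clonotypes(cohort.clonotypes))
units = {(p, c): u for p, c, u in tcr.repertoire_units(table)}

truth = cohort.truth.patients
for label in ("high", "low"):
    pid = truth.index[truth["ptrt_label"] == label][0]
    tum, blood = units[(pid, "tumor")], units[(pid, "blood")]
    _, _, expanded = tcr.clone_size_categories(tum)
    prop, k = tcr.top_expanded_tumor_exclusive(blood, tum)
    print(f"{pid} (pTRT-{label}): Chao1 tumor {tcr.chao1(tum):.0f}, "
          f"expanded-cell fraction {expanded:.2f}, "
          f"top-{k} tumor-exclusive {prop:.2f}, "
          f"Morisita blood-tumor {tcr.morisita_overlap(blood, tum):.3f}")
# pTRT-high patients: the most-expanded tumor clones are absent from blood
# (local expansion); pTRT-low patients share their top clones with blood

matches = tcr.match_antigen_db(table, cohort.antigen_db)
print(f"\n{len(matches)} clonotype-antigen matches at score >= 1 "
      f"(species: {sorted(matches['species'].unique())})")
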