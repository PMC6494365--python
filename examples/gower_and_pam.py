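"""Mixed-type Gower dissimilarities and k-medoids (PAM) on a small cohort."""

import numpy as np

import phenoclust as pc

cohort = pc.generate_cohort(pc.bsi_cohort_spec(120, seed=7))
table = pc.apply_transforms(cohort.table)  # ln(1+x) on flagged durations

D = pc.gower_matrix(table)
print(f"Gower matrix: {D.n} x {D.n}, entries in "
      f"[{D.values.min():.3f}, {D.values.max():.3f}]")

res = pc.pam(D, k=4)
print("medoid patients:", [D.patient_ids[m] for m in res.medoids])
print("cluster sizes:", np.bincount(res.labels).tolist())
print("total within-cluster dissimilarity:", round(res.cost, 2))
ari = pc.adjusted_rand_index(res.labels, cohort.true_labels)
print(f"agreement with planted phenotypes (ARI): {ari:.3f}")
# ARI near 1 means a single deterministic PAM run already recovers the
# planted structure; consensus resampling (next example) quantifies how
# stable that recovery is.
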