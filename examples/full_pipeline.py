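"""The whole pipeline as one configured, reproducible run writing a run
directory of artifacts (matrices, labels, reports, figures)."""

import json
from pathlib import Path

import phenoclust as pc

cohort = pc.generate_cohort(pc.bsi_cohort_spec(300, seed=2024))

cfg = pc.RunConfig(
    k_min=2, k_max=9,
    n_reps=60,                 # reference setting: 1000
    subsample_fraction=0.8,
    reduce=True,
    seed=2024,
    out_dir="scratch/example_run",
)
result = pc.run_pipeline(cfg, table=cohort.table, outcomes=cohort.outcomes)

print(f"selected k = {result.selected_k}")
print("PAC by k:", {k: round(v, 3) for k, v in result.pac_by_k.items()})
print("warnings/flags:", list(result.flags) or "none")
manifest = json.loads((result.run_dir / "manifest.json").read_text())
print(f"artifacts in {result.run_dir}:")
for p in sorted(Path(result.run_dir).iterdir()):
    print("  ", p.name)
# Re-running with the same config reproduces every matrix, label file and
# report byte-for-byte; the manifest records the full configuration.
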