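"""End-to-end orchestration: transform -> Gower -> consensus sweep -> PAC
model selection -> validity -> optional feature reduction, written to a run
directory as machine-readable artifacts (TSV matrices, JSON reports, PNG
figures) plus a manifest that makes the run exactly reproducible.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .consensus import run_sweep
from .gower import gower_matrix
from .model_selection import delta_area, select_k
from .reduction import reduce_features
from .schema_io import (
    FeatureTable,
    OutcomeTable,
    apply_transforms,
    read_feature_table,
    read_outcome_table,
)
from .validity import validity_report

log = logging.getLogger("phenoclust")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """All knobs of a pipeline run; defaults are the reference settings
    (80% subsampling, 1000 repetitions, k searched over 2..9)."""

    table_path: str | None = None
    schema_path: str | None = None
    outcomes_path: str | None = None
    k_min: int = 2
    k_max: int = 9
    n_reps: int = 1000
    subsample_fraction: float = 0.8
    pac_interval: tuple[float, float] = (0.1, 0.9)
    final_method: str = "pam"
    reduce: bool = False
    assoc_threshold: float = 0.1
    ari_threshold: float = 0.9
    yates_2x2: bool = False
    make_plots: bool = True
    seed: int = 0
    out_dir: str = "phenoclust_run"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pac_interval"] = list(self.pac_interval)
        return d


@dataclass
class PipelineResult:
    config: RunConfig
    selected_k: int
    pac_by_k: dict[int, float]
    final_labels: np.ndarray
    purified_labels: np.ndarray
    run_dir: Path
    flags: tuple[str, ...]


def _write_labels(path: Path, patient_ids, labels) -> None:
    pd.DataFrame({"id": patient_ids, "cluster": labels}).to_csv(path, index=False)


def run_pipeline(
    config: RunConfig,
    table: FeatureTable | None = None,
    outcomes: OutcomeTable | None = None,
) -> PipelineResult:
    """Run the full phenotyping pipeline and populate ``config.out_dir``.

    Inputs may be passed in memory or read from the paths in the config.
    Identical configs (and inputs) produce byte-identical matrices, labels
    and reports. On any stage failure a FAILED marker naming the stage is
    left in the run directory and the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if table is None:
            table = read_feature_table(config.table_path, config.schema_path)
        if outcomes is None and config.outcomes_path:
            outcomes = read_outcome_table(config.outcomes_path)
        manifest = {
            "phenoclust_version": __version__,
            "config": config.to_dict(),
            "n_patients": table.n_patients,
            "n_features": table.n_features,
        }

        stage = "transform"
        if not table.schema.transforms_applied:
            table = apply_transforms(table)

        stage = "gower"
        log.info("computing Gower matrix for %d patients", table.n_patients)
        D = gower_matrix(table)
        D.save_tsv(out / "gower_matrix.tsv")

        stage = "consensus_sweep"
        log.info("consensus sweep k=%d..%d, %d reps", config.k_min, config.k_max,
                 config.n_reps)
        sweep = run_sweep(
            D, config.k_min, config.k_max, n_reps=config.n_reps,
            fraction=config.subsample_fraction, seed=config.seed,
            final_method=config.final_method,
        )
        for k, run in sweep.runs.items():
            pd.DataFrame(run.consensus, index=D.patient_ids,
                         columns=D.patient_ids).to_csv(
                out / f"consensus_k{k}.tsv", sep="\t")

        stage = "model_selection"
        flags: list[str] = []
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            profile = select_k(sweep, *config.pac_interval)
        for w in caught:
            log.warning("%s", w.message)
        flags.extend(profile.flags)
        best = sweep.runs[profile.selected_k]
        pac_payload = {
            "pac_by_k": {str(k): v for k, v in profile.pac_by_k.items()},
            "interval": list(profile.interval),
            "selected_k": profile.selected_k,
            "flags": list(profile.flags),
            "delta_area": (
                {str(k): v for k, v in delta_area(sweep).items()}
                if len(sweep.ks) > 1 else {}
            ),
        }
        (out / "pac_profile.json").write_text(json.dumps(pac_payload, indent=2) + "\n")
        _write_labels(out / "final_labels.csv", table.patient_ids, best.final_labels)

        stage = "validity"
        purified = best.final_labels
        if outcomes is not None:
            report = validity_report(table, outcomes, best.consensus,
                                     best.final_labels, config.yates_2x2)
            report.save_json(out / "validity_report.json")
            purified = report.purified_labels
            _write_labels(out / "purified_labels.csv", table.patient_ids, purified)
            for name, res in report.outcome_tables.items():
                res.table.to_csv(out / f"outcome_{name}.tsv", sep="\t")
            for w in sum((list(r.warnings) for r in report.outcome_tables.values()), []):
                flags.append(f"sparse_contingency:{w}")
        else:
            report = None

        stage = "reduction"
        if config.reduce:
            trace = reduce_features(
                table, profile.selected_k,
                assoc_threshold=config.assoc_threshold,
                ari_threshold=config.ari_threshold,
                n_reps=config.n_reps, fraction=config.subsample_fraction,
                seed=config.seed,
            )
            (out / "reduction_trace.json").write_text(
                json.dumps(trace.to_dict(), indent=2) + "\n")

        stage = "plots"
        if config.make_plots:
            from . import plots

            plots.plot_consensus_heatmap(best, out / "consensus_heatmap.png")
            if len(sweep.ks) > 1:
                plots.plot_consensus_cdfs(sweep, out / "consensus_cdfs.png")
                plots.plot_delta_area(sweep, out / "delta_area.png")
            plots.plot_pac_curve(profile, out / "pac_curve.png")
            if report is not None:
                plots.plot_item_consensus(report.item_consensus,
                                          out / "item_consensus.png")

        manifest["selected_k"] = profile.selected_k
        manifest["flags"] = flags
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    except Exception as e:
        (out / "FAILED").write_text(f"stage={stage}: {e}\n")
        raise

    return PipelineResult(
        config=config,
        selected_k=profile.selected_k,
        pac_by_k=profile.pac_by_k,
        final_labels=best.final_labels,
        purified_labels=purified,
        run_dir=out,
        flags=tuple(flags),
    )
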