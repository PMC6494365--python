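"""Item-level consensus, outlier purification, and cluster validity reports.

A patient's *item consensus* is its mean pairwise consensus with the other
members of its assigned cluster; members sitting more than 2 SDs below their
cluster's mean item consensus are the least representative admissions and
are flagged as outliers. *Purification* removes (marks unassigned) the
outliers without reassigning anyone else.

Content validity is reported as per-cluster feature summaries (proportions
for binary/categorical, median+IQR and mean+SD for continuous, on the
untransformed scale so the tables read clinically); predictive validity as
cluster x outcome contingency tables with Pearson chi-square tests, computed
both before and after purification.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .schema_io import FeatureTable, OutcomeTable

__all__ = [
    "UNASSIGNED",
    "ItemConsensus",
    "OutlierReport",
    "ChiSquareResult",
    "ValidityReport",
    "item_consensus",
    "detect_outliers",
    "purify",
    "phenotype_summary",
    "cross_cluster_distribution",
    "outcome_comparison",
    "validity_report",
]

#: label for patients removed by purification
UNASSIGNED = -1


@dataclass(frozen=True)
class ItemConsensus:
    values: np.ndarray  # per patient, in [0, 1]
    labels: np.ndarray


@dataclass(frozen=True)
class OutlierReport:
    cluster_means: dict[int, float]
    cluster_sds: dict[int, float]
    outlier_flags: np.ndarray
    outlier_counts: dict[int, int]
    outlier_fractions: dict[int, float]
    purified_labels: np.ndarray


@dataclass(frozen=True)
class ChiSquareResult:
    table: pd.DataFrame
    statistic: float
    df: int
    p_value: float
    warnings: tuple[str, ...] = ()


def item_consensus(M: np.ndarray, labels: np.ndarray) -> ItemConsensus:
    """Mean consensus of each patient with its co-members (self excluded).

    Members of singleton clusters get 1 by convention (no co-member to
    disagree with).
    """
    M = np.asarray(M, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    if M.shape != (n, n):
        raise ValueError("labels do not match the consensus matrix")
    values = np.ones(n)
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if members.size < 2:
            continue
        sub = M[np.ix_(members, members)]
        values[members] = (sub.sum(axis=1) - np.diag(sub)) / (members.size - 1)
    return ItemConsensus(values=values, labels=labels.copy())


def detect_outliers(ic: ItemConsensus) -> OutlierReport:
    """Flag members whose item consensus is below (cluster mean - 2 SD).

    SD uses the n-1 denominator; clusters of size < 3 (SD undefined or
    degenerate) yield no outliers, as does SD = 0.
    """
    labels = ic.labels
    flags = np.zeros(len(labels), dtype=bool)
    means: dict[int, float] = {}
    sds: dict[int, float] = {}
    counts: dict[int, int] = {}
    fracs: dict[int, float] = {}
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        v = ic.values[members]
        mean = float(v.mean())
        sd = float(v.std(ddof=1)) if members.size >= 2 else 0.0
        means[int(c)] = mean
        sds[int(c)] = sd
        if members.size >= 3 and sd > 0:
            flags[members] = v < mean - 2.0 * sd
        counts[int(c)] = int(flags[members].sum())
        fracs[int(c)] = counts[int(c)] / members.size
    purified = np.where(flags, UNASSIGNED, labels)
    return OutlierReport(
        cluster_means=means,
        cluster_sds=sds,
        outlier_flags=flags,
        outlier_counts=counts,
        outlier_fractions=fracs,
        purified_labels=purified,
    )


def purify(labels: np.ndarray, report: OutlierReport) -> np.ndarray:
    """Mark flagged outliers unassigned; every retained label is unchanged."""
    labels = np.asarray(labels)
    if len(labels) != len(report.outlier_flags):
        raise ValueError("labels do not match the outlier report")
    return np.where(report.outlier_flags, UNASSIGNED, labels)


def phenotype_summary(table: FeatureTable, labels: np.ndarray) -> dict:
    """Per cluster x feature content summary.

    Binary/categorical: within-cluster proportion per level with the
    non-missing denominator; continuous: median + IQR and mean + SD.
    Unassigned (purified) patients are excluded.
    """
    labels = np.asarray(labels)
    if len(labels) != table.n_patients:
        raise ValueError("labels do not match the table")
    out: dict = {}
    for c in sorted(int(x) for x in np.unique(labels) if x != UNASSIGNED):
        members = np.flatnonzero(labels == c)
        cl: dict = {"n": int(members.size)}
        for spec in table.schema.features:
            col = table.values[spec.name].iloc[members]
            obs = col.dropna()
            entry: dict = {"n_observed": int(len(obs))}
            if spec.kind == "continuous":
                if len(obs):
                    x = obs.to_numpy(dtype=float)
                    q1, med, q3 = np.percentile(x, [25, 50, 75])
                    entry.update(
                        median=float(med), iqr=(float(q1), float(q3)),
                        mean=float(x.mean()),
                        sd=float(x.std(ddof=1)) if len(x) > 1 else 0.0,
                    )
            elif spec.kind == "binary":
                entry["proportion"] = float(obs.mean()) if len(obs) else None
            else:
                entry["proportions"] = (
                    obs.value_counts(normalize=True).to_dict() if len(obs) else {}
                )
            cl[spec.name] = entry
        out[c] = cl
    return out


def cross_cluster_distribution(indicator: np.ndarray, labels: np.ndarray) -> dict:
    """Share of indicator-positive patients falling in each cluster.

    The row sums to 1 over clusters; zero positives yield an explicitly
    flagged undefined row.
    """
    indicator = np.asarray(indicator, dtype=float)
    labels = np.asarray(labels)
    if len(indicator) != len(labels):
        raise ValueError("indicator does not match labels")
    assigned = labels != UNASSIGNED
    pos = (indicator == 1.0) & assigned
    clusters = sorted(int(x) for x in np.unique(labels[assigned]))
    total = int(pos.sum())
    if total == 0:
        return {"defined": False, "shares": {c: None for c in clusters}}
    return {
        "defined": True,
        "shares": {c: float(((labels == c) & pos).sum() / total) for c in clusters},
    }


def _chi_square(table: pd.DataFrame, yates: bool) -> ChiSquareResult:
    obs = table.to_numpy(dtype=float)
    correction = yates and obs.shape == (2, 2)
    stat, p, df, expected = chi2_contingency(obs, correction=correction)
    warns: list[str] = []
    if (expected < 1).any():
        warns.append("expected cell count < 1; chi-square approximation unreliable")
    return ChiSquareResult(
        table=table, statistic=float(stat), df=int(df), p_value=float(p),
        warnings=tuple(warns),
    )


def outcome_comparison(
    outcomes: OutcomeTable,
    labels: np.ndarray,
    yates_2x2: bool = False,
) -> dict[str, ChiSquareResult]:
    """Cluster x mortality and cluster x disposition contingency + chi-square.

    Unassigned patients are excluded. No continuity correction by default
    (``yates_2x2`` enables Yates for 2x2 tables only).
    """
    labels = np.asarray(labels)
    if len(labels) != len(outcomes.patient_ids):
        raise ValueError("labels do not match outcomes")
    assigned = labels != UNASSIGNED
    if len(np.unique(labels[assigned])) < 2:
        raise ValueError("need at least 2 clusters for outcome comparison")
    lab = pd.Series(labels[assigned], name="cluster")
    mort = pd.Series(np.asarray(outcomes.mortality)[assigned], name="mortality")
    disp = pd.Series(np.asarray(outcomes.disposition, dtype=object)[assigned],
                     name="disposition")
    results = {
        "mortality": _chi_square(pd.crosstab(lab, mort), yates_2x2),
        "disposition": _chi_square(pd.crosstab(lab, disp), yates_2x2),
    }
    for name, res in results.items():
        for w in res.warnings:
            warnings.warn(f"{name}: {w}", UserWarning, stacklevel=2)
    return results


@dataclass(frozen=True)
class ValidityReport:
    """Everything the validity stage produces, serialisable to JSON."""

    item_consensus: ItemConsensus
    outliers: OutlierReport
    purified_labels: np.ndarray
    phenotype: dict
    phenotype_purified: dict
    outcome_tables: dict[str, ChiSquareResult]
    purified_outcome_tables: dict[str, ChiSquareResult]

    def to_dict(self) -> dict:
        def chisq(d: dict[str, ChiSquareResult]) -> dict:
            return {
                name: {
                    "table": {str(k): v for k, v in r.table.to_dict().items()},
                    "statistic": r.statistic,
                    "df": r.df,
                    "p_value": r.p_value,
                    "warnings": list(r.warnings),
                }
                for name, r in d.items()
            }

        return {
            "item_consensus": self.item_consensus.values.tolist(),
            "cluster_mean_consensus": self.outliers.cluster_means,
            "cluster_sd_consensus": self.outliers.cluster_sds,
            "outlier_counts": self.outliers.outlier_counts,
            "outlier_fractions": self.outliers.outlier_fractions,
            "purified_labels": self.purified_labels.tolist(),
            "phenotype_summary": self.phenotype,
            "phenotype_summary_purified": self.phenotype_purified,
            "outcome_tables": chisq(self.outcome_tables),
            "purified_outcome_tables": chisq(self.purified_outcome_tables),
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=str) + "\n")


def validity_report(
    table: FeatureTable,
    outcomes: OutcomeTable,
    M: np.ndarray,
    labels: np.ndarray,
    yates_2x2: bool = False,
) -> ValidityReport:
    """Full validity stage: item consensus -> outliers -> purification ->
    content and predictive validity on original and purified labels."""
    outcomes.check_alignment(table)
    ic = item_consensus(M, labels)
    rep = detect_outliers(ic)
    purified = purify(labels, rep)
    return ValidityReport(
        item_consensus=ic,
        outliers=rep,
        purified_labels=purified,
        phenotype=phenotype_summary(table, labels),
        phenotype_purified=phenotype_summary(table, purified),
        outcome_tables=outcome_comparison(outcomes, labels, yates_2x2),
        purified_outcome_tables=outcome_comparison(outcomes, purified, yates_2x2),
    )
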