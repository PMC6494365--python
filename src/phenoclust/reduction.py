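"""Stability-checked feature reduction.

Features that are (near-)identically distributed across the clusters carry
no clustering signal; dropping them yields a more parsimonious model. The
loop scores each feature's association with the current cluster labels —
Cramér's V for binary/categorical, rank-based epsilon-squared
(Kruskal–Wallis) for continuous, both in [0, 1] — tentatively drops every
feature scoring below ``assoc_threshold``, re-clusters, and accepts the drop
only if the adjusted Rand index between old and new final labels stays at or
above ``ari_threshold``. A rejected drop is backtracked by restoring the
most-associated half of the drop set and retrying. A floor of 3 features is
never crossed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, kruskal
from sklearn.metrics import adjusted_rand_score

from .consensus import run_consensus
from .gower import gower_matrix
from .schema_io import FeatureTable
from .validity import UNASSIGNED

__all__ = [
    "ReductionTrace",
    "feature_cluster_association",
    "adjusted_rand_index",
    "reduce_features",
]

MIN_FEATURES = 3


def adjusted_rand_index(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Chance-corrected partition agreement; 1 for identical partitions.

    Patients unassigned in either labelling are excluded pairwise (cluster
    ids are arbitrary, so raw agreement would be meaningless).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings cover different patient sets")
    keep = (a != UNASSIGNED) & (b != UNASSIGNED)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 patients in common")
    return float(adjusted_rand_score(a[keep], b[keep]))


def _cramers_v(x: pd.Series, labels: np.ndarray) -> float:
    # positional arrays: a raw Series would align crosstab on its index
    tab = pd.crosstab(
        pd.Series(np.asarray(labels), name="cluster"),
        pd.Series(np.asarray(x), name="feature"),
    )
    tab = tab.loc[:, tab.sum(axis=0) > 0]
    if min(tab.shape) < 2:
        return 0.0  # constant feature (or single cluster): no association
    chi2 = chi2_contingency(tab.to_numpy(), correction=False)[0]
    n = tab.to_numpy().sum()
    v2 = chi2 / (n * (min(tab.shape) - 1))
    return float(np.sqrt(min(max(v2, 0.0), 1.0)))


def _epsilon_squared(x: pd.Series, labels: np.ndarray) -> float:
    groups = [x.iloc[labels == c].to_numpy(dtype=float)
              for c in np.unique(labels)]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2 or np.ptp(np.concatenate(groups)) == 0:
        return 0.0
    try:
        h = kruskal(*groups).statistic
    except ValueError:  # all values identical
        return 0.0
    n = sum(g.size for g in groups)
    eps2 = h / (n - 1)  # H * (n+1) / (n^2 - 1)
    return float(min(max(eps2, 0.0), 1.0))


def feature_cluster_association(table: FeatureTable, labels: np.ndarray) -> dict[str, float]:
    """Per-feature association with the cluster labels, each in [0, 1].

    Missing values are excluded per feature; constant features score 0.
    """
    labels = np.asarray(labels)
    if len(labels) != table.n_patients:
        raise ValueError("labels do not match the table")
    assigned = labels != UNASSIGNED
    if len(np.unique(labels[assigned])) < 2:
        raise ValueError("need at least 2 clusters")
    scores: dict[str, float] = {}
    for spec in table.schema.features:
        col = table.values[spec.name]
        obs = col.notna().to_numpy() & assigned
        x = col[obs]
        lab = labels[obs]
        if x.nunique(dropna=True) < 2:
            scores[spec.name] = 0.0
            continue
        if spec.kind == "continuous":
            scores[spec.name] = _epsilon_squared(x, lab)
        else:
            scores[spec.name] = _cramers_v(x, lab)
    return scores


@dataclass(frozen=True)
class ReductionIteration:
    dropped: tuple[str, ...]
    scores: dict[str, float]
    ari: float
    accepted: bool


@dataclass(frozen=True)
class ReductionTrace:
    iterations: tuple[ReductionIteration, ...]
    final_features: tuple[str, ...]
    final_labels: np.ndarray

    def to_dict(self) -> dict:
        return {
            "iterations": [
                {
                    "dropped": list(it.dropped),
                    "scores": it.scores,
                    "ari": it.ari,
                    "accepted": it.accepted,
                }
                for it in self.iterations
            ],
            "final_features": list(self.final_features),
        }


def _default_cluster(table: FeatureTable, k: int, n_reps: int, fraction: float,
                     seed: int) -> np.ndarray:
    return run_consensus(gower_matrix(table), k, n_reps=n_reps,
                         fraction=fraction, seed=seed).final_labels


def reduce_features(
    table: FeatureTable,
    k: int,
    assoc_threshold: float = 0.1,
    ari_threshold: float = 0.9,
    n_reps: int = 100,
    fraction: float = 0.8,
    seed: int = 0,
    cluster_fn: Callable[[FeatureTable], np.ndarray] | None = None,
) -> ReductionTrace:
    """Iteratively drop low-association features while the clustering holds.

    ``cluster_fn`` maps a feature table to final labels; the default is a
    consensus run at the given k. Each outer iteration clusters the current
    table, drops all features scoring below ``assoc_threshold`` (never past
    the 3-feature floor), re-clusters, and accepts iff ARI(old, new) >=
    ``ari_threshold``; otherwise the most-associated half of the drop set is
    restored and the smaller drop retried.
    """
    if cluster_fn is None:
        cluster_fn = lambda t: _default_cluster(t, k, n_reps, fraction, seed)

    current = table
    labels = np.asarray(cluster_fn(current))
    iterations: list[ReductionIteration] = []
    while True:
        scores = feature_cluster_association(current, labels)
        candidates = sorted(
            (name for name, s in scores.items() if s < assoc_threshold),
            key=lambda name: scores[name],
        )
        max_droppable = current.n_features - MIN_FEATURES
        candidates = candidates[: max(max_droppable, 0)]
        if not candidates:
            if not iterations:
                iterations.append(
                    ReductionIteration(dropped=(), scores=scores, ari=1.0, accepted=True)
                )
            break
        accepted = False
        drop = list(candidates)
        while drop:
            keep = [n for n in current.schema.names if n not in set(drop)]
            reduced = current.subset(keep)
            new_labels = np.asarray(cluster_fn(reduced))
            ari = adjusted_rand_index(labels, new_labels)
            ok = ari >= ari_threshold
            iterations.append(
                ReductionIteration(dropped=tuple(drop), scores=scores,
                                   ari=ari, accepted=ok)
            )
            if ok:
                current = reduced
                labels = new_labels
                accepted = True
                break
            # restore the most-associated half (tail of the sorted drop set)
            drop = drop[: len(drop) // 2]
        if not accepted:
            break
    return ReductionTrace(
        iterations=tuple(iterations),
        final_features=tuple(current.schema.names),
        final_labels=labels,
    )
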