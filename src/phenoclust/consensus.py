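"""Subsampled consensus clustering around PAM.

For each candidate number of clusters k, the cohort is subsampled (default
80% of patients, without replacement) ``n_reps`` times (default 1000); each
subsample is clustered by PAM on the corresponding slice of the precomputed
Gower matrix; and for every patient pair the engine tracks how often the two
were drawn together (co-sampling count) and, of those runs, how often they
landed in the same cluster. The consensus matrix is the elementwise ratio —
the proportion of co-sampled runs in which the pair co-clusters (Monti-style
indicator normalisation). Stable structure drives entries towards 0 or 1.

Final labels come from running PAM on ``1 - M`` (treating consensus as
similarity), keeping the base learner consistent throughout; average-linkage
hierarchical clustering of ``1 - M`` is available as an alternative for
parity with consensus-clustering packages that default to it.

Randomness: one master seed; the RNG for repetition r at cluster count k is
``numpy.random.default_rng([seed, k, r])``, so per-k results are independent
of sweep order and reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .gower import DissimilarityMatrix, gower_matrix
from .pam import pam
from .schema_io import FeatureTable

__all__ = [
    "ConsensusRun",
    "ConsensusSweep",
    "subsample_indices",
    "rep_rng",
    "run_consensus",
    "run_sweep",
]


@dataclass(frozen=True)
class ConsensusRun:
    """Consensus matrix and final assignment for one value of k."""

    k: int
    consensus: np.ndarray
    cosample_counts: np.ndarray
    final_labels: np.ndarray
    n_reps: int
    subsample_fraction: float

    @property
    def n(self) -> int:
        return self.consensus.shape[0]


@dataclass(frozen=True)
class ConsensusSweep:
    """ConsensusRun per k over a contiguous range, sharing one patient set."""

    runs: dict[int, ConsensusRun]
    patient_ids: tuple[str, ...]
    seed: int

    @property
    def ks(self) -> list[int]:
        return sorted(self.runs)


def subsample_indices(n: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """floor(fraction*n) distinct indices, uniform without replacement, sorted."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    m = int(np.floor(fraction * n))
    return np.sort(rng.choice(n, size=m, replace=False))


def rep_rng(seed: int, k: int, rep: int) -> np.random.Generator:
    """The documented substream for repetition ``rep`` of the k-cluster run."""
    return np.random.default_rng([seed, k, rep])


def _final_labels(M: np.ndarray, k: int, method: str) -> np.ndarray:
    if method == "pam":
        return pam(1.0 - M, k).labels
    if method == "hierarchical":
        d = 1.0 - M
        np.fill_diagonal(d, 0.0)
        Z = linkage(squareform(d, checks=False), method="average")
        return fcluster(Z, t=k, criterion="maxclust") - 1
    raise ValueError(f"unknown final-label method {method!r}")


def run_consensus(
    data: FeatureTable | DissimilarityMatrix,
    k: int,
    n_reps: int = 1000,
    fraction: float = 0.8,
    seed: int = 0,
    final_method: str = "pam",
) -> ConsensusRun:
    """Consensus-cluster at a single k.

    ``data`` may be a feature table (the Gower matrix is computed once) or a
    precomputed dissimilarity matrix.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    D = data if isinstance(data, DissimilarityMatrix) else gower_matrix(data)
    n = D.n
    if int(np.floor(fraction * n)) < k:
        raise ValueError("subsample smaller than k; raise fraction or n")

    coclust = np.zeros((n, n), dtype=np.int64)
    cosample = np.zeros((n, n), dtype=np.int64)
    for rep in range(n_reps):
        idx = subsample_indices(n, fraction, rep_rng(seed, k, rep))
        labels = pam(D.slice(idx), k).labels
        cosample[np.ix_(idx, idx)] += 1
        for c in range(k):
            members = idx[labels == c]
            coclust[np.ix_(members, members)] += 1

    off = ~np.eye(n, dtype=bool)
    if (cosample[off] == 0).any():
        raise RuntimeError(
            "some patient pair was never co-sampled; increase n_reps or fraction"
        )
    with np.errstate(invalid="ignore"):
        M = coclust / np.maximum(cosample, 1)
    np.fill_diagonal(M, 1.0)  # convention; self-pairs excluded from counting
    final = _final_labels(M, k, final_method)
    return ConsensusRun(
        k=k,
        consensus=M,
        cosample_counts=cosample,
        final_labels=np.asarray(final),
        n_reps=n_reps,
        subsample_fraction=fraction,
    )


def run_sweep(
    data: FeatureTable | DissimilarityMatrix,
    k_min: int = 2,
    k_max: int = 9,
    n_reps: int = 1000,
    fraction: float = 0.8,
    seed: int = 0,
    final_method: str = "pam",
) -> ConsensusSweep:
    """Consensus runs for every k in ``k_min..k_max`` over one Gower matrix."""
    if not (2 <= k_min <= k_max):
        raise ValueError("need 2 <= k_min <= k_max")
    D = data if isinstance(data, DissimilarityMatrix) else gower_matrix(data)
    runs = {
        k: run_consensus(D, k, n_reps=n_reps, fraction=fraction, seed=seed,
                         final_method=final_method)
        for k in range(k_min, k_max + 1)
    }
    return ConsensusSweep(runs=runs, patient_ids=D.patient_ids, seed=seed)
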