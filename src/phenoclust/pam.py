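"""Partitioning around medoids (k-medoids) on a precomputed dissimilarity matrix.

Classical BUILD (greedy seeding: the first medoid minimises total
dissimilarity, each later medoid maximises the decrease in cost) followed by
classical best-improvement SWAP (repeat the single medoid<->non-medoid swap
with the largest strict cost decrease until none improves). Every tie —
equal cost changes, equidistant assignment — is broken towards the lowest
index, so the algorithm is fully deterministic given the matrix.

The matrix only needs symmetry, a zero diagonal and non-negativity; no
triangle inequality is assumed (consensus clustering feeds it ``1 - M``,
which is not metric).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PAMResult", "pam_build", "pam_swap", "pam"]


@dataclass(frozen=True)
class PAMResult:
    """Medoid indices (sorted ascending), per-point labels, and total cost.

    ``labels[i]`` is the position of point i's medoid within ``medoids``,
    so clusters are numbered 0..k-1 in medoid-index order and every medoid
    is labelled to itself.
    """

    medoids: tuple[int, ...]
    labels: np.ndarray
    cost: float
    #: per-iteration total cost (SWAP appends one entry per accepted swap)
    cost_history: tuple[float, ...] = ()

    @property
    def k(self) -> int:
        return len(self.medoids)


def _assign(D: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    """Nearest-medoid labels (ties -> lower medoid index) and total cost."""
    sub = D[:, medoids]  # medoids sorted ascending; argmin takes first min
    labels = np.argmin(sub, axis=1)
    cost = float(sub[np.arange(D.shape[0]), labels].sum())
    return labels, cost


def _as_array(D) -> np.ndarray:
    values = getattr(D, "values", D)
    return np.asarray(values, dtype=float)


def pam_build(D, k: int) -> PAMResult:
    """Greedy BUILD initialisation."""
    Dm = _as_array(D)
    n = Dm.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} must be in 1..{n}")
    first = int(np.argmin(Dm.sum(axis=1)))
    medoids = [first]
    d_nearest = Dm[first].copy()
    for _ in range(k - 1):
        # gain of adding candidate j: sum_i max(d_nearest_i - D[j,i], 0)
        gains = np.maximum(d_nearest[None, :] - Dm, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        j = int(np.argmax(gains))  # first max -> lowest index
        medoids.append(j)
        d_nearest = np.minimum(d_nearest, Dm[j])
    med = np.sort(np.asarray(medoids))
    labels, cost = _assign(Dm, med)
    return PAMResult(tuple(int(m) for m in med), labels, cost, (cost,))


def _swap_deltas(Dm: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    """Cost change T[m_pos, h] of swapping medoids[m_pos] out for point h in.

    Uses the nearest (d1) / second-nearest (d2) medoid decomposition: for a
    point whose nearest medoid is removed the new cost is min(D[i,h], d2_i);
    for any other point it is min(D[i,h], d1_i).
    """
    n = Dm.shape[0]
    k = len(medoids)
    sub = Dm[:, medoids]
    order = np.argsort(sub, axis=1, kind="stable")
    nearest_pos = order[:, 0]
    d1 = sub[np.arange(n), nearest_pos]
    d2 = sub[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)

    # shared term: points not losing their medoid contribute min(D[i,h]-d1_i, 0)
    A = np.minimum(Dm - d1[:, None], 0.0)
    S = A.sum(axis=0)
    T = np.tile(S, (k, 1))
    for pos in range(k):
        members = nearest_pos == pos
        if members.any():
            T[pos] -= A[members].sum(axis=0)
            T[pos] += (
                np.minimum(Dm[members], d2[members, None]) - d1[members, None]
            ).sum(axis=0)
    T[:, medoids] = np.inf  # cannot swap in a current medoid
    return T


def pam_swap(D, start: PAMResult) -> PAMResult:
    """Best-improvement SWAP refinement from ``start`` to a local optimum."""
    Dm = _as_array(D)
    medoids = np.asarray(start.medoids)
    n = Dm.shape[0]
    if start.k >= n:
        return start
    history = [start.cost]
    while True:
        T = _swap_deltas(Dm, medoids)
        flat = int(np.argmin(T))  # first min -> lowest (medoid pos, candidate)
        best = T.flat[flat]
        if not (best < -1e-12):
            break
        pos, h = divmod(flat, n)
        medoids = np.sort(np.concatenate([np.delete(medoids, pos), [h]]))
        history.append(float(_assign(Dm, medoids)[1]))
    labels, cost = _assign(Dm, medoids)
    return PAMResult(tuple(int(m) for m in medoids), labels, cost, tuple(history))


def pam(D, k: int) -> PAMResult:
    """BUILD then SWAP; deterministic given ``D`` and ``k``."""
    return pam_swap(D, pam_build(D, k))
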