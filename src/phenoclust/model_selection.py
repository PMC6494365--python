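"""Choosing the number of clusters from consensus matrices.

The empirical CDF of the off-diagonal upper-triangle consensus values
summarises how dichotomised the matrix is: stable clusterings pile mass at 0
and 1. The proportion of ambiguous clustering (PAC) is the CDF mass inside
an intermediate interval, pac = CDF(u2) - CDF(u1) with the boundary
convention u1 < v <= u2 (default interval (0.1, 0.9)); the k minimising PAC
is selected, ties going to the smallest k. A flat, high PAC profile signals
absence of structure — resampling clusterers happily partition homogeneous
data, so the profile, not the mere existence of labels, carries the
evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .consensus import ConsensusSweep

__all__ = [
    "PACProfile",
    "NoStructureWarning",
    "BoundaryMinimumWarning",
    "upper_triangle_values",
    "consensus_cdf",
    "pac",
    "delta_area",
    "select_k",
]

#: PAC at or above this at every k is treated as "no preferred structure".
NO_STRUCTURE_PAC = 0.5


class NoStructureWarning(UserWarning):
    """PAC profile shows no unambiguous clustering at any k."""


class BoundaryMinimumWarning(UserWarning):
    """argmin PAC sits at the edge of the searched k range."""


def upper_triangle_values(M: np.ndarray) -> np.ndarray:
    """Off-diagonal upper-triangle entries (the unit diagonal is convention,
    not evidence, and never enters CDF/PAC)."""
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    if n < 2:
        raise ValueError("need at least 2 patients")
    return M[np.triu_indices(n, k=1)]


def consensus_cdf(M: np.ndarray):
    """Right-continuous empirical CDF of the upper-triangle consensus values.

    Returns a vectorised callable F with F(t) = fraction of values <= t,
    F(1) = 1.
    """
    vals = np.sort(upper_triangle_values(M))
    m = vals.size

    def F(t):
        return np.searchsorted(vals, t, side="right") / m

    F.values = vals  # type: ignore[attr-defined]
    return F


def pac(M: np.ndarray, u1: float = 0.1, u2: float = 0.9) -> float:
    """Proportion of ambiguous clustering: fraction of pair-consensus values
    in (u1, u2]. 0 on a perfectly dichotomised matrix, 1 when every pair is
    maximally ambiguous."""
    if not (0 <= u1 < u2 <= 1):
        raise ValueError("need 0 <= u1 < u2 <= 1")
    F = consensus_cdf(M)
    return float(F(u2) - F(u1))


def _cdf_area(M: np.ndarray) -> float:
    """Exact integral of the step CDF over [0, 1].

    For values v_i in [0, 1], integral of F = E[1 - V] = 1 - mean(v).
    """
    return float(1.0 - upper_triangle_values(M).mean())


def delta_area(sweep: ConsensusSweep) -> dict[int, float]:
    """Relative change in area under the consensus CDF across k.

    Delta(k_min) = A(k_min); Delta(k) = (A(k) - A(k-1)) / A(k-1) for k
    above k_min — the elbow diagnostic that accompanies the CDF plot.
    """
    ks = sweep.ks
    if len(ks) < 2:
        raise ValueError("delta-area needs a sweep over at least 2 values of k")
    A = {k: _cdf_area(sweep.runs[k].consensus) for k in ks}
    out = {ks[0]: A[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        out[k] = (A[k] - A[prev]) / A[prev] if A[prev] != 0 else 0.0
    return out


@dataclass(frozen=True)
class PACProfile:
    """Per-k PAC values, the selected k, and structure diagnostics."""

    pac_by_k: dict[int, float]
    interval: tuple[float, float]
    selected_k: int
    no_structure: bool = False
    boundary_minimum: bool = False
    flags: tuple[str, ...] = field(default=())


def select_k(sweep: ConsensusSweep, u1: float = 0.1, u2: float = 0.9) -> PACProfile:
    """PAC per k; the smallest PAC selects k (ties -> smallest k).

    Warns (and flags in the profile) when the profile never drops below
    ``NO_STRUCTURE_PAC`` — the negative-control signature of clustering
    structureless data — and when the minimum sits on the boundary of the
    searched range, where the true optimum may lie outside it.
    """
    ks = sweep.ks
    profile = {k: pac(sweep.runs[k].consensus, u1, u2) for k in ks}
    selected = min(ks, key=lambda k: (profile[k], k))
    flags: list[str] = []
    no_structure = min(profile.values()) >= NO_STRUCTURE_PAC
    if no_structure:
        flags.append("no_structure")
        warnings.warn(
            "PAC never falls below %.2f at any k: no evidence of cluster "
            "structure" % NO_STRUCTURE_PAC,
            NoStructureWarning,
            stacklevel=2,
        )
    boundary = len(ks) > 1 and selected in (ks[0], ks[-1])
    if boundary:
        flags.append("boundary_minimum")
        warnings.warn(
            f"PAC minimum at k={selected} lies on the boundary of the searched "
            f"range {ks[0]}..{ks[-1]}",
            BoundaryMinimumWarning,
            stacklevel=2,
        )
    return PACProfile(
        pac_by_k=profile,
        interval=(u1, u2),
        selected_k=selected,
        no_structure=no_structure,
        boundary_minimum=boundary,
        flags=tuple(flags),
    )
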