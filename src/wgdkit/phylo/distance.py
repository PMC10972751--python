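"""Pairwise maximum-likelihood distances between protein sequences."""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize_scalar

from ..alignment import Alignment
from .model import N_STATES, SubstitutionModel

#: value reported for saturated pairs (p-distance beyond the model's range)
SATURATED = math.inf


def p_distance(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Proportion of differing sites over shared (non-gap) sites."""
    shared = (a >= 0) & (b >= 0)
    n = int(shared.sum())
    if n == 0:
        raise ValueError("no shared ungapped sites")
    diff = int(np.sum(a[shared] != b[shared]))
    return diff / n, n


def poisson_correct(p: float) -> float:
    """Closed-form distance d = -(19/20) ln(1 - (20/19) p) for the
    equal-rates 20-state model; saturated input returns ``inf``."""
    k = N_STATES
    arg = 1.0 - p * k / (k - 1)
    if arg <= 0.0:
        return SATURATED
    return -(k - 1) / k * math.log(arg)


def ml_distance(a: np.ndarray, b: np.ndarray, model: SubstitutionModel) -> float:
    """ML distance between two encoded sequences.

    Uses the closed form under the Poisson model, otherwise maximises the
    two-sequence likelihood numerically.  Saturated pairs return ``inf``.
    """
    p, n = p_distance(a, b)
    if model.is_poisson and not model.gamma_shape:
        return poisson_correct(p)
    if p == 0.0:
        return 0.0
    shared = (a >= 0) & (b >= 0)
    aa, bb = a[shared], b[shared]
    pair = np.stack([aa, bb]).astype(np.int64)
    pairs, counts = np.unique(pair.T, axis=0, return_counts=True)
    pi = model.frequencies
    rates = model.category_rates()

    def neg_lnl(d: float) -> float:
        lik = np.zeros(len(pairs))
        for r in rates:
            P = model.transition(d * r)
            lik += pi[pairs[:, 0]] * P[pairs[:, 0], pairs[:, 1]] / len(rates)
        return -float(counts @ np.log(np.clip(lik, 1e-300, None)))

    res = minimize_scalar(neg_lnl, bounds=(1e-8, 50.0), method="bounded")
    d = float(res.x)
    if d > 45.0:
        return SATURATED
    return d


def distance_matrix(
    aln: Alignment, model: SubstitutionModel, max_distance: float | None = None
) -> np.ndarray:
    """Symmetric ML distance matrix; saturation optionally capped."""
    n = len(aln)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = ml_distance(aln.matrix[i], aln.matrix[j], model)
            if not math.isfinite(d):
                if max_distance is None:
                    raise ValueError(
                        f"saturated pair ({aln.names[i]}, {aln.names[j]}); "
                        "pass max_distance to cap"
                    )
                d = max_distance
            elif max_distance is not None:
                d = min(d, max_distance)
            D[i, j] = D[j, i] = d
    return D


def p_distance_matrix(aln: Alignment) -> np.ndarray:
    """Fast pairwise p-distance matrix (used by bootstrap replicates)."""
    mat = aln.matrix
    n = len(aln)
    D = np.zeros((n, n))
    for i in range(n):
        shared = (mat[i] >= 0) & (mat[i + 1 :] >= 0)
        diff = (mat[i] != mat[i + 1 :]) & shared
        with np.errstate(invalid="ignore"):
            p = diff.sum(axis=1) / shared.sum(axis=1)
        D[i, i + 1 :] = D[i + 1 :, i] = np.nan_to_num(p)
    return D
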