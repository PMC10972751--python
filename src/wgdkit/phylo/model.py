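"""Amino-acid substitution models.

Models are time-reversible with a symmetric exchangeability matrix S and
stationary frequencies pi; the rate matrix Q_ij = S_ij pi_j (i != j) is
normalised to one expected substitution per site per unit branch length.
Optional discrete-gamma rate heterogeneity uses equal-probability categories
with median rates renormalised to mean 1.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.stats import gamma as gamma_dist

N_STATES = 20


class SubstitutionModel:
    def __init__(
        self,
        exchangeabilities: Optional[np.ndarray] = None,
        frequencies: Optional[np.ndarray] = None,
        gamma_shape: Optional[float] = None,
        n_categories: int = 4,
    ):
        k = N_STATES
        if exchangeabilities is None:
            exchangeabilities = np.ones((k, k))
        S = np.asarray(exchangeabilities, dtype=float).copy()
        if S.shape != (k, k) or not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be 20x20 symmetric")
        np.fill_diagonal(S, 0.0)
        if frequencies is None:
            frequencies = np.full(k, 1.0 / k)
        pi = np.asarray(frequencies, dtype=float)
        if pi.shape != (k,) or np.any(pi <= 0):
            raise ValueError("frequencies must be 20 positive values")
        pi = pi / pi.sum()

        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.sum(pi * np.diag(Q))
        Q /= mu

        self.S = S
        self.frequencies = pi
        self.Q = Q
        # symmetric similarity transform for a stable eigendecomposition
        sqrt_pi = np.sqrt(pi)
        B = (Q * sqrt_pi[None, :]) / sqrt_pi[:, None]
        B = 0.5 * (B + B.T)
        evals, evecs = np.linalg.eigh(B)
        self._evals = evals
        self._left = evecs / sqrt_pi[:, None]  # rows scaled
        self._right = evecs * sqrt_pi[:, None]

        self.gamma_shape = gamma_shape
        self.n_categories = n_categories if gamma_shape else 1

    # ------------------------------------------------------------------
    def category_rates(self) -> np.ndarray:
        if not self.gamma_shape:
            return np.ones(1)
        a = self.gamma_shape
        n = self.n_categories
        qs = (np.arange(n) + 0.5) / n
        rates = gamma_dist.ppf(qs, a, scale=1.0 / a)
        return rates / rates.mean()

    def transition(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1."""
        if t < 0:
            raise ValueError("negative branch length")
        P = (self._left * np.exp(self._evals * t)) @ self._right.T
        np.clip(P, 1e-16, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    @property
    def is_poisson(self) -> bool:
        off = self.S[~np.eye(N_STATES, dtype=bool)]
        return np.allclose(off, off[0]) and np.allclose(
            self.frequencies, 1.0 / N_STATES
        )


def poisson_model(gamma_shape: Optional[float] = None, n_categories: int = 4) -> SubstitutionModel:
    """Equal-exchangeability, uniform-frequency ("Poisson") 20-state model."""
    return SubstitutionModel(gamma_shape=gamma_shape, n_categories=n_categories)


def load_rate_matrix(path) -> SubstitutionModel:
    """Load a PAML-style empirical rate matrix file.

    Expected layout: 19 lines of lower-triangular exchangeabilities followed
    by a line of 20 stationary frequencies (blank lines ignored).
    """
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            values.extend(float(x) for x in line.split())
    need = 19 * 20 // 2 + 20
    if len(values) < need:
        raise ValueError(f"rate matrix file too short ({len(values)} < {need})")
    S = np.zeros((N_STATES, N_STATES))
    it = iter(values)
    for i in range(1, N_STATES):
        for j in range(i):
            S[i, j] = S[j, i] = next(it)
    pi = np.array([next(it) for _ in range(N_STATES)])
    return SubstitutionModel(S, pi)
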