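"""Amino-acid substitution models and transition probabilities.

A :class:`SubstitutionModel` is a time-reversible continuous-time Markov
process on the 20 amino acids, parameterised by symmetric exchangeabilities
``s_ij`` and equilibrium frequencies ``pi``:  ``Q_ij = s_ij * pi_j`` for
``i != j``, diagonal set so rows sum to zero, and the whole matrix scaled so
the expected rate at equilibrium is one substitution per site per unit time.

Transition matrices ``P(t) = expm(Q t)`` are computed by eigendecomposition of
the symmetrised matrix ``B = D Q D^-1`` with ``D = diag(sqrt(pi))``, which is
exact for reversible models and lets one decomposition serve every branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from kinevo._lg_data import LG_EXCHANGEABILITIES, LG_FREQUENCIES
from kinevo.alphabet import N_AA

# probabilities below this are clipped to zero before renormalisation
_PROB_CLIP = 1e-12


@dataclass
class SubstitutionModel:
    """Reversible amino-acid replacement model.

    Attributes
    ----------
    name : str
        Model identifier ("POISSON", "LG", ...).
    rate_matrix : (20, 20) ndarray
        Instantaneous rates; rows sum to zero, off-diagonals nonnegative.
    frequencies : (20,) ndarray
        Equilibrium frequencies, summing to one.
    """

    name: str
    rate_matrix: np.ndarray
    frequencies: np.ndarray
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        Q = np.asarray(self.rate_matrix, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if Q.shape != (N_AA, N_AA):
            raise ValueError("rate matrix must be 20x20")
        if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-8):
            raise ValueError("rate matrix rows must sum to zero")
        off = Q[~np.eye(N_AA, dtype=bool)]
        if (off < -1e-12).any():
            raise ValueError("off-diagonal rates must be nonnegative")
        if not np.isclose(pi.sum(), 1.0, atol=1e-8):
            raise ValueError("equilibrium frequencies must sum to one")
        self.rate_matrix = Q
        self.frequencies = pi

    @property
    def is_reversible(self) -> bool:
        """Detailed balance pi_i q_ij == pi_j q_ji within 1e-8."""
        pi, Q = self.frequencies, self.rate_matrix
        flux = pi[:, None] * Q
        return bool(np.allclose(flux, flux.T, atol=1e-8))

    def _eigendecomposition(self):
        if self._eig is None:
            pi = self.frequencies
            d = np.sqrt(pi)
            B = (d[:, None] * self.rate_matrix) / d[None, :]
            B = 0.5 * (B + B.T)  # symmetrise away rounding noise
            w, U = scipy.linalg.eigh(B)
            self._eig = (w, U, d)
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = expm(Q t), rows summing to one; t must be >= 0."""
        if t < 0:
            raise ValueError("branch length must be nonnegative")
        w, U, d = self._eigendecomposition()
        E = (U * np.exp(w * t)) @ U.T
        P = (E / d[:, None]) * d[None, :]
        P = np.where(P < _PROB_CLIP, 0.0, P)
        return P / P.sum(axis=1, keepdims=True)


def _build(name: str, S: np.ndarray, pi: np.ndarray) -> SubstitutionModel:
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(pi * np.diag(Q)).sum()
    return SubstitutionModel(name, Q / scale, pi)


def poisson_model() -> SubstitutionModel:
    """Uniform replacement process with equal frequencies."""
    S = np.ones((N_AA, N_AA)) - np.eye(N_AA)
    return _build("POISSON", S, np.full(N_AA, 1.0 / N_AA))


def lg_model() -> SubstitutionModel:
    """Le-Gascuel empirical model (single rate; no gamma categories)."""
    return _build(
        "LG",
        np.array(LG_EXCHANGEABILITIES),
        np.array(LG_FREQUENCIES) / np.sum(LG_FREQUENCIES),
    )


def get_model(name: str) -> SubstitutionModel:
    key = name.upper()
    if key == "POISSON":
        return poisson_model()
    if key == "LG":
        return lg_model()
    raise KeyError(f"unknown substitution model {name!r}")
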