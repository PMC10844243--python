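"""Exact moments of node-set-averaged variance signals for multivariate OU processes.

Fluctuations around a stable equilibrium of a noisy dynamical system obey the
linear SDE ``dz = -A z dt + B dW`` (a multivariate Ornstein–Uhlenbeck process),
whose stationary covariance ``C`` solves the continuous Lyapunov equation
``A C + C Aᵀ = B Bᵀ``.  Given ``C``, the early warning signal

    V̂_S = (1/n) Σ_{i ∈ S} V̂_i

(the unbiased sample variance of each node averaged over a sentinel set ``S``
of ``n`` nodes, from ``L`` i.i.d. samples) has

    E[V̂_S]   = (1/n) Σ_{i ∈ S} C_ii
    var[V̂_S] = 2 / (n² (L-1)) Σ_{i,j ∈ S} C_ij²

and coefficient of variation
``CV = sqrt(2/(L-1)) sqrt(Σ λ_i²) / Σ λ_i`` in terms of the eigenvalues of the
principal submatrix of ``C`` on ``S``.  The separability of the signal
distributions at two values of a bifurcation parameter is scored by

    d = |μ₁ - μ₂| / sqrt(var₁ + var₂),

the selection objective: node sets with larger ``d`` give a more informative
early warning signal.

Moment formulas assume the ``L`` samples are i.i.d. Gaussian; temporal
correlation between consecutive samples is not corrected for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

__all__ = [
    "OUSystem",
    "SignalMoments",
    "StabilityError",
    "solve_lyapunov",
    "signal_moments",
    "coefficient_of_variation",
    "d_statistic",
    "validate_node_set",
    "read_covariance_csv",
    "write_covariance_csv",
]

#: residual tolerance for the returned Lyapunov solution, relative to ||BBᵀ||
LYAPUNOV_RTOL = 1e-10

#: a drift matrix counts as stable if every eigenvalue real part exceeds this
STABILITY_TOL = 1e-12


class StabilityError(ValueError):
    """The drift matrix has an eigenvalue with non-positive real part."""


@dataclass(frozen=True)
class OUSystem:
    """A multivariate OU process ``dz = -A z dt + B dW``.

    ``drift`` is the sign-flipped Jacobian A (stable iff all eigenvalue real
    parts are positive); ``noise`` is the matrix B multiplying the Wiener
    increments.
    """

    drift: np.ndarray
    noise: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.drift, dtype=float)
        b = np.asarray(self.noise, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("drift matrix must be square")
        if b.shape != a.shape:
            raise ValueError("noise matrix must match the drift matrix shape")
        object.__setattr__(self, "drift", a)
        object.__setattr__(self, "noise", b)

    @property
    def n_nodes(self) -> int:
        return self.drift.shape[0]

    def check_stable(self) -> None:
        eigvals = np.linalg.eigvals(self.drift)
        worst = eigvals[np.argmin(eigvals.real)]
        if worst.real <= STABILITY_TOL:
            raise StabilityError(
                f"drift matrix is not stable: eigenvalue {worst} has "
                f"real part <= {STABILITY_TOL}"
            )


def solve_lyapunov(system: OUSystem) -> np.ndarray:
    """Stationary covariance ``C`` solving ``A C + C Aᵀ = B Bᵀ``.

    Uses a direct Bartels–Stewart solve; the result is symmetrized and its
    residual is checked against :data:`LYAPUNOV_RTOL`.
    """
    system.check_stable()
    a = system.drift
    q = system.noise @ system.noise.T
    c = scipy.linalg.solve_continuous_lyapunov(a, q)
    c = 0.5 * (c + c.T)
    residual = np.abs(a @ c + c @ a.T - q).max()
    scale = max(np.abs(q).max(), 1e-300)
    if residual > LYAPUNOV_RTOL * scale:
        raise RuntimeError(
            f"Lyapunov residual {residual:.3e} exceeds tolerance "
            f"{LYAPUNOV_RTOL * scale:.3e}"
        )
    return c


@dataclass(frozen=True)
class SignalMoments:
    """Mean and variance of the node-set-averaged variance signal V̂_S."""

    mean: float
    variance: float
    sample_size: int

    @property
    def std(self) -> float:
        return math.sqrt(self.variance)

    @property
    def cv(self) -> float:
        return coefficient_of_variation(self)


def validate_node_set(node_set: Sequence[int], dim: int) -> tuple[int, ...]:
    """Normalize a node set to a sorted tuple of distinct 0-based indices."""
    members = tuple(sorted(int(i) for i in node_set))
    if len(members) == 0:
        raise ValueError("node set must contain at least one node")
    if len(set(members)) != len(members):
        raise ValueError(f"node set has duplicate members: {node_set}")
    if members[0] < 0 or members[-1] >= dim:
        raise ValueError(f"node set {node_set} out of range for dimension {dim}")
    return members


def signal_moments(
    c: np.ndarray, node_set: Sequence[int], sample_size: int
) -> SignalMoments:
    """Exact mean and variance of V̂_S for covariance ``c`` and set ``S``.

    ``sample_size`` is the number L of i.i.d. samples per node (L >= 2).
    Node indices are 0-based.
    """
    c = np.asarray(c, dtype=float)
    if sample_size < 2:
        raise ValueError(f"sample size L must be >= 2, got {sample_size}")
    members = validate_node_set(node_set, c.shape[0])
    sub = c[np.ix_(members, members)]
    n = len(members)
    mean = float(np.trace(sub)) / n
    variance = 2.0 / (n * n * (sample_size - 1)) * float(np.sum(sub * sub))
    return SignalMoments(mean=mean, variance=variance, sample_size=sample_size)


def coefficient_of_variation(m: SignalMoments) -> float:
    """CV = std/mean of the signal; ``sqrt(2/(L-1))`` for any single node."""
    if m.mean <= 0:
        raise ValueError(f"CV undefined for non-positive mean {m.mean}")
    return math.sqrt(m.variance) / m.mean


def d_statistic(m1: SignalMoments, m2: SignalMoments) -> float:
    """Separability ``d = |μ₁ - μ₂| / sqrt(var₁ + var₂)`` of two signal laws."""
    denom = m1.variance + m2.variance
    if denom <= 0:
        raise ValueError("d undefined: both variances are zero")
    return abs(m1.mean - m2.mean) / math.sqrt(denom)


def write_covariance_csv(c: np.ndarray, path: str | Path, labels=None) -> None:
    """Write a covariance matrix as CSV with a header row of node labels."""
    c = np.asarray(c, dtype=float)
    if labels is None:
        labels = [str(i) for i in range(c.shape[0])]
    pd.DataFrame(c, columns=list(labels)).to_csv(path, index=False)


def read_covariance_csv(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Read a covariance matrix written by :func:`write_covariance_csv`."""
    df = pd.read_csv(path)
    return df.to_numpy(dtype=float), tuple(str(col) for col in df.columns)
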