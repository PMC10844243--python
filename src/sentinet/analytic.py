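"""Closed-form equilibria, covariances, and d tables for two small toy networks.

Two analytically solvable systems near a saddle-node bifurcation are covered.
Both are built from the normal form ``dx/dt = r + x**2`` (stable equilibrium
``x* = -sqrt(-r)`` for r < 0) with additive coupling ``w (x_neighbor + 1)``.

*Two nodes, directed edge* (node 1 drives node 2, which carries an extra
stress offset Δr):

    dx1 = (r + x1²) dt + σ1 dW1
    dx2 = (r - Δr + x2² + w (x1 + 1)) dt + σ2 dW2

The lower equilibrium and the stationary covariance entries C11, C12, C22 are
available in closed form.

*Undirected three-node chain* (1 — 2 — 3, σ3 = σ1):

    dx1 = (r + x1² + w (x2 + 1)) dt + σ1 dW1
    dx2 = (r + x2² + w (x1 + 1) + w (x3 + 1)) dt + σ2 dW2
    dx3 = (r + x3² + w (x2 + 1)) dt + σ3 dW3

The symmetric equilibrium (x3* = x1*) solves two coupled quadratics; it is
found by a root solve continued from the decoupled w = 0 solution and verified
by residual and stability checks.  Its first saddle-node bifurcation lies at
some r_c with 0 > r_c > r_c'' = 2 w (-(w+1) + sqrt(w (w+1))), the closed-form
bound exposed here; ``chain_critical_r`` brackets r_c numerically.

``d_table`` chains equilibrium → covariance → signal moments at two values of
r into the d statistic for a collection of sentinel sets, reproducing the
ranking of candidate early warning signals on these models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .ou import SignalMoments, d_statistic, signal_moments

__all__ = [
    "TwoNodeParams",
    "ChainParams",
    "BifurcationPassedError",
    "two_node_equilibrium",
    "two_node_drift_matrix",
    "two_node_covariance",
    "chain_equilibrium",
    "chain_drift_matrix",
    "chain_covariance",
    "chain_bifurcation_bound",
    "chain_critical_r",
    "d_table",
]

_EQ_RESIDUAL_TOL = 1e-12


class BifurcationPassedError(ValueError):
    """No stable lower-state equilibrium exists at the requested parameters."""


@dataclass(frozen=True)
class TwoNodeParams:
    """Parameters of the two-node directed model."""

    r: float
    delta_r: float = 1.0
    w: float = 0.5
    sigma1: float = 0.1
    sigma2: float = 0.1
    sample_size: int = 100

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ValueError("coupling w must be non-negative")
        if self.delta_r < 0:
            raise ValueError("stress offset delta_r must be non-negative")


@dataclass(frozen=True)
class ChainParams:
    """Parameters of the three-node chain model (sigma3 = sigma1)."""

    r: float
    w: float = 0.05
    sigma1: float = 0.1
    sigma2: float = 0.1
    sample_size: int = 100

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ValueError("coupling w must be non-negative")


def two_node_equilibrium(p: TwoNodeParams) -> tuple[float, float]:
    """Lower stable equilibrium (x1*, x2*); both coordinates are negative."""
    if p.r >= 0:
        raise BifurcationPassedError(f"no lower equilibrium for r = {p.r} >= 0")
    arg2 = -p.r + p.delta_r + p.w * (math.sqrt(-p.r) - 1.0)
    if arg2 <= 0:
        raise BifurcationPassedError(
            f"node 2 has no lower equilibrium: -r + delta_r + w(sqrt(-r)-1) "
            f"= {arg2} <= 0"
        )
    return -math.sqrt(-p.r), -math.sqrt(arg2)


def two_node_drift_matrix(p: TwoNodeParams) -> np.ndarray:
    """Sign-flipped Jacobian A at the lower equilibrium."""
    x1, x2 = two_node_equilibrium(p)
    return np.array([[-2.0 * x1, 0.0], [-p.w, -2.0 * x2]])


def two_node_covariance(p: TwoNodeParams) -> np.ndarray:
    """Closed-form stationary covariance of the two-node model.

    All three entries are positive and diverge as (-r)^(-1/2) when r -> 0-.
    """
    x1, x2 = two_node_equilibrium(p)
    s1sq, s2sq = p.sigma1**2, p.sigma2**2
    c11 = -s1sq / (4.0 * x1)
    c12 = s1sq * p.w / (8.0 * x1 * (x1 + x2))
    c22 = -s1sq * p.w**2 / (16.0 * x1 * x2 * (x1 + x2)) - s2sq / (4.0 * x2)
    return np.array([[c11, c12], [c12, c22]])


def chain_bifurcation_bound(w: float) -> float:
    """Closed-form lower bound r_c'' = 2w[-(w+1) + sqrt(w(w+1))] on r_c."""
    if w < 0:
        raise ValueError("coupling w must be non-negative")
    return 2.0 * w * (-(w + 1.0) + math.sqrt(w * (w + 1.0)))


def chain_equilibrium(p: ChainParams) -> tuple[float, float]:
    """Stable lower equilibrium (x1*, x2*) of the chain; x3* = x1*.

    Solves r + x1² + w(x2+1) = 0 and r + x2² + 2w(x1+1) = 0 by a damped
    Newton iteration continued from the decoupled (w = 0) root
    x1 = x2 = -sqrt(-r), then verifies the residuals and that the
    sign-flipped Jacobian is positive definite.
    """
    if p.r >= 0:
        raise BifurcationPassedError(f"no lower equilibrium for r = {p.r} >= 0")

    def residual(x: np.ndarray, w: float) -> np.ndarray:
        x1, x2 = x
        return np.array(
            [p.r + x1 * x1 + w * (x2 + 1.0), p.r + x2 * x2 + 2.0 * w * (x1 + 1.0)]
        )

    def newton(x: np.ndarray, w: float) -> np.ndarray:
        for _ in range(60):
            res = residual(x, w)
            if np.abs(res).max() < 1e-15:
                break
            jac = np.array([[2.0 * x[0], w], [2.0 * w, 2.0 * x[1]]])
            try:
                delta = np.linalg.solve(jac, res)
            except np.linalg.LinAlgError as exc:
                raise BifurcationPassedError(
                    f"singular Jacobian at r = {p.r}, w = {w}: {exc}"
                ) from exc
            x = x - delta
            if not np.isfinite(x).all():
                raise BifurcationPassedError(
                    f"Newton iteration diverged at r = {p.r}, w = {w}"
                )
        return x

    guess = np.array([-math.sqrt(-p.r)] * 2)
    for w in np.linspace(0.0, p.w, 11)[1:]:
        guess = newton(guess, w)
    x1, x2 = float(guess[0]), float(guess[1])
    if np.abs(residual(guess, p.w)).max() > _EQ_RESIDUAL_TOL:
        raise BifurcationPassedError(
            f"equilibrium residual above {_EQ_RESIDUAL_TOL} at r = {p.r}"
        )
    if x1 >= 0 or x2 >= 0:
        raise BifurcationPassedError(
            f"root ({x1}, {x2}) is not in the lower state at r = {p.r}"
        )
    a = _chain_drift_from_point(x1, x2, p.w)
    if np.linalg.eigvalsh(a).min() <= 0:
        raise BifurcationPassedError(
            f"root ({x1}, {x2}) at r = {p.r} is not stable"
        )
    return x1, x2


def _chain_drift_from_point(x1: float, x2: float, w: float) -> np.ndarray:
    return np.array(
        [
            [-2.0 * x1, -w, 0.0],
            [-w, -2.0 * x2, -w],
            [0.0, -w, -2.0 * x1],
        ]
    )


def chain_drift_matrix(p: ChainParams) -> np.ndarray:
    """Sign-flipped Jacobian A (symmetric) at the chain's lower equilibrium."""
    x1, x2 = chain_equilibrium(p)
    return _chain_drift_from_point(x1, x2, p.w)


def chain_covariance(p: ChainParams) -> np.ndarray:
    """Closed-form stationary covariance of the chain (C11 = C33, C12 = C23)."""
    x1, x2 = chain_equilibrium(p)
    w = p.w
    s1sq, s2sq = p.sigma1**2, p.sigma2**2
    den = (2.0 * x1 * x2 - w * w) * (x1 + x2)
    c11 = (
        -4.0 * x1 * x2 * (x1 + x2) * s1sq
        + w * w * ((2.0 * x1 + x2) * s1sq - x1 * s2sq)
    ) / (8.0 * x1 * den)
    c12 = w * (x2 * s1sq + x1 * s2sq) / (4.0 * den)
    c13 = -w * w * (x2 * s1sq + x1 * s2sq) / (8.0 * x1 * den)
    c22 = (
        -2.0 * x1 * x2 * (x1 + x2) * s2sq + w * w * x2 * (s2sq - s1sq)
    ) / (4.0 * x2 * den)
    return np.array(
        [
            [c11, c12, c13],
            [c12, c22, c12],
            [c13, c12, c11],
        ]
    )


def chain_critical_r(w: float, *, tol: float = 1e-10) -> float:
    """Numerical first-bifurcation point r_c of the chain, found by bisection.

    Brackets the largest r for which :func:`chain_equilibrium` still has a
    stable lower-state root, between the closed-form bound r_c'' and 0.
    """
    lo = chain_bifurcation_bound(w)
    hi = 0.0

    def exists(r: float) -> bool:
        try:
            chain_equilibrium(ChainParams(r=r, w=w))
            return True
        except BifurcationPassedError:
            return False

    if not exists(lo):
        raise ValueError(f"no stable equilibrium even at the bound r = {lo}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if exists(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


_TWO_NODE_SETS: tuple[tuple[int, ...], ...] = ((0,), (1,), (0, 1))
_CHAIN_SETS: tuple[tuple[int, ...], ...] = ((0,), (1,), (0, 1), (0, 2), (0, 1, 2))


def _format_set(members: Sequence[int]) -> str:
    return ",".join(str(i + 1) for i in members)


def d_table(
    model: str,
    params: TwoNodeParams | ChainParams,
    r1: float,
    r2: float,
    node_sets: Sequence[Sequence[int]] | None = None,
) -> pd.DataFrame:
    """d statistic for each sentinel set, from moments at r = r1 and r = r2.

    Returns a data frame with columns ``node_set`` (1-based labels), ``mu1``,
    ``var1``, ``mu2``, ``var2``, and ``d``.  Default node sets are {1}, {2},
    {1,2} for the two-node model and {1}, {2}, {1,2}, {1,3}, {1,2,3} for the
    chain.
    """
    if model == "two_node":
        cov = two_node_covariance
        default_sets = _TWO_NODE_SETS
    elif model == "chain":
        cov = chain_covariance
        default_sets = _CHAIN_SETS
    else:
        raise ValueError(f"unknown analytic model {model!r}")
    if node_sets is None:
        node_sets = default_sets
    c1 = cov(replace(params, r=r1))
    c2 = cov(replace(params, r=r2))
    rows = []
    for s in node_sets:
        m1: SignalMoments = signal_moments(c1, s, params.sample_size)
        m2: SignalMoments = signal_moments(c2, s, params.sample_size)
        rows.append(
            {
                "node_set": _format_set(sorted(s)),
                "mu1": m1.mean,
                "var1": m1.variance,
                "mu2": m2.mean,
                "var2": m2.variance,
                "d": d_statistic(m1, m2),
            }
        )
    return pd.DataFrame(rows)
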