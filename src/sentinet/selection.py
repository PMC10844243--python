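"""Sentinel node-set scoring and search, plus two baseline selectors.

The proposed selector scores a candidate node set ``S`` by the separability
``d`` of the averaged-variance signal between two values of the bifurcation
parameter, computed from the two sample covariance matrices alone (no network
structure or model equations needed).  ``optimize_d`` returns the argmax over
all sets of size ``n`` when ``C(N, n)`` is small enough, otherwise over a
uniform random sample of distinct sets (default cap 5000).

Baselines for comparison:

* *Large SD* — the n nodes with the largest sample standard deviation near
  the bifurcation point; requires no network information but tends to pick
  intrinsically noisy nodes.
* *High/Low Input* — the n nodes receiving the highest (for upward
  transitions) or lowest (downward) total input Σ_j w_ij x_j from their
  neighbours near the bifurcation point; requires the adjacency matrix.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .networks import Network
from .ou import SignalMoments, d_statistic, signal_moments, validate_node_set

__all__ = [
    "ScoredNodeSet",
    "sample_covariance",
    "score_node_set",
    "enumerate_node_sets",
    "optimize_d",
    "large_sd_select",
    "high_low_input_select",
]


@dataclass(frozen=True)
class ScoredNodeSet:
    """A node set with its d score and the two underlying signal moments."""

    node_set: tuple[int, ...]
    d: float
    moments_at_k1: SignalMoments
    moments_at_k2: SignalMoments


def sample_covariance(samples: np.ndarray) -> np.ndarray:
    """Unbiased (divisor L-1) sample covariance of an L×N sample matrix."""
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise ValueError("samples must be a 2-D L×N matrix")
    if samples.shape[0] < 2:
        raise ValueError(f"need at least 2 samples, got {samples.shape[0]}")
    c = np.cov(samples, rowvar=False, ddof=1)
    return np.atleast_2d(c)


def score_node_set(
    c1: np.ndarray,
    c2: np.ndarray,
    node_set: Sequence[int],
    sample_size: int,
) -> ScoredNodeSet:
    """d of the averaged-variance signal between the two covariance states."""
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    if c1.shape != c2.shape:
        raise ValueError("the two covariance matrices must have the same shape")
    members = validate_node_set(node_set, c1.shape[0])
    m1 = signal_moments(c1, members, sample_size)
    m2 = signal_moments(c2, members, sample_size)
    return ScoredNodeSet(
        node_set=members,
        d=d_statistic(m1, m2),
        moments_at_k1=m1,
        moments_at_k2=m2,
    )


def enumerate_node_sets(
    n_nodes: int,
    set_size: int,
    cap: int = 5000,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, ...]]:
    """All C(N, n) node sets if within ``cap``, else ``cap`` sampled distinct sets.

    Sets are returned as sorted tuples in lexicographic order.
    """
    if not 1 <= set_size <= n_nodes:
        raise ValueError(f"set size {set_size} out of range [1, {n_nodes}]")
    total = math.comb(n_nodes, set_size)
    if total <= cap:
        return [tuple(s) for s in itertools.combinations(range(n_nodes), set_size)]
    if rng is None:
        raise ValueError("rng required when sampling node sets")
    seen: set[tuple[int, ...]] = set()
    while len(seen) < cap:
        s = tuple(sorted(rng.choice(n_nodes, size=set_size, replace=False).tolist()))
        seen.add(s)
    return sorted(seen)


def optimize_d(
    c1: np.ndarray,
    c2: np.ndarray,
    set_size: int,
    sample_size: int,
    cap: int = 5000,
    rng: np.random.Generator | None = None,
) -> ScoredNodeSet:
    """The node set of size ``n`` maximizing d among the enumerated sets.

    Ties are broken in favour of the lexicographically smallest set.
    """
    best: ScoredNodeSet | None = None
    for s in enumerate_node_sets(np.asarray(c1).shape[0], set_size, cap, rng):
        scored = score_node_set(c1, c2, s, sample_size)
        if best is None or scored.d > best.d:
            best = scored
    assert best is not None
    return best


def _top_n(scores: np.ndarray, n: int, *, largest: bool) -> tuple[int, ...]:
    """Indices of the n extreme scores; ties favour the lowest node index."""
    if not 1 <= n <= len(scores):
        raise ValueError(f"set size {n} out of range [1, {len(scores)}]")
    key = -scores if largest else scores
    order = np.argsort(key, kind="stable")
    return tuple(sorted(int(i) for i in order[:n]))


def large_sd_select(samples: np.ndarray, set_size: int) -> tuple[int, ...]:
    """The n nodes with the largest sample standard deviation of x_i(t)."""
    samples = np.asarray(samples, dtype=float)
    if samples.shape[0] < 2:
        raise ValueError(f"need at least 2 samples, got {samples.shape[0]}")
    sds = samples.std(axis=0, ddof=1)
    return _top_n(sds, set_size, largest=True)


def high_low_input_select(
    net: Network,
    states: np.ndarray,
    set_size: int,
    direction: str,
) -> tuple[int, ...]:
    """The n nodes with the highest ('up') or lowest ('down') total input.

    The score of node i is Σ_j w_ij x_j with x the (time-averaged) state
    vector near the bifurcation point.  Upward transitions (double-well, SIS)
    use the highest input; downward transitions (mutualistic, gene
    regulatory) the lowest.
    """
    states = np.asarray(states, dtype=float)
    if states.shape != (net.n_nodes,):
        raise ValueError(f"states must have length {net.n_nodes}")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    inputs = net.adjacency @ states
    return _top_n(inputs, set_size, largest=direction == "up")
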