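"""Early-warning-signal series, Kendall's τ performance, and p1/p2 indices.

The performance of a sentinel set ``S`` over a sweep is the Kendall rank
correlation τ between its signal series (the averaged sample variance V̂_S,
or averaged sample standard deviation) and the bifurcation parameter.  A
perfect signal gives τ = 1 for an upward sweep and τ = -1 for a downward one;
comparisons for downward sweeps therefore use -τ throughout.

Two indices locate the τ of the d-maximizing set, τ*, within the τ values of
all examined sets of the same size:

* ``p1`` — twice the fraction of sets whose τ is strictly larger than τ*
  (0 = best, 1 = no better than a uniformly random pick, 2 = worst);
* ``p2`` — (τ_max - τ*) / (τ_max - ⟨τ⟩) (0 iff τ* = τ_max, 1 iff τ* = ⟨τ⟩).

``run_experiment`` ties the pipeline together: repeated independent sweep
series → sample covariances at the two measurement indices → optimize_d per
set size → τ for every examined set → p1, p2 and the τ–d correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from . import dynamics as dyn
from .dynamics import DynamicsSpec, HeterogeneityConfig
from .networks import Network
from .selection import enumerate_node_sets, sample_covariance, score_node_set
from .simulate import SimulationProtocol, SweepResult, run_sweep

__all__ = [
    "SignalSeries",
    "PerformanceSummary",
    "ExperimentConfig",
    "signal_series",
    "kendall_tau",
    "p1_p2",
    "evaluate_sweep",
    "run_experiment",
    "summarize_experiment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignalSeries:
    """An early warning signal evaluated along the sweep's parameter values."""

    parameter_values: np.ndarray
    values: np.ndarray
    node_set: tuple[int, ...]
    signal_kind: str  # "variance" or "standard_deviation"


def signal_series(
    sweep: SweepResult,
    node_set: Sequence[int],
    kind: str = "variance",
) -> SignalSeries:
    """Per parameter value, the node-set-averaged sample variance (or SD)."""
    if kind not in ("variance", "standard_deviation"):
        raise ValueError(f"unknown signal kind {kind!r}")
    members = tuple(sorted(int(i) for i in node_set))
    per_node = sweep.samples.var(axis=1, ddof=1)  # (K̃, N)
    if kind == "standard_deviation":
        per_node = np.sqrt(per_node)
    values = per_node[:, list(members)].mean(axis=1)
    return SignalSeries(
        parameter_values=sweep.parameter_values,
        values=values,
        node_set=members,
        signal_kind=kind,
    )


def kendall_tau(series: SignalSeries) -> float:
    """Kendall's τ (tau-b) between the signal and the bifurcation parameter.

    Returns NaN for a constant series (undefined correlation), rather than 0.
    """
    if len(series.values) < 2:
        raise ValueError("need at least 2 points to compute a correlation")
    if np.ptp(series.values) == 0 or np.ptp(series.parameter_values) == 0:
        return math.nan
    tau = scipy.stats.kendalltau(series.parameter_values, series.values).statistic
    return float(tau)


def p1_p2(
    taus: Sequence[float],
    tau_star: float,
    direction: str = "up",
) -> tuple[float, float]:
    """Quality indices of the d-maximizer's τ* among all examined sets' τ.

    For downward transitions a more negative τ is better, so all comparisons
    flip sign.  NaN τ values (constant series) are dropped.  Ties with τ* do
    not count against the optimized set.  p2 is NaN when all τ are equal.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    taus_arr = np.asarray(taus, dtype=float)
    taus_arr = taus_arr[np.isfinite(taus_arr)]
    if taus_arr.size == 0 or not np.isfinite(tau_star):
        return math.nan, math.nan
    if direction == "down":
        taus_arr = -taus_arr
        tau_star = -tau_star
    p1 = 2.0 * float(np.mean(taus_arr > tau_star))
    tau_max = float(taus_arr.max())
    tau_mean = float(taus_arr.mean())
    if tau_max == tau_mean:
        p2 = math.nan
    else:
        p2 = (tau_max - tau_star) / (tau_max - tau_mean)
    return p1, p2


def evaluate_sweep(
    sweep: SweepResult,
    set_sizes: Sequence[int],
    *,
    sample_size: int | None = None,
    cap: int = 5000,
    rng: np.random.Generator | None = None,
    direction: str = "up",
    signal_kind: str = "variance",
) -> pd.DataFrame:
    """Score and rank node sets of each size on one completed sweep.

    For every set size n: enumerate (or sample) candidate sets, compute d
    from the covariances at the two measurement indices and τ from the full
    signal series, locate the d-maximizer, and report p1, p2, τ*, τ_max,
    ⟨τ⟩, and the Pearson correlation between τ and d over the examined sets.
    """
    k1, k2 = sweep.measurement_indices
    samples1 = sweep.samples_at(k1)
    samples2 = sweep.samples_at(k2)
    if sample_size is None:
        sample_size = samples1.shape[0]
    c1 = sample_covariance(samples1)
    c2 = sample_covariance(samples2)
    n_nodes = c1.shape[0]
    rows = []
    for n in set_sizes:
        sets = enumerate_node_sets(n_nodes, n, cap, rng)
        ds = np.array(
            [score_node_set(c1, c2, s, sample_size).d for s in sets]
        )
        taus = np.array(
            [kendall_tau(signal_series(sweep, s, signal_kind)) for s in sets]
        )
        best_idx = int(np.argmax(ds))  # first (lexicographically smallest) argmax
        tau_star = float(taus[best_idx])
        p1, p2 = p1_p2(taus, tau_star, direction)
        finite = np.isfinite(taus) & np.isfinite(ds)
        if finite.sum() >= 2 and np.ptp(ds[finite]) > 0 and np.ptp(taus[finite]) > 0:
            corr = float(scipy.stats.pearsonr(taus[finite], ds[finite]).statistic)
        else:
            corr = math.nan
        signed = -1.0 if direction == "down" else 1.0
        rows.append(
            {
                "n": n,
                "node_set": ",".join(str(i + 1) for i in sets[best_idx]),
                "d": float(ds[best_idx]),
                "tau_star": tau_star,
                "tau_max": float(signed * np.nanmax(signed * taus)),
                "tau_mean": float(np.nanmean(taus)),
                "p1": p1,
                "p2": p2,
                "corr_tau_d": corr,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ExperimentConfig:
    """Full configuration for repeated sweep series on one model/network."""

    model: str
    network: Network
    parameter: str
    set_sizes: tuple[int, ...] = (1, 2, 3, 4, 5)
    heterogeneous_stress: bool = False
    heterogeneous_noise: bool = False
    n_series: int = 50
    cap: int = 5000
    seed: int = 0
    protocol: SimulationProtocol | None = None
    heterogeneity: HeterogeneityConfig = field(default_factory=HeterogeneityConfig)
    max_values: int = 10_000


@dataclass(frozen=True)
class PerformanceSummary:
    """Per-series evaluation rows plus per-set-size averages."""

    per_series: pd.DataFrame
    summary: pd.DataFrame


def run_experiment(config: ExperimentConfig) -> PerformanceSummary:
    """Repeat independent sweep series and evaluate the d-maximizer on each.

    Heterogeneity (Δu_i, Δσ_i) is drawn once per series.  Series whose sweep
    fails (e.g. fewer than two pre-transition parameter values) are dropped
    with a warning.
    """
    direction = dyn.sweep_direction(config.model)
    master = np.random.SeedSequence(config.seed)
    frames = []
    for series in range(config.n_series):
        het_ss, sweep_ss, sets_ss = master.spawn(3)
        spec = dyn.make_spec(
            config.model,
            config.network,
            coupling=0.0,
        )
        spec = dyn.make_heterogeneity(
            spec,
            config.heterogeneity,
            np.random.default_rng(het_ss),
            heterogeneous_stress=config.heterogeneous_stress,
            heterogeneous_noise=config.heterogeneous_noise,
        )
        try:
            sweep = run_sweep(
                spec,
                config.parameter,
                sweep_ss,
                protocol=config.protocol,
                max_values=config.max_values,
            )
        except (RuntimeError, ValueError) as exc:
            logger.warning("series %d dropped: %s", series, exc)
            continue
        if sweep.n_values < 2:
            logger.warning("series %d dropped: fewer than 2 parameter values", series)
            continue
        df = evaluate_sweep(
            sweep,
            config.set_sizes,
            cap=config.cap,
            rng=np.random.default_rng(sets_ss),
            direction=direction,
        )
        df.insert(0, "series", series)
        frames.append(df)
    if not frames:
        raise RuntimeError("every series was dropped; no usable results")
    per_series = pd.concat(frames, ignore_index=True)
    summary = (
        per_series.groupby("n")[["d", "tau_star", "p1", "p2", "corr_tau_d"]]
        .mean()
        .reset_index()
    )
    return PerformanceSummary(per_series=per_series, summary=summary)


def summarize_experiment(result: PerformanceSummary) -> pd.DataFrame:
    """Mean p1, p2, τ*, and τ–d correlation per set size."""
    return result.summary
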