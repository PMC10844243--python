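"""Euler–Maruyama integration, equilibrium sampling, and the bifurcation sweep.

A *sweep* is a series of independent simulations at linearly increasing (or
decreasing, depending on the model) values of a bifurcation parameter.  Every
simulation restarts from the model's common initial state, integrates with the
Euler–Maruyama scheme (default step 0.01), discards a model-specific
transient, and then records L = 100 evenly spaced equilibrium samples per
node.  The series stops at the first parameter value at which any node leaves
the neighbourhood of its initial state; only the K̃ pre-transition parameter
values are retained.  Covariance matrices for the selection stage are
estimated at the parameter indices k(1) = round(0.1 K̃) and
k(2) = round(0.9 K̃).

Randomness: each simulation in a sweep draws from its own child stream of a
single master ``numpy`` seed sequence, so results are bit-reproducible and
independent of execution order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import dynamics as dyn
from .dynamics import DynamicsSpec

__all__ = [
    "SimulationProtocol",
    "SweepResult",
    "EquilibriumRun",
    "DivergenceError",
    "euler_maruyama",
    "equilibrium_samples",
    "run_sweep",
    "select_measurement_indices",
    "save_sweep",
    "load_sweep",
]


class DivergenceError(RuntimeError):
    """The integrated state became non-finite."""


@dataclass(frozen=True)
class SimulationProtocol:
    """Time discretization and sampling plan for one simulation.

    Defaults are filled per model: transient 100 TU and sample spacing 1 TU
    (10 TU and 0.1 TU for the faster mutualistic dynamics), dt = 0.01,
    L = 100 samples.
    """

    dt: float = 0.01
    transient: float | None = None
    spacing: float | None = None
    n_samples: int = 100

    def resolve(self, spec: DynamicsSpec) -> "SimulationProtocol":
        info = spec.info
        return SimulationProtocol(
            dt=self.dt,
            transient=info.transient if self.transient is None else self.transient,
            spacing=info.spacing if self.spacing is None else self.spacing,
            n_samples=self.n_samples,
        )


def _compiled_drift(spec: DynamicsSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Drift closure with the adjacency matrix and constants captured once."""
    w = spec.network.adjacency
    c = spec.constants
    d = spec.coupling
    u = spec.stress + spec.stress_offsets
    if spec.model == "double_well":
        r1, r2, r3 = c["r1"], c["r2"], c["r3"]

        def f(x: np.ndarray) -> np.ndarray:
            return -(x - r1) * (x - r2) * (x - r3) + d * (w @ x) + u

    elif spec.model == "mutualistic":
        b = c["B"] + u
        k, cc, dt_, e, h = c["K"], c["C"], c["Dtilde"], c["E"], c["H"]

        def f(x: np.ndarray) -> np.ndarray:
            growth = x * (1.0 - x / k) * (x / cc - 1.0)
            denom = dt_ + e * x[:, None] + h * x[None, :]
            return b + growth + d * x * ((w * (x[None, :] / denom)).sum(axis=1))

    elif spec.model == "gene_regulatory":
        bconst, fexp, hexp = c["B"], c["f"], c["h"]

        def f(x: np.ndarray) -> np.ndarray:
            xh = x**hexp
            return -bconst * x**fexp + d * (w @ (xh / (xh + 1.0))) + u

    elif spec.model == "sis":
        mu = c["mu"]

        def f(x: np.ndarray) -> np.ndarray:
            return d * (1.0 - x) * (w @ x) - mu * x

    else:  # pragma: no cover - guarded by DynamicsSpec
        raise ValueError(f"unknown dynamics model {spec.model!r}")
    return f


def euler_maruyama(
    spec: DynamicsSpec,
    x0: np.ndarray,
    dt: float,
    duration: float,
    rng: np.random.Generator,
    *,
    record_every: int | None = None,
) -> np.ndarray:
    """Integrate ``dx = drift dt + σ_i dW_i`` and return recorded states.

    ``x(t+dt) = x(t) + drift(x) dt + σ_i sqrt(dt) ξ_i`` with independent
    standard-normal ξ_i.  States are clamped at zero after each step for the
    models that require it.  Records every ``record_every`` steps (default:
    only the final state); the initial state is not recorded.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(round(duration / dt))
    if n_steps < 1:
        raise ValueError("duration must cover at least one step")
    f = _compiled_drift(spec)
    clamp = spec.info.clamp_nonnegative
    sqrt_dt = math.sqrt(dt)
    sigma = spec.noise
    x = np.array(x0, dtype=float)
    if record_every is None:
        record_every = n_steps
    out = np.empty((n_steps // record_every, spec.n_nodes))
    noise = rng.standard_normal((n_steps, spec.n_nodes))
    j = 0
    for step in range(n_steps):
        x = x + f(x) * dt + sigma * sqrt_dt * noise[step]
        if clamp:
            np.maximum(x, 0.0, out=x)
        if not np.isfinite(x).all():
            raise DivergenceError(f"non-finite state at step {step + 1}")
        if (step + 1) % record_every == 0:
            out[j] = x
            j += 1
    return out


@dataclass(frozen=True)
class EquilibriumRun:
    """L×N equilibrium samples plus whether the stop condition fired."""

    samples: np.ndarray
    transitioned: bool
    final_state: np.ndarray


def equilibrium_samples(
    spec: DynamicsSpec,
    rng: np.random.Generator,
    protocol: SimulationProtocol | None = None,
) -> EquilibriumRun:
    """Discard the transient, then record L evenly spaced equilibrium samples.

    The stop condition (any node leaving its initial neighbourhood) is checked
    at every integration step of both the transient and the sampling phase;
    if it ever fires the run is flagged as transitioned.
    """
    protocol = (protocol or SimulationProtocol()).resolve(spec)
    dt = protocol.dt
    transient_steps = int(round(protocol.transient / dt))
    spacing_steps = max(int(round(protocol.spacing / dt)), 1)
    sample_steps = spacing_steps * protocol.n_samples
    n_steps = transient_steps + sample_steps

    f = _compiled_drift(spec)
    clamp = spec.info.clamp_nonnegative
    info = spec.info
    sqrt_dt = math.sqrt(dt)
    sigma = spec.noise
    x = dyn.initial_state(spec)
    samples = np.empty((protocol.n_samples, spec.n_nodes))
    noise = rng.standard_normal((n_steps, spec.n_nodes))
    transitioned = False
    j = 0
    threshold, above = info.stop_threshold, info.stop_above
    for step in range(n_steps):
        x = x + f(x) * dt + sigma * sqrt_dt * noise[step]
        if clamp:
            np.maximum(x, 0.0, out=x)
        if not np.isfinite(x).all():
            raise DivergenceError(f"non-finite state at step {step + 1}")
        if above:
            if x.max() >= threshold:
                transitioned = True
        elif x.min() < threshold:
            transitioned = True
        if step >= transient_steps and (step - transient_steps + 1) % spacing_steps == 0:
            samples[j] = x
            j += 1
    return EquilibriumRun(samples=samples, transitioned=transitioned, final_state=x)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def select_measurement_indices(n_values: int) -> tuple[int, int]:
    """1-based indices (round(0.1 K̃), round(0.9 K̃)), clipped into [1, K̃].

    Rounding is half away from zero; the first index is clipped up to 1 when
    round(0.1 K̃) = 0.
    """
    if n_values < 2:
        raise ValueError(f"need at least 2 parameter values, got {n_values}")
    k1 = max(_round_half_away(0.1 * n_values), 1)
    k2 = min(_round_half_away(0.9 * n_values), n_values)
    if k1 >= k2:
        raise ValueError(f"degenerate measurement indices ({k1}, {k2})")
    return k1, k2


@dataclass(frozen=True)
class SweepResult:
    """All pre-transition equilibrium samples of one bifurcation sweep."""

    parameter_name: str
    parameter_values: np.ndarray  # shape (K̃,)
    samples: np.ndarray  # shape (K̃, L, N)
    measurement_indices: tuple[int, int]  # 1-based (k1, k2)
    transition_parameter: float | None

    @property
    def n_values(self) -> int:
        return len(self.parameter_values)

    def samples_at(self, k: int) -> np.ndarray:
        """L×N sample matrix at 1-based parameter index k."""
        if not 1 <= k <= self.n_values:
            raise IndexError(f"parameter index {k} out of range [1, {self.n_values}]")
        return self.samples[k - 1]


def _spec_with_parameter(
    spec: DynamicsSpec, parameter: str, value: float
) -> DynamicsSpec:
    if parameter == "u":
        return replace(spec, stress=value)
    if parameter in ("D", "lambda"):
        return replace(spec, coupling=value)
    raise ValueError(f"unknown bifurcation parameter {parameter!r}")


def run_sweep(
    spec: DynamicsSpec,
    parameter: str,
    seed: int | np.random.SeedSequence,
    *,
    protocol: SimulationProtocol | None = None,
    max_values: int = 10_000,
) -> SweepResult:
    """Sweep the bifurcation parameter until the first transition.

    ``spec`` supplies the model, network, and per-node heterogeneity; its
    stress/coupling are overridden by the sweep's starting values.  Each
    simulation restarts from the common initial state with a fresh child
    random stream of ``seed``.  Raises if the very first parameter value
    already transitions (no usable series) or if ``max_values`` is exceeded.
    """
    step = dyn.parameter_step(spec, parameter)
    u0, d0 = dyn.initial_parameters(spec.model, parameter)
    spec = replace(spec, stress=u0, coupling=d0)
    value = u0 if parameter == "u" else d0
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    values: list[float] = []
    all_samples: list[np.ndarray] = []
    transition_parameter = None
    for _ in range(max_values):
        rng = np.random.default_rng(ss.spawn(1)[0])
        run = equilibrium_samples(
            _spec_with_parameter(spec, parameter, value), rng, protocol
        )
        if run.transitioned:
            transition_parameter = value
            break
        values.append(value)
        all_samples.append(run.samples)
        value += step
    else:
        raise RuntimeError(
            f"no transition within max_values={max_values} parameter values"
        )
    if len(values) == 0:
        raise RuntimeError(
            "transition at the very first parameter value: no usable series"
        )
    indices = (
        select_measurement_indices(len(values)) if len(values) >= 2 else (1, 1)
    )
    return SweepResult(
        parameter_name=parameter,
        parameter_values=np.asarray(values),
        samples=np.asarray(all_samples),
        measurement_indices=indices,
        transition_parameter=transition_parameter,
    )


def save_sweep(result: SweepResult, directory: str | Path) -> None:
    """Persist a sweep as params.csv, one samples_k.csv per value, meta.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"k": np.arange(1, result.n_values + 1), "value": result.parameter_values}
    ).to_csv(directory / "params.csv", index=False)
    for k in range(1, result.n_values + 1):
        pd.DataFrame(result.samples_at(k)).to_csv(
            directory / f"samples_{k:04d}.csv", index=False
        )
    meta = {
        "parameter_name": result.parameter_name,
        "measurement_indices": list(result.measurement_indices),
        "transition_parameter": result.transition_parameter,
        "n_values": result.n_values,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def load_sweep(directory: str | Path) -> SweepResult:
    """Load a sweep written by :func:`save_sweep`."""
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    params = pd.read_csv(directory / "params.csv")
    samples = np.asarray(
        [
            pd.read_csv(directory / f"samples_{k:04d}.csv").to_numpy(dtype=float)
            for k in range(1, meta["n_values"] + 1)
        ]
    )
    return SweepResult(
        parameter_name=meta["parameter_name"],
        parameter_values=params["value"].to_numpy(dtype=float),
        samples=samples,
        measurement_indices=tuple(meta["measurement_indices"]),
        transition_parameter=meta["transition_parameter"],
    )
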