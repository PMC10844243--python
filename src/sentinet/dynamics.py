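"""Drift and noise specifications for the four network dynamics models.

Supported models (``x_i`` is the state of node i, ``w_ij`` the 0/1 adjacency):

``double_well``
    dx_i = [-(x_i - r1)(x_i - r2)(x_i - r3) + D Σ_j w_ij x_j + u_i] dt + σ_i dW_i
    Species abundance / climate-patch dynamics; nodes sit in a lower well near
    r1 and may tip to the upper well near r3 as stress u or coupling D grows.

``mutualistic``
    dx_i = [B_i + x_i (1 - x_i/K_i)(x_i/C_i - 1)
            + D Σ_j w_ij x_i x_j / (D̃_i + E_i x_i + H_j x_j)] dt + σ_i dW_i
    Mutualistic species interactions with migration B_i = 0.1 + u + Δu_i; loss
    of resilience is approached by *decreasing* the bifurcation parameter.

``gene_regulatory``
    dx_i = [-B x_i^f + D Σ_j w_ij x_j^h / (x_j^h + 1) + u_i] dt + σ_i dW_i
    Michaelis–Menten gene regulation (B = 1, f = 1, h = 2); also a downward
    sweep.  States are clamped at zero after each integration step.

``sis``
    dx_i = [λ Σ_j w_ij (1 - x_i) x_j - μ x_i] dt + σ_i dW_i
    Deterministic SIS epidemic approximation (μ = 1); infection rate λ plays
    the role of the coupling and is the only bifurcation parameter, because a
    stress term would create infecteds out of nothing.  States clamped at 0.

Node stress heterogeneity draws Δu_i ~ U[-0.25, 0.25] and noise heterogeneity
draws Δσ_i ~ U[-0.9 σ, 0.9 σ] once per series; the draws are then fixed node
properties for every simulation in that series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .networks import Network

__all__ = [
    "DynamicsSpec",
    "HeterogeneityConfig",
    "MODELS",
    "make_spec",
    "make_heterogeneity",
    "drift",
    "initial_state",
    "stop_condition",
    "parameter_step",
    "initial_parameters",
    "sweep_direction",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelInfo:
    """Static per-model constants and sweep protocol entries."""

    constants: Mapping[str, float]
    base_sigma: float
    initial_value: float
    stop_threshold: float
    stop_above: bool  # stop once any x_i >= threshold (else: < threshold)
    # per bifurcation parameter: (initial stress u, initial coupling D, step)
    sweeps: Mapping[str, tuple[float, float, float]]
    clamp_nonnegative: bool
    transient: float  # time units discarded before sampling
    spacing: float  # time units between recorded samples
    supports_stress_heterogeneity: bool = True


MODELS: dict[str, ModelInfo] = {
    "double_well": ModelInfo(
        constants={"r1": 1.0, "r2": 3.0, "r3": 5.0},
        base_sigma=0.05,
        initial_value=1.0,
        stop_threshold=3.0,
        stop_above=True,
        sweeps={"u": (0.0, 0.05, 0.025), "D": (0.0, 0.0, 0.0025)},
        clamp_nonnegative=False,
        transient=100.0,
        spacing=1.0,
    ),
    "mutualistic": ModelInfo(
        constants={"B": 0.1, "C": 1.0, "Dtilde": 5.0, "E": 0.9, "H": 0.1, "K": 5.0},
        base_sigma=0.25,
        initial_value=5.0,
        stop_threshold=0.1,
        stop_above=False,
        sweeps={"u": (0.0, 1.0, -0.1), "D": (0.0, 1.0, -0.01)},
        clamp_nonnegative=False,
        transient=10.0,
        spacing=0.1,
    ),
    "gene_regulatory": ModelInfo(
        constants={"B": 1.0, "f": 1.0, "h": 2.0},
        base_sigma=5e-6,
        initial_value=5.0,
        stop_threshold=0.1,
        stop_above=False,
        sweeps={"u": (0.0, 1.0, -0.01), "D": (0.0, 1.0, -0.01)},
        clamp_nonnegative=True,
        transient=100.0,
        spacing=1.0,
    ),
    "sis": ModelInfo(
        constants={"mu": 1.0},
        base_sigma=5e-4,
        initial_value=0.001,
        stop_threshold=0.1,
        stop_above=True,
        sweeps={"lambda": (0.0, 0.0, 0.0025)},
        clamp_nonnegative=True,
        transient=100.0,
        spacing=1.0,
        supports_stress_heterogeneity=False,
    ),
}


@dataclass(frozen=True)
class HeterogeneityConfig:
    """Widths of the per-node stress and noise heterogeneity draws."""

    stress_half_width: float = 0.25
    noise_relative_half_width: float = 0.9

    def __post_init__(self) -> None:
        if self.stress_half_width < 0:
            raise ValueError("stress_half_width must be >= 0")
        if not 0 <= self.noise_relative_half_width < 1:
            raise ValueError("noise_relative_half_width must be in [0, 1)")


@dataclass(frozen=True)
class DynamicsSpec:
    """A dynamics model bound to a network with all per-node parameters.

    ``coupling`` is D (or the infection rate λ for SIS); ``stress`` is the
    global stress u; ``stress_offsets`` holds Δu_i and ``noise`` holds σ_i.
    """

    model: str
    network: Network
    coupling: float
    stress: float = 0.0
    stress_offsets: np.ndarray = field(default=None)  # type: ignore[assignment]
    noise: np.ndarray = field(default=None)  # type: ignore[assignment]
    constants: Mapping[str, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown dynamics model {self.model!r}")
        info = MODELS[self.model]
        n = self.network.n_nodes
        offs = self.stress_offsets
        offs = np.zeros(n) if offs is None else np.asarray(offs, dtype=float)
        sig = self.noise
        sig = np.full(n, info.base_sigma) if sig is None else np.asarray(sig, float)
        if offs.shape != (n,) or sig.shape != (n,):
            raise ValueError("per-node parameter vectors must have length N")
        if (sig < 0).any():
            raise ValueError("noise intensities must be non-negative")
        consts = dict(info.constants)
        if self.constants is not None:
            consts.update(self.constants)
        object.__setattr__(self, "stress_offsets", offs)
        object.__setattr__(self, "noise", sig)
        object.__setattr__(self, "constants", consts)

    @property
    def info(self) -> ModelInfo:
        return MODELS[self.model]

    @property
    def n_nodes(self) -> int:
        return self.network.n_nodes


def make_spec(
    model: str,
    network: Network,
    *,
    coupling: float,
    stress: float = 0.0,
    stress_offsets: np.ndarray | None = None,
    noise: np.ndarray | None = None,
    constants: Mapping[str, float] | None = None,
) -> DynamicsSpec:
    """Convenience constructor applying per-model defaults."""
    return DynamicsSpec(
        model=model,
        network=network,
        coupling=coupling,
        stress=stress,
        stress_offsets=stress_offsets,
        noise=noise,
        constants=constants,
    )


def make_heterogeneity(
    spec: DynamicsSpec,
    cfg: HeterogeneityConfig,
    rng: np.random.Generator,
    *,
    heterogeneous_stress: bool = False,
    heterogeneous_noise: bool = False,
) -> DynamicsSpec:
    """Draw per-node stress offsets Δu_i and noise intensities σ_i.

    Δu_i ~ U[-a, a] with a = ``cfg.stress_half_width`` and
    σ_i = σ (1 + U[-b, b]) with b = ``cfg.noise_relative_half_width`` and σ
    the model's base noise.  Homogeneous directions are left at Δu_i = 0 and
    σ_i = σ.  SIS has no concept of node stress, so requesting stress
    heterogeneity for it is an error.
    """
    info = spec.info
    n = spec.n_nodes
    if heterogeneous_stress and not info.supports_stress_heterogeneity:
        raise ValueError(f"model {spec.model!r} does not support stress heterogeneity")
    offsets = np.zeros(n)
    if heterogeneous_stress:
        a = cfg.stress_half_width
        offsets = rng.uniform(-a, a, size=n)
    sigma = np.full(n, info.base_sigma)
    if heterogeneous_noise:
        b = cfg.noise_relative_half_width
        sigma = info.base_sigma * (1.0 + rng.uniform(-b, b, size=n))
    return replace(spec, stress_offsets=offsets, noise=sigma)


def drift(spec: DynamicsSpec, state: np.ndarray) -> np.ndarray:
    """Deterministic part of dx/dt for every node."""
    x = np.asarray(state, dtype=float)
    if x.shape != (spec.n_nodes,):
        raise ValueError(f"state must have length {spec.n_nodes}")
    w = spec.network.adjacency
    c = spec.constants
    d = spec.coupling
    u = spec.stress + spec.stress_offsets
    if spec.model == "double_well":
        r1, r2, r3 = c["r1"], c["r2"], c["r3"]
        return -(x - r1) * (x - r2) * (x - r3) + d * (w @ x) + u
    if spec.model == "mutualistic":
        b = c["B"] + u
        if (b < 0).any():
            warnings.warn(
                "mutualistic migration rate B_i went negative", stacklevel=2
            )
        growth = x * (1.0 - x / c["K"]) * (x / c["C"] - 1.0)
        denom = c["Dtilde"] + c["E"] * x[:, None] + c["H"] * x[None, :]
        mutual = d * x * ((w * (x[None, :] / denom)).sum(axis=1))
        return b + growth + mutual
    if spec.model == "gene_regulatory":
        xh = x ** c["h"]
        return -c["B"] * x ** c["f"] + d * (w @ (xh / (xh + 1.0))) + u
    if spec.model == "sis":
        return d * (1.0 - x) * (w @ x) - c["mu"] * x
    raise ValueError(f"unknown dynamics model {spec.model!r}")


def initial_state(spec: DynamicsSpec) -> np.ndarray:
    """The common starting value of every node for this model."""
    return np.full(spec.n_nodes, spec.info.initial_value)


def stop_condition(spec: DynamicsSpec, state: np.ndarray) -> bool:
    """True once any node is no longer near its initial state."""
    info = spec.info
    if info.stop_above:
        return bool(np.max(state) >= info.stop_threshold)
    return bool(np.min(state) < info.stop_threshold)


def parameter_step(spec: DynamicsSpec, parameter: str) -> float:
    """Signed increment of the bifurcation parameter between simulations."""
    info = spec.info
    if parameter not in info.sweeps:
        raise ValueError(
            f"model {spec.model!r} has no sweep parameter {parameter!r}; "
            f"choose from {sorted(info.sweeps)}"
        )
    return info.sweeps[parameter][2]


def initial_parameters(model: str, parameter: str) -> tuple[float, float]:
    """Starting (stress u, coupling D-or-λ) for a sweep of ``parameter``."""
    if model not in MODELS:
        raise ValueError(f"unknown dynamics model {model!r}")
    info = MODELS[model]
    if parameter not in info.sweeps:
        raise ValueError(
            f"model {model!r} has no sweep parameter {parameter!r}; "
            f"choose from {sorted(info.sweeps)}"
        )
    u0, d0, _ = info.sweeps[parameter]
    return u0, d0


def sweep_direction(model: str) -> str:
    """'up' if the bifurcation parameter increases toward the transition."""
    if model not in MODELS:
        raise ValueError(f"unknown dynamics model {model!r}")
    step = next(iter(MODELS[model].sweeps.values()))[2]
    return "up" if step > 0 else "down"
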