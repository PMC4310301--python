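"""Conductance-based integrate-and-fire dynamics.

Each neuron follows

    dV_i/dt = -g_L V_i + sum_j g_ij (E_rev - V_i),

with a spike emitted when V_i >= 1 mV, after which V_i is clamped to 0 for a
refractory period of 10 ms.  The synaptic conductance g_ij (synapse j -> i)
decays exponentially with tau_g = 10 ms and jumps by the effective efficacy
w_ij = r_ij * u_ij * A_ij whenever presynaptic neuron j fires.

Numerically, g_L and the g_ij are treated as rates in 1/ms so that the
equation is dimensionally consistent with V in mV and t in ms; the constants
are used exactly as printed in the source model.  V is integrated with
explicit Euler at dt = 1 ms; conductances decay with the exact exponential
factor per step (stabler than Euler for tau_g ~ dt, and exact for the linear
decay between spikes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "V_THR",
    "T_REF",
    "E_REV",
    "G_LEAK",
    "TAU_G",
    "NU_LIM",
    "SimClock",
    "NeuronState",
    "ConductanceState",
    "SimulationDiverged",
    "step_membrane",
    "detect_spikes",
    "decay_and_inject_conductance",
]

V_THR = 1.0  # mV, spike threshold
T_REF = 10.0  # ms, refractory period
E_REV = 30.0  # mV, reversal potential
G_LEAK = 0.1  # 1/ms, leak conductance
TAU_G = 10.0  # ms, conductance decay constant
#: maximum sustainable firing rate imposed by the refractory period (Hz)
NU_LIM = 1000.0 / T_REF


class SimulationDiverged(RuntimeError):
    """Raised when the membrane potential becomes non-finite."""


@dataclass
class SimClock:
    """Simulation clock: current time ``t`` and fixed step ``dt`` (ms)."""

    dt: float = 1.0
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")

    def advance(self) -> None:
        self.t += self.dt


@dataclass
class NeuronState:
    """Membrane potentials, refractory bookkeeping and current spike flags."""

    v: np.ndarray
    refractory_until: np.ndarray
    spiked: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "NeuronState":
        return cls(
            v=np.zeros(n),
            refractory_until=np.full(n, -np.inf),
            spiked=np.zeros(n, dtype=bool),
        )

    @property
    def n(self) -> int:
        return self.v.shape[0]

    def refractory(self, t: float) -> np.ndarray:
        """Boolean mask of neurons still inside their refractory period."""
        return t < self.refractory_until


@dataclass
class ConductanceState:
    """Synaptic conductance matrix; entry (i, j) is the synapse j -> i."""

    g: np.ndarray
    g_leak: float = G_LEAK
    e_rev: float = E_REV
    tau_g: float = TAU_G

    @classmethod
    def zeros(cls, n: int, **kwargs) -> "ConductanceState":
        return cls(g=np.zeros((n, n)), **kwargs)

    def decay_factor(self, dt: float) -> float:
        return float(np.exp(-dt / self.tau_g))


def step_membrane(
    neurons: NeuronState, cond: ConductanceState, clock: SimClock
) -> NeuronState:
    """One explicit-Euler step of the subthreshold membrane dynamics.

    Refractory neurons are held at V = 0 (their conductances keep evolving;
    only the potential is clamped).  Mutates and returns ``neurons``.
    """
    v = neurons.v
    gsum = cond.g.sum(axis=1)
    v += clock.dt * (-cond.g_leak * v + gsum * (cond.e_rev - v))
    v[neurons.refractory(clock.t)] = 0.0
    if not np.all(np.isfinite(v)):
        bad = np.flatnonzero(~np.isfinite(v))
        raise SimulationDiverged(
            f"non-finite membrane potential at t={clock.t} ms for neurons {bad[:10]}"
        )
    return neurons


def detect_spikes(neurons: NeuronState, clock: SimClock) -> NeuronState:
    """Flag threshold crossings, reset V and start the refractory period.

    A neuron spikes when V >= 1 mV and it is not refractory; its potential is
    reset to 0 and held there for the next 10 ms, bounding sustained firing at
    ``NU_LIM`` = 100 Hz.  Mutates and returns ``neurons``.
    """
    sp = (neurons.v >= V_THR) & ~neurons.refractory(clock.t)
    neurons.spiked = sp
    neurons.v[sp] = 0.0
    neurons.refractory_until[sp] = clock.t + T_REF
    return neurons


def decay_and_inject_conductance(
    cond: ConductanceState,
    presyn_spikes: np.ndarray,
    w: np.ndarray,
    clock: SimClock,
) -> ConductanceState:
    """Exponentially decay g, then add w_ij for every spiking presynaptic j.

    ``w`` is the matrix of effective efficacies r*u*A already evaluated at
    this step's spike times; it must be non-negative.  Mutates and returns
    ``cond``.
    """
    cond.g *= cond.decay_factor(clock.dt)
    cols = np.flatnonzero(presyn_spikes)
    if cols.size:
        w_cols = w[:, cols]
        if np.any(w_cols < 0):
            raise ValueError("negative effective efficacy w; upstream invariant violated")
        cond.g[:, cols] += w_cols
        # no self-synapse: the diagonal stays identically zero
        cond.g[cols, cols] = 0.0
    return cond
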