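"""Triplet spike-timing-dependent plasticity with hard bounds.

Each neuron i carries two presynaptic trace variables (m1, m2) and two
postsynaptic ones (o1, o2) that decay exponentially and jump by 1 at the
neuron's own spikes.  When neuron i fires:

  * every incoming synapse j -> i is potentiated by
        +gamma * m1_j * (A2_plus + A3_plus * o2_i^-)
  * every outgoing synapse i -> j is depressed by
        -gamma * o1_j * (A2_minus + A3_minus * m2_i^-)

where o2_i^- and m2_i^- are the slow-trace values just *before* the +1
increment due to this spike (the epsilon convention).  The slow traces make
potentiation frequency-dependent: at high rates the rule behaves Hebbian
("fire together, wire together"), at low rates it reduces to the classical
pair rule.  Maximum strengths A are hard-bounded in [A_MIN, A_MAX]; clipping
is applied once per step after summing the STDP and STP-driven deltas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SimClock

__all__ = [
    "TAU_M1",
    "TAU_M2",
    "TAU_O1",
    "TAU_O2",
    "A_MIN",
    "A_MAX",
    "STDPConstants",
    "TripletTraces",
    "traces_step",
    "stdp_on_postsynaptic_spike",
    "clip_weights",
]

TAU_M1 = 16.8  # ms, fast presynaptic trace
TAU_M2 = 575.0  # ms, slow presynaptic trace
TAU_O1 = 33.7  # ms, fast postsynaptic trace
TAU_O2 = 47.0  # ms, slow postsynaptic trace

A_MIN = 1e-3
A_MAX = 1.0


@dataclass
class STDPConstants:
    """Triplet-rule amplitudes and the shared learning rate gamma."""

    a2_plus: float = 4.6e-3
    a3_plus: float = 9.1e-3
    a2_minus: float = 3.0e-3
    a3_minus: float = 7.5e-9
    gamma: float = 1.0


@dataclass
class TripletTraces:
    """Per-neuron spike-history indicators m1, m2 (pre) and o1, o2 (post)."""

    m1: np.ndarray
    m2: np.ndarray
    o1: np.ndarray
    o2: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "TripletTraces":
        return cls(np.zeros(n), np.zeros(n), np.zeros(n), np.zeros(n))

    def decay(self, dt: float) -> None:
        self.m1 *= np.exp(-dt / TAU_M1)
        self.m2 *= np.exp(-dt / TAU_M2)
        self.o1 *= np.exp(-dt / TAU_O1)
        self.o2 *= np.exp(-dt / TAU_O2)

    def increment(self, spiked: np.ndarray) -> None:
        """+1 on all four traces of every spiking neuron."""
        self.m1[spiked] += 1.0
        self.m2[spiked] += 1.0
        self.o1[spiked] += 1.0
        self.o2[spiked] += 1.0


def traces_step(
    traces: TripletTraces, spikes: np.ndarray, clock: SimClock
) -> TripletTraces:
    """Exponential decay over one dt, then +1 for each spiking neuron."""
    traces.decay(clock.dt)
    traces.increment(spikes)
    return traces


def stdp_on_postsynaptic_spike(
    traces: TripletTraces, i: int, const: STDPConstants
) -> tuple:
    """Weight deltas triggered by a spike of neuron i.

    Must be called with trace values after this step's decay but *before*
    the +1 increments of this step's spikes (the epsilon convention; a
    partner spiking in the same step therefore contributes nothing yet).

    Returns ``(d_incoming, d_outgoing)``: d_incoming[j] is the potentiation
    of synapse j -> i, d_outgoing[j] the (negative) depression of i -> j.
    The diagonal entries are meaningless and must be masked by the caller.
    """
    d_in = const.gamma * traces.m1 * (const.a2_plus + const.a3_plus * traces.o2[i])
    d_out = -const.gamma * traces.o1 * (const.a2_minus + const.a3_minus * traces.m2[i])
    return d_in, d_out


def clip_weights(A: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Clip A to [A_MIN, A_MAX] in place; absent synapses stay at 0."""
    np.clip(A, A_MIN, A_MAX, out=A)
    if mask is not None:
        A *= mask
    return A
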