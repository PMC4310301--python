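"""Tsodyks-Markram short-term plasticity (depression r, facilitation u).

Between spikes each synapse relaxes to its rest state,

    dr/dt = (1 - r)/tau_rec,      du/dt = (U - u)/tau_facil,

and at each presynaptic spike the facilitation variable jumps by U(1 - u)
while resources r are consumed in proportion to the released fraction r*u.
The per-spike release amplitude r*u, multiplied by the maximum strength A,
gives the effective efficacy w = r*u*A.

Convention: by default the facilitation increment is applied *before* the
release is evaluated (the standard TM convention); set
``facilitation_first=False`` for the release-then-facilitate variant.  Both
are supported because the impulsive terms of the kinetic equations do not fix
the order.

The continuous relaxation is integrated with explicit Euler at dt = 1 ms,
which is stable for the admissible time constants (tau_facil >= 1 ms,
tau_rec >= 100 ms); the event-driven spike-to-spike map used by
:func:`synapse_trace` and :func:`stp_steady_state` is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SimClock

__all__ = [
    "U_MIN",
    "U_MAX",
    "TAU_REC_MIN",
    "TAU_REC_MAX",
    "TAU_FACIL_MIN",
    "TAU_FACIL_MAX",
    "STPParams",
    "STPState",
    "stp_decay_step",
    "stp_spike_update",
    "stp_on_presynaptic_spike",
    "stp_steady_state",
    "synapse_trace",
    "classify_trace",
]

U_MIN, U_MAX = 0.05, 0.95
TAU_REC_MIN, TAU_REC_MAX = 100.0, 900.0  # ms
TAU_FACIL_MIN, TAU_FACIL_MAX = 1.0, 900.0  # ms


@dataclass
class STPParams:
    """Per-synapse TM parameters U, tau_rec (ms), tau_facil (ms)."""

    U: np.ndarray
    tau_rec: np.ndarray
    tau_facil: np.ndarray

    @classmethod
    def from_uniform(cls, shape, rng: np.random.Generator) -> "STPParams":
        """Draw each parameter iid uniform over its admissible range."""
        return cls(
            U=rng.uniform(U_MIN, U_MAX, shape),
            tau_rec=rng.uniform(TAU_REC_MIN, TAU_REC_MAX, shape),
            tau_facil=rng.uniform(TAU_FACIL_MIN, TAU_FACIL_MAX, shape),
        )

    @classmethod
    def scalar(cls, U: float, tau_rec: float, tau_facil: float) -> "STPParams":
        return cls(
            U=np.asarray(float(U)),
            tau_rec=np.asarray(float(tau_rec)),
            tau_facil=np.asarray(float(tau_facil)),
        )

    def clip(self) -> "STPParams":
        """Clip all parameters to their hard bounds, in place."""
        np.clip(self.U, U_MIN, U_MAX, out=self.U)
        np.clip(self.tau_rec, TAU_REC_MIN, TAU_REC_MAX, out=self.tau_rec)
        np.clip(self.tau_facil, TAU_FACIL_MIN, TAU_FACIL_MAX, out=self.tau_facil)
        return self

    def validate(self) -> None:
        for name, arr, lo, hi in (
            ("U", self.U, U_MIN, U_MAX),
            ("tau_rec", self.tau_rec, TAU_REC_MIN, TAU_REC_MAX),
            ("tau_facil", self.tau_facil, TAU_FACIL_MIN, TAU_FACIL_MAX),
        ):
            a = np.asarray(arr)
            if a.size and (np.nanmin(a) < lo or np.nanmax(a) > hi):
                raise ValueError(f"{name} outside bounds [{lo}, {hi}]")


@dataclass
class STPState:
    """Dynamic synapse state: resources r and utilization u, both in [0, 1]."""

    r: np.ndarray
    u: np.ndarray

    @classmethod
    def at_rest(cls, params: STPParams) -> "STPState":
        """Rest state r = 1, u = U (the no-spike fixed point)."""
        U = np.asarray(params.U, dtype=float)
        return cls(r=np.ones_like(U), u=U.copy())


def stp_decay_step(state: STPState, params: STPParams, clock: SimClock) -> STPState:
    """Euler relaxation of r toward 1 and u toward U over one dt."""
    state.r += clock.dt * (1.0 - state.r) / params.tau_rec
    state.u += clock.dt * (params.U - state.u) / params.tau_facil
    return state


def stp_spike_update(r, u, U, facilitation_first: bool = True):
    """Pure spike map: returns (r_new, u_new, release) for arrays r, u, U.

    release = r*u with u taken post-increment (default) or pre-increment.
    """
    r = np.asarray(r, dtype=float)
    u = np.asarray(u, dtype=float)
    U = np.asarray(U, dtype=float)
    if facilitation_first:
        u_new = u + U * (1.0 - u)
        release = r * u_new
    else:
        release = r * u
        u_new = u + U * (1.0 - u)
    r_new = r - release
    return r_new, u_new, release


def stp_on_presynaptic_spike(
    state: STPState,
    params: STPParams,
    presyn: np.ndarray,
    facilitation_first: bool = True,
) -> np.ndarray:
    """Apply the spike map to the columns of spiking presynaptic neurons.

    ``state`` arrays are (n_post, n_pre); ``presyn`` is an index array of
    spiking presynaptic neurons.  Returns the released fractions r*u as an
    (n_post, len(presyn)) array (to be multiplied by A upstream to give w).
    Mutates ``state`` in place.
    """
    cols = np.atleast_1d(presyn)
    r_new, u_new, release = stp_spike_update(
        state.r[:, cols], state.u[:, cols], params.U[:, cols], facilitation_first
    )
    state.r[:, cols] = r_new
    state.u[:, cols] = u_new
    return release


def stp_steady_state(
    params: STPParams, rate: float, facilitation_first: bool = True
) -> tuple:
    """Fixed point of the spike-to-spike map under periodic stimulation.

    Returns (r, u) evaluated at spike times such that r*u is the steady
    per-spike release: r just before the spike, u as used for the release
    (post-increment under the default convention).  rate = 0 returns the rest
    state (1, U).
    """
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    U = np.asarray(params.U, dtype=float)
    if rate == 0:
        return np.ones_like(U), U.copy()
    T = 1000.0 / rate  # inter-spike interval in ms
    a = np.exp(-T / np.asarray(params.tau_facil, dtype=float))
    b = np.exp(-T / np.asarray(params.tau_rec, dtype=float))
    # u just before a spike: u_pre' = U + a*(u_post - U), u_post = u_pre + U(1-u_pre)
    u_pre = U / (1.0 - a * (1.0 - U))
    u_post = u_pre + U * (1.0 - u_pre)
    u_rel = u_post if facilitation_first else u_pre
    # r just before a spike: r_pre' = 1 + b*(r_pre*(1-u_rel) - 1)
    r_pre = (1.0 - b) / (1.0 - b * (1.0 - u_rel))
    return r_pre, u_rel


def synapse_trace(
    params: STPParams,
    stim_rate: float,
    n_spikes: int,
    facilitation_first: bool = False,
) -> np.ndarray:
    """Per-spike release amplitudes r_k * u_k for a periodic spike train.

    The synapse starts from rest (r = 1, u = U) and is driven at
    ``stim_rate`` Hz for ``n_spikes`` spikes using the exact event-driven
    map.  The amplitude sequence classifies the synapse: initially rising =
    facilitating, monotonically decreasing = depressing.

    Traces default to the release-then-facilitate convention, which yields
    the canonical first-pulse amplitude U from rest (the paired-pulse ratio
    then directly reads facilitation); pass ``facilitation_first=True`` to
    match the network's default spike-update convention instead.
    """
    if n_spikes < 1:
        raise ValueError("n_spikes must be >= 1")
    if stim_rate <= 0:
        raise ValueError("stim_rate must be positive")
    U = float(np.asarray(params.U))
    tau_rec = float(np.asarray(params.tau_rec))
    tau_facil = float(np.asarray(params.tau_facil))
    T = 1000.0 / stim_rate
    a = np.exp(-T / tau_facil)
    b = np.exp(-T / tau_rec)
    r, u = 1.0, U
    amps = np.empty(n_spikes)
    for k in range(n_spikes):
        r, u, release = stp_spike_update(r, u, U, facilitation_first)
        amps[k] = release
        # relax until the next spike
        r = 1.0 + (r - 1.0) * b
        u = U + (u - U) * a
    return amps


def classify_trace(amplitudes: np.ndarray) -> str:
    """'facilitating' if amplitudes initially rise, 'depressing' otherwise."""
    amps = np.asarray(amplitudes, dtype=float)
    if amps.size < 2:
        return "depressing"
    return "facilitating" if amps[1] > amps[0] else "depressing"
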