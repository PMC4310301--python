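"""Sequential wave stimulus for the input neurons.

The N_in input neurons are driven one after another in a fixed cyclic order
with inter-neuron lag t_delay = 1/(nu_in * N_in), so each neuron receives
suprathreshold 2 mV pulses at nu_in = 10 Hz and the stimulus travels as a
wave around the input "ring".  Gaussian jitter with SD = 0.1 t_delay is
added to each pulse time; draws that would invert the firing order are
resampled so the wave ordering is always preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PULSE_AMPLITUDE", "StimulusProtocol", "build_protocol", "stimulus_pulse"]

PULSE_AMPLITUDE = 2.0  # mV, always suprathreshold (threshold is 1 mV)


@dataclass
class StimulusProtocol:
    """Event list (times in ms, global neuron ids) plus protocol constants."""

    n_in: int
    nu_in: float
    t_delay: float
    jitter_sd: float
    amplitude: float
    order: np.ndarray  # neuron ids in stimulation order
    times: np.ndarray  # event times (ms), strictly increasing
    neurons: np.ndarray  # event target neuron ids

    def events_in_step(self, t: float, dt: float) -> np.ndarray:
        """Neuron ids of events falling in [t, t + dt)."""
        lo = np.searchsorted(self.times, t, side="left")
        hi = np.searchsorted(self.times, t + dt, side="left")
        return self.neurons[lo:hi]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_ms": self.times, "neuron_id": self.neurons})


def build_protocol(
    n_in: int,
    nu_in: float = 10.0,
    horizon_ms: float = 1000.0,
    rng: np.random.Generator | None = None,
    jitter: bool = True,
    neuron_ids: np.ndarray | None = None,
    amplitude: float = PULSE_AMPLITUDE,
) -> StimulusProtocol:
    """Generate the jittered cyclic wave event list over ``horizon_ms``.

    ``neuron_ids`` maps the cyclic position to global neuron indices
    (defaults to 0..n_in-1).  With ``jitter=False`` the wave is exactly
    periodic and each neuron is stimulated at exactly nu_in Hz.
    """
    if n_in < 1:
        raise ValueError("n_in must be >= 1")
    if nu_in <= 0:
        raise ValueError("nu_in must be positive")
    if horizon_ms <= 0:
        raise ValueError("horizon_ms must be positive")
    if neuron_ids is None:
        neuron_ids = np.arange(n_in)
    neuron_ids = np.asarray(neuron_ids)
    if neuron_ids.shape != (n_in,):
        raise ValueError("neuron_ids must have length n_in")
    t_delay = 1000.0 / (nu_in * n_in)  # ms
    jitter_sd = 0.1 * t_delay
    n_events = int(np.floor(horizon_ms / t_delay))
    nominal = np.arange(n_events) * t_delay
    times = nominal.copy()
    if jitter and n_events:
        if rng is None:
            rng = np.random.default_rng()
        times = nominal + rng.normal(0.0, jitter_sd, n_events)
        # resample any draw that would invert the firing order
        for _ in range(1000):
            bad = np.flatnonzero(np.diff(times) <= 0)
            if bad.size == 0:
                break
            redo = np.unique(np.concatenate([bad, bad + 1]))
            times[redo] = nominal[redo] + rng.normal(0.0, jitter_sd, redo.size)
        else:  # pragma: no cover - SD = 0.1 t_delay makes this unreachable
            times = np.sort(times)
        times = np.clip(times, 0.0, None)
    targets = neuron_ids[np.arange(n_events) % n_in]
    return StimulusProtocol(
        n_in=n_in,
        nu_in=nu_in,
        t_delay=t_delay,
        jitter_sd=jitter_sd if jitter else 0.0,
        amplitude=amplitude,
        order=neuron_ids,
        times=times,
        neurons=targets,
    )


def stimulus_pulse(neurons, event_targets: np.ndarray, amplitude: float = PULSE_AMPLITUDE):
    """Add the pulse amplitude to the membrane of each targeted neuron.

    A pulse to a resting neuron guarantees a spike this step; a pulse to a
    refractory neuron is absorbed (the membrane stays clamped at 0).
    Mutates and returns ``neurons``.
    """
    if len(event_targets):
        np.add.at(neurons.v, event_targets, amplitude)
    return neurons
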