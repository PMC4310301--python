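"""Error-driven adaptation of short-term plasticity parameters.

Each population is assigned a target firing rate nu_targ and minimizes

    E = ((nu_targ - <nu>) / nu_lim)^2,

where <nu> is the population-mean EMA firing-rate estimate and nu_lim =
100 Hz is the refractory ceiling.  Gradient descent through a mean-field
surrogate of the network's rate (<nu> ~ A/tau_rec + I_ext and its U- and
tau_facil-analogues) yields per-spike updates applied by each spiking neuron
to its *incoming* synapses (target-specific plasticity):

    d tau_rec  = -2 eta (nu_targ - <nu>) A / (nu_lim^2 tau_rec^2)
    d U        = -2 eta (nu_targ - <nu>) A / (nu_lim^2 U^2)
    d tau_fac  = +2 eta (nu_targ - <nu>) A / nu_lim^2
    d A^STP    = +2 eta_A (nu_targ - <nu>) / (nu_lim^2 tau_rec)

with the shared, error-dependent learning rate
eta = eta_bar (1 + (nu_targ - <nu>)/nu_lim)^2 for the three STP parameters
and the fixed STDP rate eta_A = gamma for the strength update.  The physical
units of the per-spike increments are a modeling choice: rates are in Hz and
time constants in seconds inside the rules, with deltas converted back to ms,
giving per-spike tau_rec steps of order 1 ms (an `update_scale` factor is
exposed for recalibration; it does not touch the A rule, whose rate is the
fixed relation eta_A = gamma).

Which parameters actually move is selected by a named scheme; frozen
parameters receive exactly zero delta.  All parameters are clipped to their
hard bounds after every update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import NU_LIM
from . import tm
from .stdp import A_MIN, A_MAX

__all__ = [
    "SCHEMES",
    "RateState",
    "LearningConfig",
    "update_rate_estimate",
    "compute_error",
    "adaptive_learning_rate",
    "stp_learning_deltas",
    "stp_learning_on_spike",
    "total_weight_update",
]

#: learning scheme -> set of adapted parameters
SCHEMES: dict = {
    "U_taurec": frozenset({"U", "tau_rec"}),
    "U_taurec_A": frozenset({"U", "tau_rec", "A"}),
    "full": frozenset({"U", "tau_rec", "tau_facil", "A"}),
    "taurec_A": frozenset({"tau_rec", "A"}),
    "U_A": frozenset({"U", "A"}),
    "none": frozenset(),  # ablation: STP parameters frozen
}

TAU_NU = 1000.0  # ms, EMA time constant of the rate estimate (1 s)


@dataclass
class RateState:
    """EMA firing-rate estimates (Hz) per neuron.

    The estimate follows tau_nu * dnu/dt = -nu + nu_hat with a unit-area
    impulse per spike, so steady firing at f Hz converges to nu = f Hz.
    """

    nu: np.ndarray
    tau_nu: float = TAU_NU

    @classmethod
    def zeros(cls, n: int, tau_nu: float = TAU_NU) -> "RateState":
        return cls(nu=np.zeros(n), tau_nu=tau_nu)

    def decay_factor(self, dt: float) -> float:
        return float(np.exp(-dt / self.tau_nu))

    @property
    def impulse(self) -> float:
        """Rate increment per spike (Hz): 1 / tau_nu with tau_nu in seconds."""
        return 1000.0 / self.tau_nu

    def population_mean(self, idx: np.ndarray) -> float:
        return float(self.nu[idx].mean())


def update_rate_estimate(
    rates: RateState, spikes: np.ndarray, dt: float
) -> RateState:
    """One EMA step: exponential decay plus the per-spike impulse."""
    rates.nu *= rates.decay_factor(dt)
    rates.nu[spikes] += rates.impulse
    return rates


def compute_error(nu_targ: float, nu_mean: float) -> float:
    """Objective E = ((nu_targ - <nu>) / nu_lim)^2."""
    return ((nu_targ - nu_mean) / NU_LIM) ** 2


def adaptive_learning_rate(
    nu_targ: float, nu_mean: float, eta_bar: float = 0.1
) -> float:
    """Shared error-dependent rate for U, tau_rec, tau_facil."""
    return eta_bar * (1.0 + (nu_targ - nu_mean) / NU_LIM) ** 2


@dataclass
class LearningConfig:
    """Scheme selection and learning-rate constants."""

    scheme: str = "full"
    eta_bar: float = 0.1
    gamma: float = 2.0  # STDP rate; also eta_A for the STP-driven A update
    update_scale: float = 5.0
    facilitation_first: bool = True

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(
                f"unknown scheme {self.scheme!r}; valid: {sorted(SCHEMES)}"
            )

    @property
    def adapted(self) -> frozenset:
        return SCHEMES[self.scheme]


def stp_learning_deltas(
    U: np.ndarray,
    tau_rec: np.ndarray,
    A: np.ndarray,
    nu_targ: float,
    nu_mean: float,
    cfg: LearningConfig,
) -> dict:
    """Per-spike deltas for the incoming synapses of one spiking neuron.

    Inputs are the rows (incoming synapses) of the parameter matrices, with
    tau_rec in ms; returned time-constant deltas are in ms.  Parameters not
    in the active scheme get scalar 0.
    """
    err = nu_targ - nu_mean  # Hz
    eta = adaptive_learning_rate(nu_targ, nu_mean, cfg.eta_bar)
    scale = cfg.update_scale
    adapted = cfg.adapted
    nl2 = NU_LIM**2
    tau_rec_s = tau_rec / 1000.0
    out: dict = {"tau_rec": 0.0, "U": 0.0, "tau_facil": 0.0, "A": 0.0}
    if "tau_rec" in adapted:
        out["tau_rec"] = -2.0 * eta * err * A / (nl2 * tau_rec_s**2) * 1000.0 * scale
    if "U" in adapted:
        out["U"] = -2.0 * eta * err * A / (nl2 * U**2) * scale
    if "tau_facil" in adapted:
        out["tau_facil"] = 2.0 * eta * err * A / nl2 * 1000.0 * scale
    if "A" in adapted:
        # eta_A == gamma is a fixed relation; the unit calibration factor
        # applies only to the dimensionful STP-parameter updates
        out["A"] = 2.0 * cfg.gamma * err / (nl2 * tau_rec_s)
    return out


def stp_learning_on_spike(
    params: tm.STPParams,
    A: np.ndarray,
    i: int,
    nu_targ: float,
    nu_mean: float,
    cfg: LearningConfig,
    mask_row: np.ndarray | None = None,
) -> np.ndarray:
    """Apply the STP-parameter updates for a spike of neuron i, in place.

    Only the incoming row i of U, tau_rec, tau_facil is touched
    (target-specific mechanism); parameters are clipped to their bounds.
    Returns dA^STP for row i (not yet applied: it must be summed with the
    STDP delta before a single clip, see :func:`total_weight_update`).
    """
    d = stp_learning_deltas(
        params.U[i], params.tau_rec[i], A[i], nu_targ, nu_mean, cfg
    )
    if "tau_rec" in cfg.adapted:
        np.clip(
            params.tau_rec[i] + d["tau_rec"],
            tm.TAU_REC_MIN,
            tm.TAU_REC_MAX,
            out=params.tau_rec[i],
        )
    if "U" in cfg.adapted:
        np.clip(params.U[i] + d["U"], tm.U_MIN, tm.U_MAX, out=params.U[i])
    if "tau_facil" in cfg.adapted:
        np.clip(
            params.tau_facil[i] + d["tau_facil"],
            tm.TAU_FACIL_MIN,
            tm.TAU_FACIL_MAX,
            out=params.tau_facil[i],
        )
    dA = d["A"]
    if mask_row is not None and np.ndim(dA):
        dA = dA * mask_row
    return np.broadcast_to(np.asarray(dA, dtype=float), A[i].shape)


def total_weight_update(
    A: np.ndarray,
    dA_stdp: np.ndarray,
    dA_stp: np.ndarray,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """A += dA^STDP + dA^STP, then a single clip to [A_MIN, A_MAX].

    Mutates and returns ``A``; masked (absent) synapses remain 0.
    """
    A += dA_stdp + dA_stp
    np.clip(A, A_MIN, A_MAX, out=A)
    if mask is not None:
        A *= mask
    return A
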