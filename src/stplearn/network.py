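"""Network architectures and the orchestrating simulation loop.

Two canonical architectures are provided:

* ``single_population``: N = 40 all-to-all neurons split into an input
  region (30 neurons, driven by the sequential wave) and an output region
  (10 neurons) whose target rate alternates low/high across phases.
* ``double_population``: two mirrored 40-neuron branches (N = 80).  Cross
  connections input1<->output2 and output1<->input2 are absent; lateral
  input-input and output-output connections start weak (A in [1e-3, 0.1]).
  Branch 1 is assigned the 30 Hz target, branch 2 the 5 Hz target.

The per-step order of :func:`run_simulation` is: stimulus pulses ->
conductance/STP/trace/rate decay -> membrane Euler step (refractory clamp)
-> threshold crossing -> STP release and conductance injection -> rate
impulse -> STDP + error-driven STP learning per spiking neuron -> trace
increments -> recording.  Spikes injected at step t therefore influence
other membranes from step t+1 on (one-step transmission delay implied by the
discretization).  Simultaneous spikes are processed sequentially in
neuron-index order; all trace reads use the post-decay, pre-increment values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import core, tm
from .core import SimClock, SimulationDiverged
from .learning import LearningConfig, RateState, adaptive_learning_rate, SCHEMES
from .stdp import (
    A_MIN,
    A_MAX,
    TAU_M1,
    TAU_M2,
    TAU_O1,
    TAU_O2,
    STDPConstants,
    TripletTraces,
)
from .stimulus import build_protocol
from .analysis import symmetry_index

#: pooled synaptic coupling: the conductance injected per unit of released
#: efficacy r*u*A is COUPLING_POOL / N (1/N synaptic scaling, so the mean
#: recurrent drive is invariant to network size).  The printed model
#: constants leave the unit of w open; this default places the drive in the
#: graded regime where firing rates respond smoothly to the STP variables
#: and maximum strengths (see docs/methods.md).
COUPLING_POOL = 0.32

__all__ = [
    "COUPLING_POOL",
    "NetworkSpec",
    "Phase",
    "SimState",
    "RunResult",
    "single_population",
    "double_population",
    "single_phase_schedule",
    "double_phase_schedule",
    "build_network",
    "run_simulation",
]


@dataclass
class NetworkSpec:
    """Static architecture: sizes, populations, connectivity and init ranges."""

    n: int
    populations: dict
    mask: np.ndarray  # bool (n, n): allowed synapses, False on diagonal
    init_A_upper: np.ndarray  # (n, n) upper bound of the uniform A init
    input_ids: np.ndarray  # global ids in wave-stimulation order
    out_pops: list
    record_groups: list  # (label, source idx, target idx) summaries

    def __post_init__(self) -> None:
        cover = np.zeros(self.n, dtype=int)
        for idx in self.populations.values():
            cover[idx] += 1
        if not np.all(cover == 1):
            raise ValueError("populations must partition the neurons exactly")
        if np.any(np.diag(self.mask)):
            raise ValueError("connection mask must exclude the diagonal")


def single_population(n_in: int = 30, n_out: int = 10) -> NetworkSpec:
    """All-to-all single-branch network (input region + output region)."""
    n = n_in + n_out
    pin = np.arange(n_in)
    pout = np.arange(n_in, n)
    mask = ~np.eye(n, dtype=bool)
    return NetworkSpec(
        n=n,
        populations={"in": pin, "out": pout},
        mask=mask,
        init_A_upper=np.full((n, n), A_MAX),
        input_ids=pin,
        out_pops=["out"],
        record_groups=[("onto_out", np.arange(n), pout)],
    )


def double_population(n_in: int = 30, n_out: int = 10) -> NetworkSpec:
    """Two mirrored branches with weak lateral and no cross connections."""
    nb = n_in + n_out
    n = 2 * nb
    in1 = np.arange(n_in)
    out1 = np.arange(n_in, nb)
    in2 = nb + np.arange(n_in)
    out2 = nb + np.arange(n_in, nb)
    mask = np.zeros((n, n), dtype=bool)
    upper = np.zeros((n, n))

    def allow(tgt, src, a_up):
        mask[np.ix_(tgt, src)] = True
        upper[np.ix_(tgt, src)] = a_up

    for grp in (in1, out1, in2, out2):
        allow(grp, grp, A_MAX)  # within population
    allow(out1, in1, A_MAX)  # within branch 1
    allow(in1, out1, A_MAX)
    allow(out2, in2, A_MAX)  # within branch 2
    allow(in2, out2, A_MAX)
    allow(in1, in2, 0.1)  # weak lateral input-input
    allow(in2, in1, 0.1)
    allow(out1, out2, 0.1)  # weak lateral output-output
    allow(out2, out1, 0.1)
    np.fill_diagonal(mask, False)
    outs = np.concatenate([out1, out2])
    return NetworkSpec(
        n=n,
        populations={"in1": in1, "out1": out1, "in2": in2, "out2": out2},
        mask=mask,
        init_A_upper=upper,
        input_ids=np.concatenate([in1, in2]),
        out_pops=["out1", "out2"],
        record_groups=[("onto_out1", outs, out1), ("onto_out2", outs, out2)],
    )


@dataclass
class Phase:
    """One task phase: duration, per-population target rates, STDP gamma."""

    duration_s: float
    targets: dict  # population name -> target rate (Hz)
    gamma: float | None = None  # None -> LearningConfig.gamma

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise ValueError("phase duration must be non-negative")


def single_phase_schedule(
    t_ph_s: float = 500.0,
    low: float = 5.0,
    high: float = 30.0,
    gamma_low: float = 2.0,
    gamma_high: float = 1.0,
    sequence: str = "low-high-low-high",
) -> list:
    """Alternating-target schedule for the single-population task."""
    phases = []
    for name in sequence.split("-"):
        if name == "low":
            phases.append(Phase(t_ph_s, {"in": low, "out": low}, gamma_low))
        elif name == "high":
            phases.append(Phase(t_ph_s, {"in": high, "out": high}, gamma_high))
        else:
            raise ValueError(f"unknown phase {name!r}")
    return phases


def double_phase_schedule(
    duration_s: float = 500.0,
    high: float = 30.0,
    low: float = 5.0,
    gamma: float = 2.0,
) -> list:
    """Single fixed phase: branch 1 -> high target, branch 2 -> low target."""
    targets = {"in1": high, "out1": high, "in2": low, "out2": low}
    return [Phase(duration_s, targets, gamma)]


@dataclass
class SimState:
    """All dynamic arrays of one simulation, plus the RNG streams."""

    spec: NetworkSpec
    neurons: core.NeuronState
    cond: core.ConductanceState
    stp: tm.STPState
    stp_params: tm.STPParams
    traces: TripletTraces
    A: np.ndarray
    rates: RateState
    clock: SimClock
    jitter_rng: np.random.Generator
    seed: int | None = None


def build_network(
    spec: NetworkSpec, seed: int | None = None, dt: float = 1.0
) -> SimState:
    """Allocate and randomly initialize the full simulation state.

    Separate RNG streams (parameter init, stimulus jitter) are spawned from
    the master seed so ablations do not shift unrelated draws.  The same
    seed reproduces the initial state bit for bit.
    """
    ss = np.random.SeedSequence(seed)
    init_ss, jitter_ss = ss.spawn(2)
    init_rng = np.random.default_rng(init_ss)
    jitter_rng = np.random.default_rng(jitter_ss)
    n = spec.n
    params = tm.STPParams.from_uniform((n, n), init_rng)
    maskf = spec.mask.astype(float)
    span = np.clip(spec.init_A_upper - A_MIN, 0.0, None)
    A = (A_MIN + init_rng.uniform(size=(n, n)) * span) * maskf
    stp = tm.STPState.at_rest(params)
    return SimState(
        spec=spec,
        neurons=core.NeuronState.zeros(n),
        cond=core.ConductanceState.zeros(n),
        stp=stp,
        stp_params=params,
        traces=TripletTraces.zeros(n),
        A=A,
        rates=RateState.zeros(n),
        clock=SimClock(dt=dt),
        jitter_rng=jitter_rng,
        seed=seed,
    )


@dataclass
class RunResult:
    """Recorded time series, phase-boundary snapshots and the final state."""

    times_s: np.ndarray
    rates: pd.DataFrame  # population-mean EMA rate per recorded second
    symmetry: pd.DataFrame  # s of each output population's weight submatrix
    params: pd.DataFrame  # projection-group means of tau_rec / tau_facil / U
    snapshots: list  # dict per phase end: t_s, U, tau_rec, tau_facil, A
    state: SimState
    raster: pd.DataFrame | None = None

    def phase_end_symmetry(self, pop: str = "out") -> list:
        """Symmetry index of ``pop``'s weight submatrix at each phase end."""
        idx = self.state.spec.populations[pop]
        return [
            symmetry_index(snap["A"][np.ix_(idx, idx)]).s for snap in self.snapshots
        ]


def run_simulation(
    state: SimState,
    phases: list,
    cfg: LearningConfig,
    stdp: STDPConstants | None = None,
    record_every_s: float = 1.0,
    record_raster: bool = False,
    nu_in: float = 10.0,
    coupling: float | None = None,
) -> RunResult:
    """Run the learning network through the phase schedule.

    Returns a :class:`RunResult`; ``state`` is advanced in place.  An empty
    or zero-duration schedule returns the initial state unchanged (with a
    single snapshot).  Non-finite membrane potentials abort with a step
    diagnostic.
    """
    if stdp is None:
        stdp = STDPConstants(gamma=cfg.gamma)
    spec = state.spec
    n = spec.n
    if coupling is None:
        coupling = COUPLING_POOL / n
    dt = state.clock.dt
    adapted = cfg.adapted
    learn_tau_rec = "tau_rec" in adapted
    learn_U = "U" in adapted
    learn_tau_facil = "tau_facil" in adapted
    learn_A = "A" in adapted

    # local aliases (hot loop)
    v = state.neurons.v
    refr_until = state.neurons.refractory_until
    g = state.cond.g
    r, u = state.stp.r, state.stp.u
    U, tau_rec, tau_facil = (
        state.stp_params.U,
        state.stp_params.tau_rec,
        state.stp_params.tau_facil,
    )
    A = state.A
    m1, m2 = state.traces.m1, state.traces.m2
    o1, o2 = state.traces.o1, state.traces.o2
    nu = state.rates.nu
    maskf = spec.mask.astype(float)

    inv_tau_rec = 1.0 / tau_rec
    inv_tau_facil = 1.0 / tau_facil
    g_decay = state.cond.decay_factor(dt)
    d_m1, d_m2 = np.exp(-dt / TAU_M1), np.exp(-dt / TAU_M2)
    d_o1, d_o2 = np.exp(-dt / TAU_O1), np.exp(-dt / TAU_O2)
    nu_decay = state.rates.decay_factor(dt)
    nu_imp = state.rates.impulse
    g_leak, e_rev = state.cond.g_leak, state.cond.e_rev
    nl2 = core.NU_LIM**2
    scale = cfg.update_scale
    t_ref = core.T_REF
    v_thr = core.V_THR

    pop_names = list(spec.populations)
    pop_idx = [spec.populations[p] for p in pop_names]
    pop_of = np.empty(n, dtype=int)
    for k, idx in enumerate(pop_idx):
        pop_of[idx] = k

    total_ms = sum(ph.duration_s for ph in phases) * 1000.0
    protocol = None
    if total_ms > 0:
        protocol = build_protocol(
            n_in=len(spec.input_ids),
            nu_in=nu_in,
            horizon_ms=total_ms,
            rng=state.jitter_rng,
            neuron_ids=spec.input_ids,
        )
        # the wave continues from the current clock time (resumed runs)
        ev_times = protocol.times + state.clock.t
        ev_neurons = protocol.neurons
    ev_ptr = 0

    rec_steps = max(int(round(record_every_s * 1000.0 / dt)), 1)
    rec_t: list = []
    rec_rates: dict = {p: [] for p in pop_names}
    rec_sym: dict = {p: [] for p in spec.out_pops}
    rec_params: dict = {}
    for label, _, _ in spec.record_groups:
        for pname in ("tau_rec", "tau_facil", "U"):
            rec_params[f"{label}:{pname}"] = []
    group_masks = [
        spec.mask[np.ix_(tgt, src)] for _, src, tgt in spec.record_groups
    ]
    out_idx = {p: spec.populations[p] for p in spec.out_pops}
    raster_t: list = []
    raster_n: list = []
    snapshots: list = []

    param_mats = {"tau_rec": tau_rec, "tau_facil": tau_facil, "U": U}

    def record_row() -> None:
        rec_t.append(state.clock.t / 1000.0)
        for p, idx in zip(pop_names, pop_idx):
            rec_rates[p].append(nu[idx].mean())
        for p, idx in out_idx.items():
            rec_sym[p].append(symmetry_index(A[np.ix_(idx, idx)]).s)
        for (label, src, tgt), gm in zip(spec.record_groups, group_masks):
            for pname, mat in param_mats.items():
                rec_params[f"{label}:{pname}"].append(
                    mat[np.ix_(tgt, src)][gm].mean()
                )

    def snapshot() -> None:
        snapshots.append(
            {
                "t_s": state.clock.t / 1000.0,
                "U": U.copy(),
                "tau_rec": tau_rec.copy(),
                "tau_facil": tau_facil.copy(),
                "A": A.copy(),
            }
        )

    step_counter = 0
    for phase in phases:
        gamma = cfg.gamma if phase.gamma is None else phase.gamma
        a2p, a3p = stdp.a2_plus, stdp.a3_plus
        a2m, a3m = stdp.a2_minus, stdp.a3_minus
        targ_of = np.array([phase.targets[p] for p in pop_names])
        eta_A = gamma  # learning rate of the STP-driven A update
        n_steps = int(round(phase.duration_s * 1000.0 / dt))
        for _ in range(n_steps):
            t = state.clock.t
            # stimulus pulses due in [t, t+dt)
            if protocol is not None:
                hi = ev_ptr
                n_ev = ev_times.shape[0]
                while hi < n_ev and ev_times[hi] < t + dt:
                    hi += 1
                if hi > ev_ptr:
                    np.add.at(v, ev_neurons[ev_ptr:hi], protocol.amplitude)
                    ev_ptr = hi
            # decays
            g *= g_decay
            r += (1.0 - r) * inv_tau_rec * dt
            u += (U - u) * inv_tau_facil * dt
            m1 *= d_m1
            m2 *= d_m2
            o1 *= d_o1
            o2 *= d_o2
            nu *= nu_decay
            # membrane (explicit Euler), refractory clamp
            gsum = g.sum(axis=1)
            v += dt * (-g_leak * v + gsum * (e_rev - v))
            v[t < refr_until] = 0.0
            sp_mask = v >= v_thr
            if sp_mask.any():
                sp = np.flatnonzero(sp_mask)
                v[sp] = 0.0
                refr_until[sp] = t + t_ref
                # STP release and conductance injection (pre-update A)
                Uc = U[:, sp]
                uc = u[:, sp]
                if cfg.facilitation_first:
                    uc = uc + Uc * (1.0 - uc)
                    rel = r[:, sp] * uc
                else:
                    rel = r[:, sp] * uc
                    uc = uc + Uc * (1.0 - uc)
                u[:, sp] = uc
                r[:, sp] -= rel
                g[:, sp] += coupling * rel * A[:, sp]
                # rate estimate updated by the spikes, then the error signal
                nu[sp] += nu_imp
                pop_means = np.array([nu[idx].mean() for idx in pop_idx])
                for i in sp:
                    k = pop_of[i]
                    err = targ_of[k] - pop_means[k]
                    # triplet STDP, epsilon convention: slow traces pre-increment
                    d_in = gamma * m1 * (a2p + a3p * o2[i])
                    d_out = -gamma * o1 * (a2m + a3m * m2[i])
                    A_row = A[i]
                    if learn_A:
                        d_in = d_in + 2.0 * eta_A * err / (nl2 * (tau_rec[i] / 1000.0))
                    # error-driven STP updates on incoming synapses
                    if learn_tau_rec or learn_U or learn_tau_facil:
                        eta = adaptive_learning_rate(
                            targ_of[k], pop_means[k], cfg.eta_bar
                        )
                        fac = 2.0 * eta * err * A_row / nl2 * scale
                        if learn_tau_rec:
                            np.clip(
                                tau_rec[i] - fac / (tau_rec[i] / 1000.0) ** 2 * 1000.0,
                                tm.TAU_REC_MIN,
                                tm.TAU_REC_MAX,
                                out=tau_rec[i],
                            )
                            inv_tau_rec[i] = 1.0 / tau_rec[i]
                        if learn_U:
                            np.clip(
                                U[i] - fac / U[i] ** 2, tm.U_MIN, tm.U_MAX, out=U[i]
                            )
                        if learn_tau_facil:
                            np.clip(
                                tau_facil[i] + fac * 1000.0,
                                tm.TAU_FACIL_MIN,
                                tm.TAU_FACIL_MAX,
                                out=tau_facil[i],
                            )
                            inv_tau_facil[i] = 1.0 / tau_facil[i]
                    # total weight update, single clip (STDP + STP deltas)
                    A_row += d_in
                    np.clip(A_row, A_MIN, A_MAX, out=A_row)
                    A_row *= maskf[i]
                    A_col = A[:, i]
                    A_col += d_out
                    np.clip(A_col, A_MIN, A_MAX, out=A_col)
                    A_col *= maskf[:, i]
                m1[sp] += 1.0
                m2[sp] += 1.0
                o1[sp] += 1.0
                o2[sp] += 1.0
                if record_raster:
                    raster_t.append(np.full(sp.size, t))
                    raster_n.append(sp)
            state.clock.advance()
            step_counter += 1
            if step_counter % rec_steps == 0:
                record_row()
            if step_counter % 10000 == 0 and not np.all(np.isfinite(v)):
                snapshot()
                raise SimulationDiverged(
                    f"membrane diverged near t={state.clock.t} ms"
                )
        snapshot()
    if not snapshots:
        snapshot()

    raster = None
    if record_raster:
        raster = pd.DataFrame(
            {
                "time_ms": np.concatenate(raster_t) if raster_t else np.array([]),
                "neuron_id": np.concatenate(raster_n).astype(int)
                if raster_n
                else np.array([], dtype=int),
            }
        )
    times = np.asarray(rec_t)
    return RunResult(
        times_s=times,
        rates=pd.DataFrame(rec_rates, index=times),
        symmetry=pd.DataFrame(rec_sym, index=times),
        params=pd.DataFrame(rec_params, index=times),
        snapshots=snapshots,
        state=state,
        raster=raster,
    )
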