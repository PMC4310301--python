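"""Tsodyks-Markram synapse dynamics, steady states and trace classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stplearn.core import SimClock
from stplearn import tm
from stplearn.tm import (
    STPParams,
    STPState,
    classify_trace,
    stp_decay_step,
    stp_on_presynaptic_spike,
    stp_spike_update,
    stp_steady_state,
    synapse_trace,
)


def iterate_spike_map(U, tau_rec, tau_facil, rate, n_spikes, facilitation_first=True):
    """Independent oracle: iterate the event-driven map spike by spike."""
    T = 1000.0 / rate
    a, b = np.exp(-T / tau_facil), np.exp(-T / tau_rec)
    r, u = 1.0, U
    for _ in range(n_spikes):
        r, u, release = stp_spike_update(r, u, U, facilitation_first)
        r_pre_next = 1.0 + (r - 1.0) * b
        u_pre_next = U + (u - U) * a
        r, u = r_pre_next, u_pre_next
    return r, u, release


class TestDecay:
    def test_rest_state_is_fixed_point(self):
        params = STPParams.scalar(0.3, 200.0, 50.0)
        params = STPParams(
            U=np.full((2, 2), 0.3), tau_rec=np.full((2, 2), 200.0),
            tau_facil=np.full((2, 2), 50.0),
        )
        state = STPState.at_rest(params)
        stp_decay_step(state, params, SimClock(dt=1.0))
        assert np.all(state.r == 1.0)
        assert np.all(state.u == 0.3)

    def test_recovery_efold(self):
        # r = 0 with tau_rec = 100 ms: after 100 ms, r ~ 1 - 1/e
        params = STPParams(
            U=np.array([0.5]), tau_rec=np.array([100.0]), tau_facil=np.array([100.0])
        )
        state = STPState(r=np.array([0.0]), u=np.array([0.5]))
        clock = SimClock(dt=1.0)
        for _ in range(100):
            stp_decay_step(state, params, clock)
        # Euler at dt=1 vs exact e-fold: agree to O(dt/tau)
        assert state.r[0] == pytest.approx(1.0 - 1.0 / np.e, abs=5e-3)

    def test_infinite_facilitation_limit(self):
        params = STPParams(
            U=np.array([0.05]), tau_rec=np.array([100.0]), tau_facil=np.array([1e12])
        )
        state = STPState(r=np.array([1.0]), u=np.array([1.0]))
        clock = SimClock(dt=1.0)
        for _ in range(1000):
            stp_decay_step(state, params, clock)
        assert state.u[0] == pytest.approx(1.0, abs=1e-6)


class TestSpikeMap:
    def test_first_spike_facilitation_then_release(self):
        # from rest with U=0.5: u -> 0.75, release = 1 * 0.75, r -> 0.25
        r, u, release = stp_spike_update(1.0, 0.5, 0.5, facilitation_first=True)
        assert u == pytest.approx(0.75)
        assert release == pytest.approx(0.75)
        assert r == pytest.approx(0.25)

    def test_first_spike_release_then_facilitation(self):
        # release convention: amplitude from rest equals U
        r, u, release = stp_spike_update(1.0, 0.5, 0.5, facilitation_first=False)
        assert release == pytest.approx(0.5)
        assert r == pytest.approx(0.5)
        assert u == pytest.approx(0.75)

    def test_saturated_facilitation_is_pure_depression(self):
        # U=1 pins u at 1: the release sequence decays geometrically
        r, u = 1.0, 1.0
        releases = []
        for _ in range(4):
            r, u, rel = stp_spike_update(r, u, 1.0)
            releases.append(rel)
        assert u == 1.0
        assert releases == pytest.approx([1.0, 0.0, 0.0, 0.0])

    def test_depleted_resources_release_nothing(self):
        _, _, release = stp_spike_update(0.0, 0.9, 0.5)
        assert release == 0.0

    def test_column_update_on_matrix_state(self):
        params = STPParams(
            U=np.full((3, 3), 0.5),
            tau_rec=np.full((3, 3), 200.0),
            tau_facil=np.full((3, 3), 50.0),
        )
        state = STPState.at_rest(params)
        release = stp_on_presynaptic_spike(state, params, np.array([1]))
        assert release.shape == (3, 1)
        assert np.all(state.r[:, 1] == pytest.approx(0.25))
        assert np.all(state.r[:, [0, 2]] == 1.0)


class TestSteadyState:
    def test_rest_at_zero_rate(self):
        params = STPParams.scalar(0.4, 300.0, 60.0)
        r, u = stp_steady_state(params, 0.0)
        assert r == 1.0 and u == 0.4

    def test_full_depletion_at_high_rate(self):
        params = STPParams.scalar(0.4, 300.0, 60.0)
        r, u = stp_steady_state(params, 1e6)
        assert r == pytest.approx(0.0, abs=1e-3)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            stp_steady_state(STPParams.scalar(0.4, 300.0, 60.0), -1.0)

    @pytest.mark.parametrize("facilitation_first", [True, False])
    @pytest.mark.parametrize(
        "U,tau_rec,tau_facil,rate",
        [(0.1, 150.0, 700.0, 12.0), (0.7, 800.0, 30.0, 5.0), (0.5, 400.0, 400.0, 30.0)],
    )
    def test_matches_long_run_map_iteration(
        self, U, tau_rec, tau_facil, rate, facilitation_first
    ):
        # closed-form fixed point vs 10^4 iterations of the spike map
        params = STPParams.scalar(U, tau_rec, tau_facil)
        r_ss, u_ss = stp_steady_state(params, rate, facilitation_first)
        r_it, u_it, release_it = iterate_spike_map(
            U, tau_rec, tau_facil, rate, 10000, facilitation_first
        )
        assert r_ss * u_ss == pytest.approx(release_it, abs=1e-6)

    def test_steady_release_monotone_in_tau_rec(self):
        # deeper depression (larger tau_rec) never increases steady release
        for U in (0.1, 0.5, 0.9):
            rels = []
            for tr in np.linspace(100.0, 900.0, 9):
                params = STPParams.scalar(U, tr, 200.0)
                r, u = stp_steady_state(params, 10.0)
                rels.append(r * u)
            assert np.all(np.diff(rels) <= 1e-12)


class TestTraces:
    def test_depressing_regime_monotone_decreasing(self):
        # high tau_rec, high U (depressed-phase means) at 5 Hz
        params = STPParams.scalar(0.85, 800.0, 50.0)
        amps = synapse_trace(params, 5.0, 8)
        assert np.all(np.diff(amps) < 0)
        assert classify_trace(amps) == "depressing"

    def test_facilitating_regime_initially_rising(self):
        # low tau_rec, low U, high tau_facil (facilitated-phase means) at 12 Hz
        params = STPParams.scalar(0.1, 150.0, 750.0)
        amps = synapse_trace(params, 12.0, 8)
        assert amps[1] > amps[0]
        assert classify_trace(amps) == "facilitating"

    def test_single_spike_amplitude_is_U_under_release_convention(self):
        params = STPParams.scalar(0.37, 300.0, 200.0)
        amps = synapse_trace(params, 10.0, 1, facilitation_first=False)
        assert amps[0] == pytest.approx(0.37)

    def test_trace_matches_map_oracle(self):
        params = STPParams.scalar(0.2, 300.0, 500.0)
        amps = synapse_trace(params, 10.0, 50)
        _, _, last_release = iterate_spike_map(
            0.2, 300.0, 500.0, 10.0, 50, facilitation_first=False
        )
        assert amps[-1] == pytest.approx(last_release, rel=1e-12)

    def test_event_driven_matches_dt_discretized(self):
        # the exact map and the Euler dt-simulation agree to O(dt)
        U, tau_rec, tau_facil, rate = 0.3, 250.0, 400.0, 10.0
        params = STPParams(
            U=np.full((1, 1), U),
            tau_rec=np.full((1, 1), tau_rec),
            tau_facil=np.full((1, 1), tau_facil),
        )
        state = STPState.at_rest(params)
        clock = SimClock(dt=1.0)
        interval = int(1000 / rate)
        releases = []
        for step in range(interval * 20):
            stp_decay_step(state, params, clock)
            if step % interval == interval - 1:
                releases.append(
                    stp_on_presynaptic_spike(state, params, np.array([0]))[0, 0]
                )
            clock.advance()
        amps = synapse_trace(
            STPParams.scalar(U, tau_rec, tau_facil), rate, 20, facilitation_first=True
        )
        np.testing.assert_allclose(releases, amps, atol=0.02)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    U=st.floats(0.05, 0.95),
    tau_rec=st.floats(100.0, 900.0),
    tau_facil=st.floats(1.0, 900.0),
    isis=st.lists(st.floats(1.0, 500.0), min_size=1, max_size=40),
    facilitation_first=st.booleans(),
)
def test_r_u_bounded_for_any_spike_train(U, tau_rec, tau_facil, isis, facilitation_first):
    """r and u stay in [0, 1] along arbitrary spike trains."""
    r, u = 1.0, U
    for isi in isis:
        r, u, release = stp_spike_update(r, u, U, facilitation_first)
        assert -1e-12 <= r <= 1 + 1e-12
        assert -1e-12 <= u <= 1 + 1e-12
        assert release >= -1e-12
        b = np.exp(-isi / tau_rec)
        a = np.exp(-isi / tau_facil)
        r = 1.0 + (r - 1.0) * b
        u = U + (u - U) * a
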