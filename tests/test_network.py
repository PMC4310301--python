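"""Architecture builders and the closed-loop simulation contract."""

import numpy as np
import pytest

from stplearn import core
from stplearn.learning import LearningConfig
from stplearn.network import (
    Phase,
    build_network,
    double_population,
    run_simulation,
    single_phase_schedule,
    single_population,
    NetworkSpec,
)
from stplearn.stdp import STDPConstants


class TestSpecs:
    def test_single_population_layout(self):
        spec = single_population()
        assert spec.n == 40
        assert len(spec.populations["in"]) == 30
        assert len(spec.populations["out"]) == 10
        assert spec.mask.sum() == 40 * 39  # all-to-all without diagonal

    def test_double_population_layout(self):
        spec = double_population()
        assert spec.n == 80
        in1, out1 = spec.populations["in1"], spec.populations["out1"]
        in2, out2 = spec.populations["in2"], spec.populations["out2"]
        # cross connections absent in both directions
        assert not spec.mask[np.ix_(out2, in1)].any()
        assert not spec.mask[np.ix_(in1, out2)].any()
        assert not spec.mask[np.ix_(in2, out1)].any()
        assert not spec.mask[np.ix_(out1, in2)].any()
        # lateral output-output present but initialized weak
        assert spec.mask[np.ix_(out1, out2)].all()
        assert np.all(spec.init_A_upper[np.ix_(out1, out2)] == 0.1)
        assert np.all(spec.init_A_upper[np.ix_(in2, in1)] == 0.1)

    def test_bad_partition_rejected(self):
        spec = single_population()
        pops = {"in": np.arange(30), "out": np.arange(29, 40)}  # overlap
        with pytest.raises(ValueError, match="partition"):
            NetworkSpec(
                n=40,
                populations=pops,
                mask=spec.mask,
                init_A_upper=spec.init_A_upper,
                input_ids=np.arange(30),
                out_pops=["out"],
                record_groups=[],
            )


class TestBuild:
    def test_same_seed_is_bit_identical(self):
        a = build_network(single_population(), seed=7)
        b = build_network(single_population(), seed=7)
        np.testing.assert_array_equal(a.A, b.A)
        np.testing.assert_array_equal(a.stp_params.tau_rec, b.stp_params.tau_rec)
        np.testing.assert_array_equal(a.stp.u, b.stp.u)

    def test_initial_state_contract(self):
        state = build_network(double_population(), seed=3)
        spec = state.spec
        assert np.all(state.stp.r == 1.0)
        np.testing.assert_array_equal(state.stp.u, state.stp_params.U)
        assert np.all(state.A[~spec.mask] == 0.0)
        out1, out2 = spec.populations["out1"], spec.populations["out2"]
        assert state.A[np.ix_(out1, out2)].max() <= 0.1
        state.stp_params.validate()


class TestRun:
    def short_cfg(self):
        return LearningConfig(scheme="U_taurec_A", gamma=2.0)

    def test_zero_duration_returns_initial_state(self):
        state = build_network(single_population(), seed=1)
        A0 = state.A.copy()
        res = run_simulation(state, [Phase(0.0, {"in": 5.0, "out": 5.0})], self.short_cfg())
        np.testing.assert_array_equal(state.A, A0)
        assert len(res.snapshots) == 1

    def test_end_to_end_determinism(self):
        results = []
        for _ in range(2):
            state = build_network(single_population(), seed=11)
            res = run_simulation(
                state,
                [Phase(5.0, {"in": 5.0, "out": 5.0}, 2.0)],
                self.short_cfg(),
                record_raster=True,
            )
            results.append(res)
        a, b = results
        np.testing.assert_array_equal(a.rates.values, b.rates.values)
        np.testing.assert_array_equal(a.raster.values, b.raster.values)
        np.testing.assert_array_equal(a.state.A, b.state.A)

    def test_invariants_on_short_run(self):
        state = build_network(single_population(), seed=5)
        res = run_simulation(
            state,
            [Phase(10.0, {"in": 30.0, "out": 30.0}, 1.0)],
            self.short_cfg(),
            record_raster=True,
        )
        # refractory correctness: no ISI below 10 ms anywhere in the raster
        ras = res.raster
        for nid, grp in ras.groupby("neuron_id"):
            ts = grp.time_ms.values
            if len(ts) > 1:
                assert np.min(np.diff(ts)) >= core.T_REF
        # EMA rates below the refractory ceiling
        assert res.rates.values.max() <= core.NU_LIM * 1.01
        # bounds on all learned quantities
        state.stp_params.validate()
        off = state.spec.mask
        assert state.A[off].min() >= 1e-3 - 1e-12
        assert state.A[off].max() <= 1.0 + 1e-12
        assert state.stp.r.min() >= -1e-9 and state.stp.r.max() <= 1 + 1e-9
        assert state.stp.u.min() >= -1e-9 and state.stp.u.max() <= 1 + 1e-9

    def test_input_rate_floor(self):
        state = build_network(single_population(), seed=2)
        res = run_simulation(
            state,
            [Phase(10.0, {"in": 5.0, "out": 5.0}, 2.0)],
            self.short_cfg(),
            record_raster=True,
        )
        ras = res.raster
        in_ids = set(state.spec.populations["in"])
        counts = ras[ras.neuron_id.isin(in_ids)].groupby("neuron_id").size()
        # the wave guarantees each input neuron fires at >= nu_in = 10 Hz
        assert counts.min() / 10.0 >= 10.0 * 0.95

    def test_all_plasticity_disabled_freezes_weights(self):
        state = build_network(single_population(), seed=4)
        A0 = state.A.copy()
        tr0 = state.stp_params.tau_rec.copy()
        cfg = LearningConfig(scheme="none", gamma=0.0)
        run_simulation(
            state,
            [Phase(5.0, {"in": 5.0, "out": 5.0}, 0.0)],
            cfg,
            stdp=STDPConstants(gamma=0.0),
        )
        np.testing.assert_array_equal(state.A, A0)
        np.testing.assert_array_equal(state.stp_params.tau_rec, tr0)

    def test_resumed_run_continues_the_wave(self):
        # chaining run_simulation calls must keep delivering the stimulus
        # (events are scheduled relative to the current clock time)
        state = build_network(single_population(), seed=9)
        cfg = LearningConfig(scheme="none", gamma=0.0)
        first = run_simulation(
            state, [Phase(2.0, {"in": 5.0, "out": 5.0}, 0.0)], cfg, record_raster=True
        )
        second = run_simulation(
            state, [Phase(2.0, {"in": 5.0, "out": 5.0}, 0.0)], cfg, record_raster=True
        )
        n_in = len(state.spec.populations["in"])
        # each input neuron fires ~10 Hz in both segments
        assert len(first.raster) >= 0.9 * 2 * 10 * n_in
        assert len(second.raster) >= 0.9 * 2 * 10 * n_in
        assert second.raster.time_ms.min() >= 2000.0

    def test_low_target_drives_depression(self):
        # from random init with a 5 Hz target the incoming parameters of the
        # output population move toward depressing values (tau_rec, U up)
        state = build_network(single_population(), seed=6)
        tr0 = state.stp_params.tau_rec[state.spec.populations["out"]].mean()
        res = run_simulation(
            state,
            [Phase(30.0, {"in": 5.0, "out": 5.0}, 2.0)],
            LearningConfig(scheme="U_taurec", gamma=2.0),
        )
        tr_end = res.params["onto_out:tau_rec"].iloc[-1]
        assert tr_end > tr0
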