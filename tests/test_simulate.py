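import numpy as np
import pytest
import scipy.sparse as sp

from synchain.model import CouplingMatrix, DendriticModulation, ModelParams, build_network
from synchain.phase import PhaseFunctions, free_period
from synchain.simulate import (
    SimulationUnstable,
    SpikeRaster,
    StimulusProtocol,
    TAG_STIMULUS,
    advance,
    deliver_wave,
    equilibrate,
    init_state,
    sample_potentials,
    simulate,
)

LIN = DendriticModulation.identity()


def empty_net(N):
    return CouplingMatrix(sp.csr_matrix((N, N)))


def uncoupled(N=40, I_ext=1.5):
    return ModelParams(N=N, p_conn=0.1, p_exc=0.8, eps_exc=0.0, eps_inh=0.0,
                       I_ext=I_ext)


class TestFreeDynamics:
    def test_isi_equals_free_period(self):
        p = uncoupled()
        raster = simulate(p, empty_net(p.N), LIN, duration=8.0, stim=None, seed=3)
        T = free_period(p)
        for i in range(p.N):
            t = np.sort(raster.times[raster.ids == i])
            assert len(t) >= 2
            assert np.allclose(np.diff(t), T, rtol=1e-9)

    def test_deterministic_given_seed(self, small_params, small_net, ref_mod):
        a = simulate(small_params, small_net, ref_mod, 5.0, None, seed=11)
        b = simulate(small_params, small_net, ref_mod, 5.0, None, seed=11)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.ids, b.ids)
        assert np.array_equal(a.tags, b.tags)

    def test_different_seed_changes_raster(self, small_params, small_net, ref_mod):
        a = simulate(small_params, small_net, ref_mod, 5.0, None, seed=11)
        b = simulate(small_params, small_net, ref_mod, 5.0, None, seed=12)
        assert not (len(a) == len(b) and np.array_equal(a.times, b.times))


class TestStimulus:
    def test_pulse_forces_spikes_at_exact_time(self, small_params, small_net, ref_mod):
        t0 = 1.0
        stim = StimulusProtocol.single(t0, 25, small_params.N, seed=5)
        raster = simulate(small_params, small_net, ref_mod, 2.0, stim, seed=9)
        m = raster.times == t0
        stim_ids = set(raster.ids[m & (raster.tags == TAG_STIMULUS)].tolist())
        assert stim_ids == set(stim.pulses[0][1].tolist())

    def test_prefix_mode(self):
        stim = StimulusProtocol.single(0.5, 10, 100, prefix=True)
        assert np.array_equal(stim.pulses[0][1], np.arange(10))

    def test_empty_target_set_rejected(self):
        with pytest.raises(ValueError):
            StimulusProtocol([(0.0, np.array([], dtype=int))])


class TestEquilibrate:
    def test_zero_time_returns_initial_condition(self, small_params, small_net, ref_mod):
        a = equilibrate(small_params, small_net, ref_mod, 0.0, seed=21)
        b = init_state(small_params, seed=21)
        assert a.t_now == 0.0
        assert np.array_equal(a.next_spike, b.next_spike)
        assert np.array_equal(a.q_time, b.q_time)

    def test_same_seed_same_state(self, small_params, small_net, ref_mod):
        a = equilibrate(small_params, small_net, ref_mod, 3.0, seed=21)
        b = equilibrate(small_params, small_net, ref_mod, 3.0, seed=21)
        assert np.array_equal(a.next_spike, b.next_spike)
        assert np.array_equal(a.q_time, b.q_time)
        assert np.array_equal(a.q_sender, b.q_sender)

    def test_initial_phases_uniform(self):
        p = uncoupled(N=5000)
        st = init_state(p, seed=2)
        pf = PhaseFunctions.from_params(p)
        phases = st.phases(pf)
        assert phases.min() >= 0 and phases.max() < pf.phi_theta
        # KS distance from uniform must be small at N = 5000
        u = np.sort(phases) / pf.phi_theta
        ks = np.max(np.abs(u - np.arange(1, 5001) / 5000))
        assert ks < 0.03

    def test_potentials_stationary_after_equilibration(self, small_params,
                                                       small_net, ref_mod):
        """Membrane-potential distribution is time-invariant in the background
        state: first and second half of a long run agree."""
        state = equilibrate(small_params, small_net, ref_mod, 20.0, seed=3)
        snaps, state = sample_potentials(state, small_params, small_net, ref_mod,
                                         n_snapshots=60, interval=0.37)
        first, second = snaps[:30].ravel(), snaps[30:].ravel()
        qs = np.linspace(0.05, 0.95, 19)
        d = np.abs(np.quantile(first, qs) - np.quantile(second, qs))
        assert d.max() < 0.1  # potential units (threshold = 1)


class TestDeliverWave:
    def test_single_subthreshold_epsp(self):
        p = ModelParams(N=2, p_conn=0.5, p_exc=1.0, eps_exc=0.02, eps_inh=-0.0,
                        I_ext=1.5)
        pf = PhaseFunctions.from_params(p)
        mat = CouplingMatrix(sp.csr_matrix(([0.02], ([0], [1])), shape=(2, 2)))
        state = init_state(p, seed=0, n_transit_init=0)
        state.next_spike[:] = state.t_now + pf.phi_theta - pf.U_inv(0.3)
        fired = deliver_wave(state, [0], mat, LIN, pf)
        assert fired.size == 0
        V = state.potentials(pf)
        assert V[1] == pytest.approx(0.32, rel=1e-12)
        assert V[0] == pytest.approx(0.3, rel=1e-12)  # sender not its own target

    def test_supra_threshold_fires_and_resets(self):
        p = ModelParams(N=2, p_conn=0.5, p_exc=1.0, eps_exc=0.9, eps_inh=-0.0,
                        I_ext=1.5)
        pf = PhaseFunctions.from_params(p)
        mat = CouplingMatrix(sp.csr_matrix(([0.9], ([0], [1])), shape=(2, 2)))
        state = init_state(p, seed=0, n_transit_init=0)
        state.next_spike[:] = state.t_now + pf.phi_theta - pf.U_inv(0.3)
        fired = deliver_wave(state, [0], mat, LIN, pf, tau=0.1)
        assert fired.tolist() == [1]
        assert state.potentials(pf)[1] == pytest.approx(0.0, abs=1e-12)
        assert state.in_transit == [(state.t_now + 0.1, 1)]

    def test_convergent_inputs_supra_additive(self, ref_mod):
        """Two synchronous EPSPs inside the supra-additive band depolarize the
        target by sigma(2 eps) > 2 eps."""
        eps = 0.04  # 2*eps = 0.08 lies in (theta_b, theta_s) = (0.05, 0.1)
        p = ModelParams(N=3, p_conn=0.5, p_exc=1.0, eps_exc=eps, eps_inh=-0.0,
                        I_ext=1.5)
        pf = PhaseFunctions.from_params(p)
        mat = CouplingMatrix(
            sp.csr_matrix(([eps, eps], ([0, 1], [2, 2])), shape=(3, 3))
        )
        state = init_state(p, seed=0, n_transit_init=0)
        state.next_spike[:] = state.t_now + pf.phi_theta - pf.U_inv(0.2)
        deliver_wave(state, [0, 1], mat, ref_mod, pf)
        boost = state.potentials(pf)[2] - 0.2
        assert boost == pytest.approx(ref_mod(2 * eps), rel=1e-10)
        assert boost > 2 * eps

    def test_kernel_matches_reference_wave(self, small_params, small_net, ref_mod):
        """One wave processed by the event kernel equals deliver_wave."""
        pf = PhaseFunctions.from_params(small_params)
        state = equilibrate(small_params, small_net, ref_mod, 2.0, seed=8)
        senders = np.arange(0, 60)
        # route A: reference implementation
        ref_state = state.copy()
        ref_state.q_time = np.empty(0)
        ref_state.q_sender = np.empty(0, dtype=np.int64)
        fired_ref = deliver_wave(ref_state, senders, small_net, ref_mod, pf)
        # route B: kernel, by planting the wave in the queue
        kern_state = state.copy()
        kern_state.q_time = np.full(senders.size, state.t_now + 1e-6)
        kern_state.q_sender = senders.copy()
        raster, kern_after = advance(
            kern_state, small_params, small_net, ref_mod, 2e-6
        )
        assert set(raster.ids.tolist()) == set(fired_ref.tolist())
        # non-firing neurons carry identical updated pseudo-spike times
        quiet = np.setdiff1d(np.arange(small_params.N), raster.ids)
        assert np.allclose(
            kern_after.next_spike[quiet] - 1e-6,
            ref_state.next_spike[quiet],
            atol=1e-9,
        )


class TestCausalityAndConservation:
    def test_postsynaptic_spike_follows_after_exactly_tau(self):
        # 0 -> 1 with a strength that always fires the target
        p = ModelParams(N=2, p_conn=0.5, p_exc=1.0, eps_exc=1.0, eps_inh=-0.0,
                        I_ext=1.5, tau=0.1)
        mat = CouplingMatrix(sp.csr_matrix(([1.0], ([0], [1])), shape=(2, 2)))
        stim = StimulusProtocol.single(0.25, 1, 2, prefix=True)
        raster = simulate(p, mat, LIN, 0.5, stim, seed=1)
        t1 = raster.times[(raster.ids == 1)]
        assert np.any(np.abs(t1 - 0.35) < 1e-12)

    def test_explosion_guard_trips_on_runaway(self):
        # all-to-all strong excitation with a tiny delay: the whole network
        # re-fires every tau, far beyond the explosion guard
        p = ModelParams(N=100, p_conn=1.0, p_exc=1.0, eps_exc=1.0, eps_inh=-0.0,
                        I_ext=1.5, tau=0.001)
        mat = build_network(p, seed=0)
        with pytest.raises(SimulationUnstable):
            simulate(p, mat, LIN, duration=50.0, stim=None, seed=1)


class TestRasterIO:
    def test_csv_round_trip(self, tmp_path, small_params, small_net, ref_mod):
        stim = StimulusProtocol.single(0.5, 10, small_params.N, seed=1)
        r = simulate(small_params, small_net, ref_mod, 1.0, stim, seed=4)
        path = tmp_path / "raster.csv"
        r.to_csv(path, config_hash="abc123")
        assert "config_hash=abc123" in path.read_text().splitlines()[0]
        r2 = SpikeRaster.from_csv(path)
        assert np.array_equal(r.times, r2.times)
        assert np.array_equal(r.ids, r2.ids)
        assert np.array_equal(r.tags, r2.tags)
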