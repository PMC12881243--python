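"""Unit dynamics, update ordering, delay buffers and the two backends."""

import numpy as np
import pytest

from casim.network import (RingBuffer, compute_input, integrate_state,
                           spike_decision, update_adaptation, update_global,
                           update_rate, NumericalInstabilityError)
from casim.params import matched_delay_params, matched_exact_tau, preset
from casim.protocols import single_neuron_testbench


class TestIntegrateState:
    def test_euler_fixed_point(self):
        assert integrate_state(0.0, 0.0, tau=2.5, k1=0.01) == 0.0

    def test_euler_hand_step(self):
        assert integrate_state(0.0, 100.0, tau=2.5, k1=0.01, dt=1.0,
                               scheme="euler") == pytest.approx(0.4)

    def test_exact_closed_form(self):
        v = integrate_state(0.0, 100.0, tau=5.0, k1=0.01, dt=0.5, scheme="exact")
        assert v == pytest.approx(1.0 * (1 - np.exp(-0.1)), rel=1e-12)
        assert v == pytest.approx(0.09516, abs=1e-5)

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            integrate_state(0.0, 1.0, tau=0.0)

    def test_schemes_agree_first_order(self):
        """Euler approaches the exact map as dt -> 0 on a fixed input trace."""
        rng = np.random.default_rng(0)
        I = rng.uniform(-1, 1, 64)
        errs = []
        for dt in (0.5, 0.25, 0.125, 0.0625):
            ve = vx = 0.0
            steps = int(8 / dt)
            err = 0.0
            for t in range(steps):
                cur = I[int(t * dt * 8) % 64]
                ve = integrate_state(ve, cur, tau=2.5, dt=dt, scheme="euler")
                vx = integrate_state(vx, cur, tau=2.5, dt=dt, scheme="exact")
                err = max(err, abs(ve - vx))
            errs.append(err)
        assert errs[-1] < errs[0] / 4  # shrinks at least linearly in dt

    def test_decay_monotone_without_input(self):
        for scheme in ("euler", "exact"):
            v, trace = 1.0, []
            for _ in range(50):
                v = integrate_state(v, 0.0, tau=5.0, scheme=scheme)
                trace.append(v)
            assert all(a > b > 0 for a, b in zip(trace, trace[1:]))


class TestSpikeDecision:
    @pytest.mark.parametrize("V,omega,expected", [
        (0.2, 0.0, True),
        (0.18, 0.0, False),          # strict inequality at threshold
        (0.22, 0.05, False),         # 0.22 - 0.872*0.05 = 0.1764 < 0.18
    ])
    def test_threshold_cases(self, V, omega, expected):
        assert bool(spike_decision(V, omega, preset("felix"))) is expected


class TestLeakyTraces:
    def test_adaptation_hand_step(self):
        assert update_adaptation(0.0, 1.0, tau_adapt=10.0) == pytest.approx(0.1)

    def test_adaptation_saturates_at_one(self):
        w = 0.0
        for _ in range(500):
            w = update_adaptation(w, 1.0, tau_adapt=10.0)
        assert w == pytest.approx(1.0, abs=1e-6)

    def test_adaptation_pure_decay(self):
        w, trace = 0.7, []
        for _ in range(30):
            w = update_adaptation(w, 0.0, tau_adapt=10.0)
            trace.append(w)
        assert all(a > b > 0 for a, b in zip(trace, trace[1:]))

    def test_rate_hand_step(self):
        assert update_rate(0.0, 1.0, tau_favg=30.0) == pytest.approx(1 / 30)

    def test_rate_bounded_for_binary_input(self, rng):
        w = 0.0
        for phi in rng.integers(0, 2, 500):
            w = update_rate(w, float(phi), tau_favg=30.0)
            assert 0.0 <= w <= 1.0

    def test_global_hand_step(self):
        assert update_global(0.0, 50.0, tau_glob=12.0) == pytest.approx(50 / 12)

    def test_global_fixed_point(self):
        g = 0.0
        for _ in range(400):
            g = update_global(g, 7.0, tau_glob=12.0)
        assert g == pytest.approx(7.0, abs=1e-6)


class TestComputeInput:
    def test_silent_network_zero(self):
        assert compute_input() == 0.0

    def test_global_inhibition_term(self):
        assert compute_input(G=1.0, k_G=65.0) == pytest.approx(-65.0)

    def test_single_edge_contribution(self):
        assert compute_input([(500.0, [0.1], [1.0])]) == pytest.approx(50.0)


class TestRingBuffer:
    @pytest.mark.parametrize("lag", [1, 2, 5])
    def test_conserves_content_at_exact_lag(self, lag):
        buf = RingBuffer(lag, np.zeros(3))
        pushed = []
        for t in range(20):
            x = np.full(3, float(t))
            pushed.append(x)
            out = buf.push_pop(x)
            if t < lag:
                assert np.all(out == 0)
            else:
                assert np.array_equal(out, pushed[t - lag])

    def test_rejects_zero_lag(self):
        with pytest.raises(ValueError):
            RingBuffer(0, np.zeros(1))


class TestNetworkStep:
    def test_zero_state_is_fixed_point(self, fresh_felix_net):
        net = fresh_felix_net
        for _ in range(5):
            net.step(noise=False)
        assert not net.V_e.any() and not net.phi.any() and not net.G.any()

    def test_fast_engine_matches_reference_step(self):
        """The compiled multi-step kernel reproduces the numpy path exactly."""
        from casim import Network
        a = Network.build(preset("felix"), seed=5)
        b = Network.build(preset("felix"), seed=5)
        rng = np.random.default_rng(17)
        drive = np.zeros(a.n_e)
        drive[rng.choice(a.n_e, 60, replace=False)] = 55.0
        eta = rng.uniform(-0.5, 0.5, (20, a.n_e))
        a.run(20, drive=drive, noise_amplitude=30.0, plastic=True, eta=eta)
        for t in range(20):
            b.step(drive=drive, noise_amplitude=30.0, plastic=True, eta=eta[t])
        assert np.array_equal(a.V_e, b.V_e)
        assert np.array_equal(a.ee_w, b.ee_w)
        assert np.array_equal(a.phi, b.phi)
        assert np.array_equal(a.G, b.G)

    def test_identical_seeds_identical_trajectories(self):
        from casim import Network
        a = Network.build(preset("felix"), seed=9)
        b = Network.build(preset("felix"), seed=9)
        ra = a.run(30, noise_amplitude=30.0)
        rb = b.run(30, noise_amplitude=30.0)
        assert np.array_equal(ra.area_counts, rb.area_counts)
        assert np.array_equal(a.V_e, b.V_e)

    def test_delay_mode_network_runs(self):
        """The exact-integration backend drives the full architecture too."""
        from casim import Network
        net = Network.build(preset("nest"), seed=2)
        drive = np.zeros(net.n_e)
        drive[:20] = 55.0
        res = net.run(10, drive=drive, noise_amplitude=30.0, plastic=True,
                      record_spikes=True)
        assert res.spikes[:, :20].any()
        assert np.isfinite(net.V_e).all()

    def test_instability_names_area(self, fresh_felix_net):
        net = fresh_felix_net
        net.V_e[net.area_slice("TO").start] = np.nan
        with pytest.raises(NumericalInstabilityError, match="TO"):
            net.step(noise=False)


class TestBackendEquivalence:
    """Same dependency graph, matched per-step decays -> identical dynamics."""

    def test_single_pair_spike_trains_identical(self):
        felix = preset("felix")
        delay = matched_delay_params()
        tf = single_neuron_testbench(felix, 55.0, duration=16, total_steps=40)
        td = single_neuron_testbench(delay, 55.0, duration=16, total_steps=40)
        assert np.array_equal(tf["spikes"], td["spikes"])
        assert tf["spikes"].sum() >= 2

    def test_single_pair_traces_match_closely(self):
        tf = single_neuron_testbench(preset("felix"), 55.0)
        td = single_neuron_testbench(matched_delay_params(), 55.0)
        for key in ("V_exc", "omega_adapt", "V_inh"):
            assert np.max(np.abs(tf[key] - td[key])) < 1e-6

    def test_matched_tau_inverts_euler_decay(self):
        for tau in (2.5, 5.0, 12.0, 30.0):
            te = matched_exact_tau(tau, substeps=2)
            assert np.exp(-2 / te) == pytest.approx(1 - 1 / tau, rel=1e-12)

    def test_table_constants_differ_slightly(self):
        """With the published (unmatched) constants the integrators differ."""
        tf = single_neuron_testbench(preset("felix"), 55.0)
        tn = single_neuron_testbench(preset("nest"), 55.0)
        assert not np.allclose(tf["V_exc"], tn["V_exc"], atol=1e-6)


class TestSingleNeuronBehaviour:
    def test_zero_current_flat(self):
        t = single_neuron_testbench(preset("felix"), 0.0)
        assert not t["spikes"].any()
        assert not t["V_exc"].any()

    def test_adaptation_rises_then_decays(self):
        t = single_neuron_testbench(preset("felix"), 55.0, duration=16,
                                    total_steps=48)
        om = t["omega_adapt"]
        assert om[:16].max() > 0.1            # builds up under stimulation
        assert om[20] > om[30] > om[47] > 0   # slow decay afterwards

    def test_interspike_intervals_lengthen(self):
        """Adaptation raises the effective threshold during constant drive."""
        t = single_neuron_testbench(preset("felix"), 55.0, duration=30,
                                    total_steps=30)
        times = np.flatnonzero(t["spikes"])
        isis = np.diff(times)
        assert len(isis) >= 2
        assert isis[-1] > isis[0]
        assert all(b >= a for a, b in zip(isis, isis[1:]))
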