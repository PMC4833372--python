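"""Spiking simulation: input statistics, conductances, membrane, online STDP."""

import numpy as np
import pytest
from conftest import stdp_all_pairs

from ringstdp.ring_meanfield import RingConfig, ring_phases
from ringstdp.single_synapse import fixed_point_weight
from ringstdp.spiking_sim import (
    NeuronParams,
    OnlineSTDPState,
    SimConfig,
    conductance_trace,
    generate_input_spikes,
    lif_step,
    measure_effective_delay,
    measure_post_oscillation,
    run_simulation,
)
from ringstdp.stdp_core import STDPRule, wrap_phase

NU10 = 2 * np.pi * 10
DT = 1e-3


def _poisson_train(rate_fn, duration, seed, dt=DT):
    T = int(round(duration / dt))
    t = (np.arange(T) + 0.5) * dt
    rng = np.random.Generator(np.random.PCG64(seed))
    return (rng.random(T) < rate_fn(t) * dt).astype(np.uint8)


class TestInputSpikes:
    def test_unmodulated_rates(self):
        ring = RingConfig(N=20, D=10.0, A=0.0, nu=NU10, d=0.0)
        raster = generate_input_spikes(ring, DT, 100.0, seed=0)
        rates = raster.sum(axis=1) / 100.0
        se = np.sqrt(10.0 / 100.0)  # Poisson counting error per source
        assert np.all(np.abs(rates - 10.0) < 3 * se)

    def test_probability_cap(self):
        ring = RingConfig(N=4, D=600.0, A=600.0, nu=NU10, d=0.0)
        with pytest.raises(ValueError):
            generate_input_spikes(ring, DT, 1.0, seed=0)

    def test_population_rate_constant_in_time(self):
        """Evenly spaced phases make the summed pre-synaptic rate flat."""
        ring = RingConfig(N=60, D=10.0, A=10.0, nu=NU10, d=0.0)
        duration = 100.0
        raster = generate_input_spikes(ring, DT, duration, seed=1)
        pop = raster.sum(axis=0).astype(float)
        # bin the population count by oscillation phase
        t = (np.arange(pop.size) + 0.5) * DT
        phase_bin = ((NU10 * t) % (2 * np.pi) / (2 * np.pi) * 8).astype(int)
        counts = np.bincount(phase_bin, weights=pop, minlength=8)
        n_bins = np.bincount(phase_bin, minlength=8)
        rate_per_bin = counts / n_bins / DT
        expected = 60 * 10.0
        se = np.sqrt(expected / (n_bins[0] * DT))
        assert np.all(np.abs(rate_per_bin - expected) < 4 * se)

    def test_full_modulation_non_negative(self):
        ring = RingConfig(N=8, D=10.0, A=10.0, nu=NU10, d=0.0)
        raster = generate_input_spikes(ring, DT, 10.0, seed=2)
        assert raster.min() >= 0 and raster.max() <= 1


class TestConductance:
    def test_single_spike_alpha_bump(self):
        params = NeuronParams()
        raster = np.zeros((1, 100), dtype=np.uint8)
        raster[0, 10] = 1
        g = conductance_trace(raster, [1.0], params, "E", DT)
        peak = np.argmax(g)
        assert peak == 10 + int(params.tau_E / DT)
        assert g[peak] == pytest.approx(params.g0_E(1) * params.tau_E * np.exp(-1), rel=1e-12)
        assert np.all(g[:11] == 0.0)

    def test_no_spikes_and_linearity(self):
        params = NeuronParams()
        empty = np.zeros((1, 50), dtype=np.uint8)
        assert np.all(conductance_trace(empty, [1.0], params, "I", DT) == 0.0)
        rng = np.random.Generator(np.random.PCG64(3))
        train = (rng.random(200) < 0.05).astype(np.uint8)[None, :]
        g1 = conductance_trace(train, [1.0], params, "E", DT)
        g2 = conductance_trace(np.vstack([train, train]), [1.0, 1.0], params, "E", DT)
        # two identical trains double the drive, up to the 1/N_E scale in g0
        assert np.allclose(g2 * 1.0, 2 * g1 * (1 / 2), rtol=1e-12)


class TestMembrane:
    def test_leak_decay_closed_form(self):
        """With no synaptic input the Euler membrane relaxes geometrically
        with the 20 ms membrane time constant."""
        p = NeuronParams()
        tau_m = p.R_m * p.C_m
        assert tau_m == pytest.approx(0.020)
        V = -60e-3
        a = 1.0 - DT / tau_m
        for k in range(1, 61):
            V, spiked = lif_step(V, 0.0, 0.0, p, DT)
            assert not spiked
            assert V == pytest.approx(p.V_rest + (-60e-3 - p.V_rest) * a**k, rel=1e-12)

    def test_rest_is_stationary(self):
        p = NeuronParams()
        V, spiked = lif_step(p.V_rest, 0.0, 0.0, p, DT)
        assert V == p.V_rest and not spiked

    def test_constant_drive_period_matches_charging_time(self):
        """Suprathreshold constant conductance gives periodic firing with the
        analytic charging period (to within one Euler step)."""
        p = NeuronParams()
        gE = 5e-9
        V, last, periods = p.V_rest, None, []
        for n in range(2000):
            V, spiked = lif_step(V, gE, 0.0, p, DT)
            if spiked:
                if last is not None:
                    periods.append((n - last) * DT)
                last = n
        g_tot = 1 / p.R_m + gE
        tau_eff = p.C_m / g_tot
        V_inf = (p.V_rest / p.R_m + gE * p.E_E) / g_tot
        t_star = tau_eff * np.log((V_inf - p.V_rest) / (V_inf - p.V_th))
        assert len(set(periods)) == 1
        assert abs(periods[0] - t_star) <= DT


class TestOnlineSTDP:
    def test_single_pair_update(self):
        """One pre spike 10 ms before one post spike: Delta-w = lam*f+(w)*K+(10ms)."""
        rule = STDPRule(family="exponential", tau_plus=0.020, tau_minus=0.020,
                        H=1, alpha=1.0, mu=1.0, learning_rate=1e-3)
        state = OnlineSTDPState(rule, n_synapses=1, dt=DT, w0=0.5)
        state.step([True], False)
        for _ in range(9):
            state.step([False], False)
        w = state.step([False], True)  # post fires 10 ms after pre
        expected = 0.5 + 1e-3 * 0.5 * np.exp(-0.010 / 0.020) / 0.020
        assert w[0] == pytest.approx(expected, rel=1e-12)

    def test_post_before_pre_only_depresses(self):
        rule = STDPRule(family="exponential", tau_plus=0.020, tau_minus=0.020,
                        H=1, alpha=1.0, mu=1.0, learning_rate=1e-3)
        state = OnlineSTDPState(rule, n_synapses=1, dt=DT, w0=0.5)
        state.step([False], True)
        for _ in range(4):
            state.step([False], False)
        w = state.step([True], False)
        assert w[0] < 0.5

    def test_simultaneous_pair_is_ignored_exponential(self):
        rule = STDPRule(family="exponential", learning_rate=1e-3, mu=1.0)
        state = OnlineSTDPState(rule, 1, dt=DT, w0=0.5)
        w = state.step([True], True)
        assert w[0] == 0.5

    @pytest.mark.parametrize(
        "rule",
        [
            STDPRule(family="exponential", tau_plus=0.020, tau_minus=0.035, H=1,
                     alpha=1.2, mu=0.5, learning_rate=1e-3),
            STDPRule(family="exponential", tau_plus=0.015, tau_minus=0.020, H=-1,
                     alpha=1.0, mu=0.0, learning_rate=1e-3),
            STDPRule(family="gaussian", tau_plus=0.020, tau_minus=0.030,
                     T_plus=0.009, T_minus=0.009, alpha=1.1, mu=0.3, learning_rate=1e-3),
        ],
        ids=["hebbian-exp", "anti-hebbian-additive", "shifted-gaussian"],
    )
    def test_online_matches_all_pairs_bruteforce(self, rule):
        """Trace/buffer accumulation equals the explicit all-pairs double loop."""
        rng = np.random.Generator(np.random.PCG64(7))
        T = 1000  # 1 s
        pre = (rng.random((6, T)) < 0.02).astype(np.uint8)
        post = (rng.random(T) < 0.02).astype(np.uint8)
        state = OnlineSTDPState(rule, n_synapses=6, dt=DT, w0=0.5)
        for n in range(T):
            state.step(pre[:, n].astype(bool), bool(post[n]))
        max_lag = state.L if rule.family == "gaussian" else None
        ref = stdp_all_pairs(pre, post, rule, DT, 0.5, max_lag_bins=max_lag)
        assert np.max(np.abs(state.w - ref)) < 1e-12

    @pytest.mark.parametrize("family", ["exponential", "gaussian"])
    def test_compiled_core_matches_online_state(self, family):
        """The compiled simulation loop and the step-wise reference implementation
        produce identical weights on the same raster."""
        if family == "exponential":
            rule = STDPRule(family="exponential", tau_plus=0.020, tau_minus=0.030,
                            H=1, alpha=1.1, mu=0.2, learning_rate=2e-3)
        else:
            rule = STDPRule(family="gaussian", tau_plus=0.020, tau_minus=0.030,
                            T_plus=0.005, T_minus=0.005, alpha=1.0, mu=0.0,
                            learning_rate=2e-3)
        ring = RingConfig(N=12, D=10.0, A=10.0, nu=NU10, d=0.0)
        duration = 5.0
        post = _poisson_train(lambda t: 8 + 8 * np.cos(NU10 * t), duration, seed=5)
        cfg = SimConfig(ring=ring, rule=rule, duration=duration, seed=21)
        series, exc = run_simulation(cfg, post_override=post, return_raster=True)
        state = OnlineSTDPState(rule, n_synapses=12, dt=DT, w0=0.5)
        for n in range(post.size):
            state.step(exc[:, n].astype(bool), bool(post[n]))
        assert np.max(np.abs(series.final_weights - state.w)) < 1e-12


class TestMeasurement:
    def test_recovers_rate_modulation(self):
        nu = NU10
        train = _poisson_train(lambda t: 10 + 5 * np.cos(nu * t - 1.0), 60.0, seed=11)
        times = (np.nonzero(train)[0] + 0.5) * DT
        _, D, A, phi = measure_post_oscillation(times, nu, 60.0, 60.0)
        assert D[0] == pytest.approx(10.0, abs=3 * np.sqrt(10 / 60))
        assert A[0] == pytest.approx(5.0, abs=3 * np.sqrt(2 * 10 / 60))
        assert abs(wrap_phase(phi[0] - 1.0)) < 0.25

    def test_unmodulated_amplitude_near_zero(self):
        train = _poisson_train(lambda t: 10 + 0 * t, 120.0, seed=13)
        times = (np.nonzero(train)[0] + 0.5) * DT
        _, D, A, _ = measure_post_oscillation(times, NU10, 120.0, 120.0)
        assert A[0] < 3 * np.sqrt(2 * D[0] / 120.0)

    def test_empty_window_flagged(self):
        _, D, A, phi = measure_post_oscillation(np.array([]), NU10, 10.0, 20.0)
        assert np.all(D == 0.0) and np.all(np.isnan(A)) and np.all(np.isnan(phi))


class TestSimulation:
    def test_deterministic_given_seed(self):
        rule = STDPRule(family="exponential", alpha=1.1, mu=0.1, learning_rate=5e-3)
        ring = RingConfig(N=40, D=10.0, A=10.0, nu=NU10, d=0.0)
        cfg = SimConfig(ring=ring, rule=rule, duration=20.0, seed=123)
        s1, s2 = run_simulation(cfg), run_simulation(cfg)
        assert np.array_equal(s1.post_spike_times, s2.post_spike_times)
        assert np.array_equal(s1.final_weights, s2.final_weights)
        assert np.array_equal(s1.w_tilde, s2.w_tilde)

    def test_homogeneous_weights_do_not_oscillate(self):
        """Uniform weights cancel the ring modulation: the post-synaptic rate
        carries no significant component at the input frequency."""
        rule = STDPRule(family="exponential", alpha=1.0, mu=0.0)
        ring = RingConfig(N=120, D=10.0, A=10.0, nu=NU10, d=0.0)
        cfg = SimConfig(ring=ring, rule=rule, duration=120.0, seed=29,
                        plasticity=False, post_bin=120.0)
        s = run_simulation(cfg)
        n_spikes = s.post_spike_times.size
        assert n_spikes > 100  # the neuron does fire
        se_null = np.sqrt(2 * s.D_post[0] / 120.0)  # Poisson shuffle-null SE
        assert s.A_post[0] < 3 * se_null

    def test_no_modulation_no_symmetry_breaking(self):
        """Without rate modulation w_tilde stays at the noise floor (mu > 0)."""
        rule = STDPRule(family="exponential", alpha=1.1, mu=0.1, learning_rate=5e-4)
        ring = RingConfig(N=60, D=10.0, A=0.0, nu=NU10, d=0.0)
        s = run_simulation(SimConfig(ring=ring, rule=rule, duration=240.0, seed=31))
        # the first Fourier mode stays at the finite-N noise floor and does not grow
        q = s.w_tilde.size // 4
        assert np.all(s.w_tilde < 0.1)
        assert s.w_tilde[-q:].mean() < 2 * s.w_tilde[:q].mean()

    def test_single_synapse_theory_recovered(self):
        """With a prescribed modulated post train (weak coupling), stationary
        mean weights reproduce the single-synapse fixed-point profile."""
        rule = STDPRule(family="exponential", tau_plus=0.020, tau_minus=0.020,
                        H=1, alpha=1.0, mu=0.1, learning_rate=1e-4)
        ring = RingConfig(N=48, D=10.0, A=10.0, nu=NU10, d=0.0)
        duration = 1500.0
        post = _poisson_train(lambda t: 10 + 10 * np.cos(NU10 * t), duration, seed=99)
        s = run_simulation(SimConfig(ring=ring, rule=rule, duration=duration, seed=42),
                           post_override=post)
        w_mean = s.weight_snapshots[-700:].mean(axis=0)
        w_star = fixed_point_weight(ring_phases(48), rule, NU10, 0.5)
        dev = np.abs(w_mean - w_star)
        assert dev.mean() < 0.05
        # pointwise agreement away from the (near-discontinuous) transition
        plateau = (w_star < 0.1) | (w_star > 0.9)
        assert plateau.sum() > 20
        assert dev[plateau].max() < 0.05


class TestEffectiveDelay:
    def test_imposed_linear_poisson_delay_recovered(self):
        """A prescribed post train with a built-in delay d0 returns d0."""
        d0 = 0.012
        ring = RingConfig(N=64, D=10.0, A=10.0, nu=NU10, d=0.0)
        rule = STDPRule(family="exponential")
        weights = 0.5 + 0.5 * np.cos(ring_phases(64))
        # linear Poisson read-out of the delayed weighted drive (phase psi = 0)
        post = _poisson_train(lambda t: 10 + 8 * np.cos(NU10 * (t - d0)), 400.0, seed=17)
        cfg = SimConfig(ring=ring, rule=rule, duration=400.0, seed=55)
        d = measure_effective_delay(cfg, frozen_weights=weights, post_override=post)
        assert d == pytest.approx(d0, abs=1.5e-3)

    def test_requires_modulated_profile(self):
        ring = RingConfig(N=16, D=10.0, A=10.0, nu=NU10, d=0.0)
        cfg = SimConfig(ring=ring, rule=STDPRule(), duration=10.0, seed=1)
        with pytest.raises(ValueError):
            measure_effective_delay(cfg, frozen_weights=np.full(16, 0.5))
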