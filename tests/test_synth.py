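import numpy as np
import pytest
from scipy.linalg import expm
from scipy.signal import periodogram

from ipsckit import (
    AgonistPulse,
    MixtureSpec,
    MiniTrainSpec,
    Trace,
    add_noise,
    calibrate_scheme,
    default_scheme,
    generate_biexp_event,
    generate_mini_train,
    sample_decay_mixture,
    simulate_channels_mc,
    simulate_macroscopic,
)
from ipsckit import params as P
from ipsckit.errors import CalibrationError
from ipsckit.synth import measure_macroscopic_tau

PULSE = AgonistPulse()  # 1-ms pulse of 1 mM agonist


class TestMacroscopic:
    def test_occupancy_conservation(self):
        res = simulate_macroscopic(default_scheme(), PULSE, duration=400.0)
        np.testing.assert_allclose(res.occupancy.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_concentration_gives_flat_zero_current(self):
        res = simulate_macroscopic(default_scheme(),
                                   AgonistPulse(concentration=0.0), duration=100.0)
        assert np.abs(res.trace.samples).max() == 0.0

    def test_current_is_zero_before_pulse_onset(self):
        res = simulate_macroscopic(default_scheme(),
                                   AgonistPulse(onset=20.0), duration=100.0)
        pre = res.trace.samples[res.trace.time() < 20.0]
        assert np.abs(pre).max() < 1e-12

    def test_matches_matrix_exponential_oracle(self):
        # piecewise-constant generator: the propagator over each segment is
        # a matrix exponential, an independent route to the same solution
        sch = default_scheme()
        res = simulate_macroscopic(sch, PULSE, duration=50.0, dt=0.5)
        p = np.zeros(len(sch.state_names))
        p[sch.index("U")] = 1.0
        QT_on = sch.rate_matrix(1e-3).T
        QT_off = sch.rate_matrix(0.0).T
        p_end_pulse = expm(QT_on * 1e-3) @ p          # 1 ms in seconds
        p_10ms = expm(QT_off * 9e-3) @ p_end_pulse     # to t = 10 ms
        i_10 = int(round(10.0 / 0.5))
        np.testing.assert_allclose(res.occupancy[i_10], p_10ms, atol=1e-7)

    def test_scaled_scheme_macroscopic_tau_matches_calibration(self, fast_scheme):
        tau = measure_macroscopic_tau(fast_scheme)
        assert tau == pytest.approx(P.FAST_DECAY_TARGET_MS, rel=0.05)


class TestMonteCarlo:
    def test_zero_channels_gives_zero_trace(self):
        tr = simulate_channels_mc(default_scheme(), 0, PULSE, duration=50.0, seed=1)
        assert np.all(tr.samples == 0.0)

    def test_seeded_determinism(self):
        a = simulate_channels_mc(default_scheme(), 50, PULSE, duration=100.0, seed=9)
        b = simulate_channels_mc(default_scheme(), 50, PULSE, duration=100.0, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_mean_open_fraction_tracks_ode(self, fast_scheme):
        # 400 channels: a fast sanity check of the MC/ODE equivalence that
        # the acceptance suite verifies at 2000 channels
        n = 400
        mc = simulate_channels_mc(fast_scheme, n, PULSE, duration=200.0, seed=7)
        ode = simulate_macroscopic(fast_scheme, PULSE, duration=200.0)
        p_open = ode.open_occupancy(fast_scheme)
        emp = mc.samples / (fast_scheme.unitary_current * n)
        se = np.sqrt(p_open * (1 - p_open) / n)
        mask = se > 0
        z = np.abs(emp - p_open)[mask] / se[mask]
        assert z.max() < 3.5


class TestCalibration:
    def test_fixed_point_returns_unit_scale(self):
        sch = default_scheme()
        tau0 = measure_macroscopic_tau(sch)
        back = calibrate_scheme(sch, tau0, vary="all")
        for edge, rate in sch.fixed_rates.items():
            assert back.fixed_rates[edge] == pytest.approx(rate, rel=0.05)

    def test_binding_unbinding_only_preserves_other_rates(self, fast_scheme, slow_scheme):
        unbinding = set(fast_scheme.unbinding_edges())
        for edge, rate in fast_scheme.fixed_rates.items():
            if edge not in unbinding:
                assert slow_scheme.fixed_rates[edge] == rate
        assert slow_scheme.agonist_rates == fast_scheme.agonist_rates

    def test_slow_target_reached(self, slow_scheme):
        tau = measure_macroscopic_tau(slow_scheme, duration=2000.0)
        assert tau == pytest.approx(P.SLOW_DECAY_TARGET_MS, rel=0.05)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            calibrate_scheme(default_scheme(), -5.0)

    def test_unreachable_target_raises(self):
        with pytest.raises(CalibrationError):
            calibrate_scheme(default_scheme(), 1e9, vary="all")


class TestNoise:
    def test_zero_sd_is_identity(self, rng):
        tr = Trace(rng.standard_normal(1000), dt=0.1)
        out = add_noise(tr, 0.0, seed=1)
        np.testing.assert_array_equal(out.samples, tr.samples)

    def test_sample_sd_matches_request(self):
        tr = Trace(np.zeros(100_000), dt=0.1)  # 10 s at 10 kHz
        out = add_noise(tr, 2.0, seed=2)
        assert 1.9 < out.samples.std() < 2.1

    def test_mean_is_stationary(self):
        tr = Trace(np.zeros(200_000), dt=0.1)
        out = add_noise(tr, 2.0, seed=3)
        assert abs(out.samples.mean()) < 0.05 * 2.0

    def test_spectrum_attenuated_beyond_cutoff(self):
        tr = Trace(np.zeros(400_000), dt=0.1)
        out = add_noise(tr, 1.0, bandwidth_khz=3.0, seed=4)
        f, pxx = periodogram(out.samples, fs=1.0 / 0.1)  # kHz
        passband = pxx[(f > 0.2) & (f < 2.0)].mean()
        stopband = pxx[f >= 4.0].mean()
        assert 10 * np.log10(passband / stopband) >= 20.0


class TestBiexpEvent:
    def test_peak_equals_summed_amplitudes(self):
        ev = generate_biexp_event(31.5, 31.9, 15.1, 152.0, rise_tau=0.5, dt=0.1)
        assert ev.samples.max() == pytest.approx(46.6, rel=0.02)

    def test_pure_monoexponential_when_second_amp_zero(self):
        ev = generate_biexp_event(20.0, 50.0, 0.0, rise_tau=0.2, dt=0.1)
        pk = int(np.argmax(ev.samples))
        t = np.arange(ev.samples.size - pk) * 0.1
        np.testing.assert_allclose(ev.samples[pk:], 20.0 * np.exp(-t / 50.0), rtol=1e-12)

    def test_equal_taus_collapse_to_single_exponential(self):
        ev = generate_biexp_event(10.0, 40.0, 10.0, 40.0, rise_tau=0.2, dt=0.1)
        mono = generate_biexp_event(20.0, 40.0, 0.0, rise_tau=0.2, dt=0.1,
                                    duration=ev.duration)
        np.testing.assert_allclose(ev.samples, mono.samples, atol=1e-12)

    def test_taus_sorted(self):
        ev = generate_biexp_event(15.1, 152.0, 31.5, 31.9, rise_tau=0.5, dt=0.1,
                                  duration=1500.0)
        ref = generate_biexp_event(31.5, 31.9, 15.1, 152.0, rise_tau=0.5, dt=0.1,
                                   duration=1500.0)
        np.testing.assert_allclose(ev.samples, ref.samples)


class TestMixtureSampler:
    def test_single_narrow_component_returns_mean(self):
        spec = MixtureSpec((1.0,), (50.0,), (1e-12,))
        np.testing.assert_allclose(sample_decay_mixture(spec, 10, seed=1), 50.0)

    def test_degenerate_weights_select_one_component(self):
        spec = MixtureSpec((1.0, 0.0, 0.0), (10.0, 100.0, 1000.0), (1.0, 1.0, 1.0))
        taus = sample_decay_mixture(spec, 500, seed=2)
        assert np.all(taus < 20.0)

    def test_mass_below_boundary_matches_mixture_cdf(self):
        from scipy.stats import norm
        spec = P.MIXTURE_EGFP_NEG
        n = 10_000
        taus = sample_decay_mixture(spec, n, seed=3)
        x = 45.0
        expected = sum(
            w * norm.cdf(x, m, s) for w, m, s in zip(spec.weights, spec.means, spec.sds)
        )
        se = np.sqrt(expected * (1 - expected) / n)
        # 3 binomial SE plus a small allowance for the tau>0 truncation
        assert abs(np.mean(taus < x) - expected) < 3 * se + 0.005

    def test_all_draws_positive(self):
        spec = MixtureSpec((1.0,), (5.0,), (20.0,))  # heavy mass below zero
        taus = sample_decay_mixture(spec, 2000, seed=4)
        assert (taus > 0).all()

    def test_reproducible_by_seed(self):
        a = sample_decay_mixture(P.MIXTURE_EGFP_POS, 100, seed=5)
        b = sample_decay_mixture(P.MIXTURE_EGFP_POS, 100, seed=5)
        np.testing.assert_array_equal(a, b)


class TestMiniTrain:
    def test_zero_rate_gives_pure_noise_and_empty_truth(self):
        spec = MiniTrainSpec(duration=10.0, event_rate=0.0, noise_sd=1.0, seed=1)
        trace, truth = generate_mini_train(spec)
        assert len(truth) == 0
        assert 0.9 < trace.samples.std() < 1.1

    def test_event_count_near_poisson_mean(self):
        spec = MiniTrainSpec(duration=600.0, event_rate=0.15, noise_sd=0.0, seed=2)
        _, truth = generate_mini_train(spec)
        mean = 0.15 * 600  # 90
        assert abs(len(truth) - mean) < 4 * np.sqrt(mean)

    def test_same_seed_identical_output(self):
        spec = MiniTrainSpec(duration=30.0, event_rate=0.2, seed=3)
        t1, truth1 = generate_mini_train(spec)
        t2, truth2 = generate_mini_train(spec)
        np.testing.assert_array_equal(t1.samples, t2.samples)
        assert truth1.equals(truth2)

    def test_inward_polarity_is_negative_going(self):
        spec = MiniTrainSpec(duration=60.0, event_rate=0.5, noise_sd=0.0, seed=4)
        trace, truth = generate_mini_train(spec)
        assert len(truth) > 0
        assert trace.samples.min() < -5.0
        assert trace.samples.max() <= 1e-9
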