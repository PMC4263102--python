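import numpy as np
import pytest

from ipsckit import (
    Event,
    MiniTrainSpec,
    Trace,
    detect_events,
    event_charge,
    generate_biexp_event,
    generate_mini_train,
    rise_time_10_90,
    rms_noise,
)


class TestRmsNoise:
    def test_constant_trace_is_zero(self):
        assert rms_noise(Trace(np.full(1000, 3.7), dt=0.1)) == pytest.approx(0.0)

    def test_gaussian_noise_estimate(self, rng):
        tr = Trace(2.0 * rng.standard_normal(100_000), dt=0.1)  # 10 s
        assert 1.9 < rms_noise(tr) < 2.1
        assert 1.9 < rms_noise(tr, robust=True) < 2.1

    def test_sine_closed_form(self):
        a, periods = 5.0, 20
        t = np.linspace(0, periods * 2 * np.pi, periods * 1000, endpoint=False)
        tr = Trace(a * np.sin(t), dt=0.1)
        assert rms_noise(tr) == pytest.approx(a / np.sqrt(2), rel=0.01)

    def test_window_selects_segment(self):
        y = np.r_[np.zeros(5000), 50.0 * np.ones(1000)]
        tr = Trace(y, dt=0.1)
        assert rms_noise(tr, window=(0.0, 400.0)) == pytest.approx(0.0)


def _train(amplitude, seed, duration=600.0, rate=0.1, noise_sd=2.0):
    spec = MiniTrainSpec(duration=duration, event_rate=rate,
                         amplitude_mean=amplitude, amplitude_sd=0.0,
                         noise_sd=noise_sd, seed=seed)
    return generate_mini_train(spec)


def _match(events, truth, tol_ms=10.0):
    onsets = truth["onset_ms"].to_numpy()
    used = np.zeros(len(onsets), dtype=bool)
    tp = 0
    for ev in events:
        d = np.abs(onsets - ev.onset)
        d[used] = np.inf
        if d.size and d.min() <= tol_ms:
            used[np.argmin(d)] = True
            tp += 1
    return tp


class TestDetection:
    def test_subthreshold_events_not_detected(self):
        trace, _ = _train(amplitude=2.0, seed=3, duration=120.0, rate=0.2)
        assert detect_events(trace, polarity="inward") == []

    def test_recall_and_precision_on_synthetic_train(self):
        trace, truth = _train(amplitude=16.0, seed=7)  # 8x noise SD
        events = detect_events(trace, polarity="inward")
        tp = _match(events, truth)
        assert tp / len(truth) >= 0.95
        assert (len(events) - tp) / 600.0 <= 0.01  # false positives per second

    def test_compound_flag_for_close_events(self):
        ev = generate_biexp_event(20.0, 30.0, rise_tau=0.3, dt=0.1, duration=300.0)
        y = np.zeros(6000)
        y[:len(ev.samples)] += ev.samples
        i5 = int(5.0 / 0.1)
        y[i5:i5 + len(ev.samples)] += ev.samples[:6000 - i5]
        trace = Trace(-y, dt=0.1)
        events = detect_events(trace, threshold=5.0, polarity="inward")
        assert len(events) >= 2
        assert events[1].compound

    def test_short_trace_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert detect_events(Trace(np.zeros(3), dt=0.1), threshold=1.0) == []

    def test_amplitude_measured_against_local_baseline(self):
        trace, truth = _train(amplitude=20.0, seed=5, noise_sd=0.0, duration=300.0,
                              rate=0.05)
        events = detect_events(trace, threshold=2.0, polarity="inward")
        assert len(events) == len(truth)
        for ev in events:
            assert ev.amplitude == pytest.approx(20.0, rel=0.02)


class TestRiseTime:
    def test_exponential_rise_closed_form(self):
        # t(10->90) = tau_r * ln(0.9/0.1) for a saturating exponential
        tau_r, dt = 2.0, 0.01
        t = np.arange(0, 40, dt)
        y = 10.0 * (1 - np.exp(-t / tau_r))
        trace = Trace(y, dt=dt)
        ev = Event(onset=0.0, peak_time=t[-1], amplitude=10.0, rise_10_90=1.0)
        measured = rise_time_10_90(trace, ev, polarity="outward")
        assert measured == pytest.approx(tau_r * np.log(9.0), rel=0.01)

    def test_step_rise_within_one_sample(self):
        y = np.r_[np.zeros(100), np.full(100, 10.0)]
        trace = Trace(y, dt=0.1)
        ev = Event(onset=9.0, peak_time=11.0, amplitude=10.0, rise_10_90=1.0)
        assert rise_time_10_90(trace, ev, polarity="outward") <= 0.1

    def test_synthetic_fast_event_rise(self):
        # reconstruction of the recorded fast mini used in the filtering
        # study: 10-90% rise 1.2 ms on a 27.3-ms decay
        rise_tau = 1.2 / np.log(9.0)
        ev_tr = generate_biexp_event(20.0, 27.3, rise_tau=rise_tau, dt=0.02)
        pk = int(np.argmax(ev_tr.samples))
        ev = Event(onset=0.0, peak_time=pk * 0.02, amplitude=20.0, rise_10_90=1.0)
        measured = rise_time_10_90(ev_tr, ev, polarity="outward")
        assert measured == pytest.approx(1.2, rel=0.10)


class TestCharge:
    def test_monoexponential_charge_closed_form(self):
        a, tau = 20.0, 50.0
        tr = generate_biexp_event(a, tau, rise_tau=0.05, dt=0.02, duration=2000.0)
        pk = int(np.argmax(tr.samples))
        ev = Event(onset=0.0, peak_time=pk * 0.02, amplitude=a, rise_10_90=0.1)
        q = event_charge(tr, ev, window=1990.0, polarity="outward")
        assert q == pytest.approx(a * tau, rel=0.02)

    def test_biexponential_charge_closed_form(self):
        a1, t1, a2, t2 = 31.5, 31.9, 15.1, 152.0
        tr = generate_biexp_event(a1, t1, a2, t2, rise_tau=0.05, dt=0.02,
                                  duration=4000.0)
        pk = int(np.argmax(tr.samples))
        ev = Event(onset=0.0, peak_time=pk * 0.02, amplitude=a1 + a2, rise_10_90=0.1)
        q = event_charge(tr, ev, window=3990.0, polarity="outward")
        assert q == pytest.approx(a1 * t1 + a2 * t2, rel=0.02)

    def test_zero_amplitude_region_zero_charge(self):
        tr = Trace(np.zeros(10_000), dt=0.1)
        ev = Event(onset=100.0, peak_time=101.0, amplitude=1.0, rise_10_90=0.5)
        assert event_charge(tr, ev, window=500.0, polarity="outward") == pytest.approx(0.0)
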