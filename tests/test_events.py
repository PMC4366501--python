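"""Event detection, response classification, SNR, bursts and latencies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pfclust import (
    DetectionParams,
    SimulationConfig,
    Trace,
    classify_responses,
    compute_dff,
    compute_snr,
    decompose_burst,
    detect_events,
    highpass_detrend,
    latency_distribution,
    simulate_traces,
)
from pfclust.synthetic import GroundTruth, simulate_spike_times


def _clean_cfg(**kw):
    defaults = dict(seed=0, event_amplitude_dff=(0.5, 0.0), noise_sd_dff=0.07)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def _trace_with_events(times, seed=0, duration=60.0, **cfg_kw):
    cfg = _clean_cfg(**cfg_kw)
    truth = GroundTruth(spike_times=[np.asarray(times, dtype=float)])
    return (
        simulate_traces(cfg, truth, duration, rng=np.random.default_rng(seed))[0],
        cfg,
    )


class TestDff:
    def test_constant_trace_maps_to_zero(self):
        tr = Trace(np.full(200, 40.0), 32.0, units="raw")
        out = compute_dff(tr)
        assert out.units == "dff"
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_doubling_gives_unity(self):
        x = np.full(400, 10.0)
        x[200] = 20.0
        out = compute_dff(Trace(x, 32.0, units="raw"))
        assert out.samples[200] == pytest.approx(1.0)

    def test_nonpositive_baseline_named(self):
        x = np.zeros(200)
        with pytest.raises(ValueError, match="t="):
            compute_dff(Trace(x, 32.0, units="raw"))

    def test_round_trip_from_generator(self):
        """Raw = F0·(1+ΔF/F) converts back to the generator's ΔF/F."""
        tr, _ = _trace_with_events([10.0, 30.0], noise_sd_dff=0.01)
        f0 = 100.0
        raw = Trace(f0 * (1.0 + tr.samples), tr.sampling_rate, units="raw")
        rec = compute_dff(raw)
        peak = int(10.0 * 32)
        assert rec.samples[peak] == pytest.approx(tr.samples[peak], abs=0.05)


class TestHighpass:
    def test_dc_removed(self):
        tr = Trace(np.full(3200, 3.3), 32.0)
        out = highpass_detrend(tr, 0.5)
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-9)
        assert abs(out.samples.mean()) < 1e-12

    def test_fast_transient_survives_slow_drift_removal(self):
        fs, n = 32.0, 6400
        t = np.arange(n) / fs
        slow = 0.5 * np.sin(2 * np.pi * 0.01 * t)
        transient = np.where(t >= 50.0, 0.8 * np.exp(-(t - 50.0) / 0.4), 0.0)
        out = highpass_detrend(Trace(slow + transient, fs), 0.05)
        peak = int(50.0 * fs)
        assert out.samples[peak] == pytest.approx(0.8, rel=0.05)

    def test_white_noise_variance_reduced_by_band_share(self, rng):
        fs, n = 100.0, 20_000
        x = rng.normal(0, 1, n)
        cutoff = 10.0
        out = highpass_detrend(Trace(x, fs), cutoff)
        # Parseval: removed variance share = removed bins / total bins
        share = 1.0 - cutoff / (fs / 2)
        assert out.samples.var() / x.var() == pytest.approx(share, rel=0.05)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            highpass_detrend(Trace(np.zeros(100), 32.0), 16.0)


class TestDetection:
    def test_flat_trace_no_events(self):
        ev = detect_events(Trace(np.zeros(640), 32.0))
        assert len(ev) == 0

    def test_five_transients_recovered_with_onset_accuracy(self):
        """At SNR ≈ 7 every transient is found within one frame of truth."""
        true_t = np.array([5.0, 15.0, 25.0, 35.0, 45.0])
        tr, _ = _trace_with_events(true_t, seed=3)
        ev = detect_events(tr)
        assert len(ev) == 5
        for t_true, t_det in zip(true_t, ev.onset_times):
            assert abs(t_det - t_true) <= 1.0 / 32 + 1e-9

    def test_subthreshold_excursion_ignored(self):
        """A 1.9 s.d. bump does not clear the two-standard-deviation rule."""
        rng = np.random.default_rng(8)
        noise_sd = 0.07
        x = rng.normal(0, noise_sd, 960)
        i0 = 480
        decay = 1.9 * noise_sd * np.exp(-np.arange(100) / (0.4 * 32))
        x[i0 : i0 + 100] += decay
        ev = detect_events(Trace(x, 32.0))
        assert np.all(np.abs(ev.onset_times - i0 / 32.0) > 0.5)

    def test_translation_equivariance(self):
        """Shifting a trace in time shifts every onset by the same amount."""
        true_t = np.array([10.0, 20.0, 40.0])
        tr, cfg = _trace_with_events(true_t, seed=5)
        shift_s = 4.0
        k = int(shift_s * tr.sampling_rate)
        shifted = Trace(np.roll(tr.samples, k), tr.sampling_rate)
        ev0 = detect_events(tr)
        ev1 = detect_events(shifted)
        assert len(ev0) == len(ev1) == 3
        np.testing.assert_allclose(ev1.onset_times, ev0.onset_times + shift_s, atol=1.5 / 32)

    def test_amplitude_scale_invariance(self):
        """Scaling signal and noise together leaves detections and SNR fixed."""
        tr, _ = _trace_with_events([12.0, 30.0, 50.0], seed=6)
        ev0 = detect_events(tr)
        ev1 = detect_events(Trace(tr.samples * 7.3, tr.sampling_rate))
        np.testing.assert_array_equal(ev0.onset_times, ev1.onset_times)
        np.testing.assert_allclose(ev0.snr, ev1.snr, rtol=1e-9)

    def test_noise_false_positive_rate_bounded(self):
        """FP rate on pure noise stays below the Gaussian run expectation.

        An event needs d=3 consecutive samples above 2σ; per sample that
        has probability Φ(−2)³ ≈ 1.2e-5, i.e. ≲0.023 events per 60 s at
        32 Hz. Allow the hysteresis extension a generous factor.
        """
        fp = 0
        n_traces = 100
        for k in range(n_traces):
            x = np.random.default_rng(1000 + k).normal(0, 0.07, 1920)
            fp += len(detect_events(Trace(x, 32.0)))
        analytic = 1920 * 0.0228**3
        assert fp / n_traces <= max(5 * analytic, 0.1)


class TestResponses:
    def test_no_events_means_nonresponder(self):
        tr = Trace(
            np.zeros(640), 32.0, stimulus_times=np.array([5.0, 10.0, 15.0])
        )
        rc = classify_responses(tr)
        assert not rc.per_trial.any()
        assert not rc.is_responder

    def test_event_outside_window_excluded(self):
        """An event 400 ms after the stimulus misses a 200 ms window."""
        tr, _ = _trace_with_events([5.4], duration=20.0, seed=2)
        tr = Trace(tr.samples, tr.sampling_rate, stimulus_times=np.array([5.0]))
        rc = classify_responses(tr)
        assert not rc.per_trial[0]

    def test_overlapping_windows_rejected(self):
        tr = Trace(np.zeros(640), 32.0, stimulus_times=np.array([5.0, 5.1]))
        with pytest.raises(ValueError, match="window"):
            classify_responses(tr)

    def test_per_trial_accuracy_against_ground_truth(self):
        """≥95% per-trial accuracy at p=0.5, SNR ≈ 7–8."""
        cfg = SimulationConfig(
            seed=9, p_response=0.5, frac_spontaneously_active=0.0
        )
        correct = total = 0
        for k in range(10):
            rng = np.random.default_rng(4000 + k)
            stims = 2.0 + np.arange(40) * 2.0
            resp = rng.random((1, 40)) < 0.5
            gt = simulate_spike_times(
                cfg, 84.0, 1, responses=resp, stimulus_times=stims, rng=rng
            )
            tr = simulate_traces(cfg, gt, 84.0, stimulus_times=stims, rng=rng)[0]
            rc = classify_responses(tr)
            correct += int(np.sum(rc.per_trial == resp[0]))
            total += 40
            assert rc.is_responder
        assert correct / total >= 0.95


class TestSnr:
    def test_single_event_ratio(self):
        from pfclust import EventList

        ev = EventList(np.array([1.0]), np.array([0.5]), np.array([5.0]), 0.1)
        out = compute_snr([ev])
        assert out["per_event_snr"][0] == pytest.approx(5.0)

    def test_equal_amplitudes_normalise_to_one(self):
        from pfclust import EventList

        ev = EventList(
            np.array([1.0, 2.0, 3.0]),
            np.array([0.4, 0.4, 0.4]),
            np.array([4.0, 4.0, 4.0]),
            0.1,
        )
        np.testing.assert_allclose(compute_snr([ev])["normalized_amplitudes"], 1.0)

    def test_zero_baseline_rms_rejected(self):
        from pfclust import EventList

        ev = EventList(np.array([1.0]), np.array([0.5]), np.array([5.0]), 0.0)
        with pytest.raises(ValueError, match="noiseless"):
            compute_snr([ev])

    def test_pooled_snr_in_reported_regime(self):
        """Generator defaults land the pooled mean SNR in the 6–9 band."""
        cfg = SimulationConfig(
            seed=13, frac_spontaneously_active=1.0, spontaneous_rate_hz=0.2
        )
        evs = []
        for k in range(20):
            rng = np.random.default_rng(3000 + k)
            gt = simulate_spike_times(cfg, 120.0, 1, rng=rng)
            tr = simulate_traces(cfg, gt, 120.0, rng=rng)[0]
            evs.append(detect_events(tr))
        assert 6.0 <= compute_snr(evs)["mean_snr"] <= 9.0


class TestBursts:
    def test_single_step(self):
        tr, _ = _trace_with_events(
            [0.5], duration=1.0, frame_rate_hz=1000.0, noise_sd_dff=0.02
        )
        bs = decompose_burst(tr, 0.49)
        assert bs.n_events_in_rise == 1
        assert bs.max_intraburst_freq_hz is None

    def test_three_steps_at_six_ms(self):
        tr, _ = _trace_with_events(
            [0.5, 0.506, 0.512],
            duration=1.0,
            frame_rate_hz=1000.0,
            noise_sd_dff=0.02,
        )
        bs = decompose_burst(tr, 0.499)
        assert bs.n_events_in_rise == 3
        assert bs.max_intraburst_freq_hz == pytest.approx(1000 / 6, rel=0.02)

    def test_framescan_rate_rejected(self):
        tr = Trace(np.zeros(640), 32.0)
        with pytest.raises(ValueError, match="500"):
            decompose_burst(tr, 1.0)

    def test_generator_burst_sizes_recovered(self):
        """Step counting matches the generating burst size in ≥90% of trials."""
        cfg = SimulationConfig(
            seed=2,
            frame_rate_hz=1000.0,
            noise_sd_dff=0.0625,
            event_amplitude_dff=(0.5, 0.0),
            burst_size_dist=((2, 0.5), (3, 0.5)),
            frac_spontaneously_active=0.0,
        )
        rng = np.random.default_rng(42)
        exact = 0
        n = 100
        for _ in range(n):
            gt = simulate_spike_times(
                cfg,
                1.0,
                1,
                responses=np.ones((1, 1), dtype=bool),
                stimulus_times=np.array([0.3]),
                rng=rng,
            )
            tr = simulate_traces(cfg, gt, 1.0, rng=rng)[0]
            bs = decompose_burst(tr, 0.3)
            exact += bs.n_events_in_rise == len(gt.spike_times[0])
        assert exact / n >= 0.9


class TestLatencies:
    def test_identical_latencies_single_bin(self):
        fit = latency_distribution(np.full(20, 10.0))
        assert np.count_nonzero(fit.counts) == 1

    def test_bimodal_mixture_recovered(self):
        """EM recovers the 10/22 ms peaks within 2 ms from 200 latencies."""
        from pfclust.synthetic import _draw_latency

        cfg = SimulationConfig(seed=5)
        rng = np.random.default_rng(5)
        lat = np.array([_draw_latency(cfg, rng) for _ in range(200)]) * 1000
        fit = latency_distribution(lat)
        assert fit.bimodal
        assert fit.component_means_ms[0] == pytest.approx(10.0, abs=2.0)
        assert fit.component_means_ms[1] == pytest.approx(22.0, abs=2.0)

    def test_unimodal_input_flagged(self):
        rng = np.random.default_rng(6)
        lat = rng.normal(15.0, 3.0, 300)
        fit = latency_distribution(lat)
        assert not fit.bimodal


@settings(deadline=None, max_examples=20, derandomize=True)
@given(
    shift=st.integers(min_value=1, max_value=60),
    scale=st.floats(min_value=0.2, max_value=8.0),
)
def test_detection_equivariance_properties(shift, scale):
    """Time shifts move onsets; joint amplitude scaling changes nothing."""
    tr, _ = _trace_with_events([12.0, 33.0], seed=21)
    base = detect_events(tr)
    rolled = detect_events(Trace(np.roll(tr.samples, shift), tr.sampling_rate))
    scaled = detect_events(Trace(tr.samples * scale, tr.sampling_rate))
    assert len(rolled) == len(base)
    np.testing.assert_allclose(
        rolled.onset_times, base.onset_times + shift / tr.sampling_rate, atol=2 / 32
    )
    np.testing.assert_array_equal(scaled.onset_times, base.onset_times)
    np.testing.assert_allclose(scaled.snr, base.snr, rtol=1e-9)
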