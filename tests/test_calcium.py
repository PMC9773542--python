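"""Calcium-transient kinetics against closed-form and programmed truth."""

import numpy as np
import pytest
from dataclasses import replace

from ccopheno.calcium import (
    TransientConfig,
    analyze_trace,
    detect_transients,
    estimate_baseline,
    summarize_transients,
    transient_metrics,
)
from ccopheno.io import CalciumTrace
from ccopheno.synth import CalciumSimParams, make_calcium_trace


def _exp_decay_trace(tau=0.5, baseline=100.0, amp=50.0, dt=0.002, duration=6.0):
    """Instantaneous upstroke at t=1 s, then pure exponential decay."""
    t = np.arange(0, duration, dt)
    f = np.full_like(t, baseline)
    post = t >= 1.0
    f[post] += amp * np.exp(-(t[post] - 1.0) / tau)
    return CalciumTrace(t, f)


def _triangle_trace(base=1.0, baseline=10.0, amp=20.0, dt=0.001):
    """Symmetric triangular transient of total base width 1 s, peak at 1.5 s."""
    t = np.arange(0, 3.0, dt)
    f = np.full_like(t, baseline)
    f += amp * np.clip(1 - np.abs(t - 1.5) / (base / 2), 0, None)
    return CalciumTrace(t, f)


class TestBaseline:
    def test_flat_trace_baseline_is_constant(self):
        trace = CalciumTrace(np.arange(0, 10, 0.02), np.full(500, 100.0))
        np.testing.assert_allclose(estimate_baseline(trace), 100.0)

    def test_tracks_linear_drift_with_sparse_transients(self):
        params = CalciumSimParams(drift_slope=2.0, noise_sd=0.0,
                                  beat_interval_mean=4.0, beat_interval_sd=0.0,
                                  duration=40.0)
        trace, _ = make_calcium_trace(params)
        baseline = estimate_baseline(trace, window_s=8.0)
        # central slope of the estimated baseline within 10 % of programmed
        sel = (trace.time > 5) & (trace.time < 35)
        slope = np.polyfit(trace.time[sel], baseline[sel], 1)[0]
        assert slope == pytest.approx(2.0, rel=0.10)

    def test_window_longer_than_trace_falls_back_with_warning(self):
        trace = CalciumTrace(np.arange(0, 2, 0.02), np.linspace(90, 110, 100))
        with pytest.warns(UserWarning, match="global percentile"):
            baseline = estimate_baseline(trace, window_s=100.0)
        assert np.all(baseline == baseline[0])


class TestDetectTransients:
    def test_flat_trace_gives_no_peaks(self):
        trace = CalciumTrace(np.arange(0, 10, 0.02), np.full(500, 100.0))
        baseline = estimate_baseline(trace)
        assert detect_transients(trace, baseline).size == 0

    def test_programmed_train_count_recovered(self):
        params = CalciumSimParams(beat_interval_mean=0.8, beat_interval_sd=0.0,
                                  noise_sd=0.0, duration=30.0)
        trace, truth = make_calcium_trace(params)
        baseline = estimate_baseline(trace)
        peaks = detect_transients(trace, baseline)
        assert abs(peaks.size - truth.n_transients) <= 1

    def test_close_peaks_merged_by_min_interval(self):
        t = np.arange(0, 2, 0.005)
        f = np.zeros_like(t)
        for c in (1.0, 1.05):  # two bumps 0.05 s apart
            f += np.exp(-((t - c) / 0.01) ** 2)
        trace = CalciumTrace(t, f + 100.0)
        peaks = detect_transients(trace, np.full_like(t, 100.0),
                                  TransientConfig(min_interval_s=0.2))
        assert peaks.size == 1


class TestTransientMetrics:
    def test_exponential_decay_repol_closed_forms(self):
        tau = 0.5
        trace = _exp_decay_trace(tau=tau)
        baseline = np.full(len(trace), 100.0)
        peak = int(np.argmax(trace.fluorescence))
        ev = transient_metrics(trace, baseline, peak)
        dt = trace.frame_interval
        assert ev.repol30 == pytest.approx(tau * np.log(1 / 0.7), abs=dt)
        assert ev.repol60 == pytest.approx(tau * np.log(1 / 0.4), abs=dt)
        assert ev.repol90 == pytest.approx(tau * np.log(10), abs=dt)

    @pytest.mark.parametrize("tau", [0.1, 0.5, 1.0, 2.0])
    def test_closed_form_agreement_across_tau(self, tau):
        trace = _exp_decay_trace(tau=tau, duration=4 + 12 * tau)
        baseline = np.full(len(trace), 100.0)
        peak = int(np.argmax(trace.fluorescence))
        ev = transient_metrics(trace, baseline, peak)
        dt = trace.frame_interval
        for x, got in ((30, ev.repol30), (60, ev.repol60), (90, ev.repol90)):
            assert got == pytest.approx(tau * np.log(1 / (1 - x / 100)), abs=dt)

    def test_triangular_transient_linear_geometry(self):
        trace = _triangle_trace()
        baseline = np.full(len(trace), 10.0)
        peak = int(np.argmax(trace.fluorescence))
        cfg = TransientConfig(onset_frac=0.0, end_frac=0.0)
        ev = transient_metrics(trace, baseline, peak, cfg)
        assert ev.depolarization_duration == pytest.approx(0.5, abs=0.01)
        assert ev.ctd == pytest.approx(1.0, abs=0.01)
        assert ev.repol60 == pytest.approx(0.3, abs=0.01)

    def test_truncated_decay_flagged_missing(self):
        trace = _exp_decay_trace(tau=2.0, duration=1.5)  # ends mid-decay
        baseline = np.full(len(trace), 100.0)
        peak = int(np.argmax(trace.fluorescence))
        ev = transient_metrics(trace, baseline, peak)
        assert np.isnan(ev.repol90)
        assert np.isnan(ev.ctd)

    def test_repol_ordering_on_synthetic_fixture(self, default_calcium):
        trace, _ = default_calcium
        events, _ = analyze_trace(trace)
        for ev in events:
            vals = [v for v in (ev.repol30, ev.repol60, ev.repol90) if np.isfinite(v)]
            assert vals == sorted(vals)

    @pytest.mark.parametrize("c", [0.5, 3.0])
    def test_amplitude_scale_invariance(self, c):
        trace = _exp_decay_trace()
        baseline = np.full(len(trace), 100.0)
        scaled = CalciumTrace(trace.time, 100.0 + c * (trace.fluorescence - 100.0))
        peak = int(np.argmax(trace.fluorescence))
        e1 = transient_metrics(trace, baseline, peak)
        e2 = transient_metrics(scaled, baseline, peak)
        for name in ("ctd", "repol30", "repol60", "repol90",
                     "depolarization_duration"):
            assert getattr(e2, name) == pytest.approx(getattr(e1, name), abs=1e-9)
        assert e2.peak_intensity == pytest.approx(c * e1.peak_intensity, rel=1e-9)
        assert e2.depolarization_speed == pytest.approx(c * e1.depolarization_speed, rel=1e-9)

    def test_noisy_isolated_transient_within_10pct_of_truth(self):
        # one well separated transient per 5 s, noise at 5 % of amplitude
        errs = {k: [] for k in ("ctd", "repol30", "repol60", "repol90",
                                "depolarization_duration", "peak_intensity")}
        for seed in range(5):
            params = CalciumSimParams(beat_interval_mean=5.0, beat_interval_sd=0.0,
                                      noise_sd=4.0, duration=30.0, seed=seed)
            trace, truth = make_calcium_trace(params)
            events, _ = analyze_trace(trace, TransientConfig(window_s=None))
            truth_map = {
                "ctd": truth.transient_duration,
                "repol30": truth.repol30,
                "repol60": truth.repol60,
                "repol90": truth.repol90,
                "depolarization_duration": truth.depolarization_duration,
                "peak_intensity": truth.amplitude,
            }
            for name, tv in truth_map.items():
                vals = np.asarray([getattr(e, name) for e in events], dtype=float)
                vals = vals[np.isfinite(vals)]
                errs[name].append(abs(vals.mean() - tv) / tv)
        for name, es in errs.items():
            assert np.mean(es) < 0.10, f"{name}: {es}"


class TestSummaries:
    def test_single_event_summary_equals_event(self, default_calcium):
        trace, _ = default_calcium
        events, _ = analyze_trace(trace)
        summary = summarize_transients(events[:1])
        assert summary.n_transients == 1
        assert summary.ctd_m == pytest.approx(events[0].ctd)

    def test_mean_of_two_ctds(self):
        from ccopheno.calcium import TransientEvent

        def ev(ctd):
            return TransientEvent(0, 0.1, 0.1 + ctd, 1.0, 0.1, 10.0, ctd,
                                  0.01, 0.02, 0.03)

        summary = summarize_transients([ev(0.4), ev(0.6)])
        assert summary.ctd_m == pytest.approx(0.5)

    def test_zero_events_summary_undefined(self):
        summary = summarize_transients([])
        assert summary.n_transients == 0
        assert np.isnan(summary.ctd_m)

    def test_programmed_beat_to_beat_recovered(self, default_calcium):
        trace, truth = default_calcium
        _, summary = analyze_trace(trace, TransientConfig(window_s=None))
        assert summary.beat_to_beat_m == pytest.approx(truth.interval_mean, rel=0.02)

    def test_treated_group_ordering_in_calcium_cohort(self):
        from ccopheno.synth import make_calcium_cohort

        records, _ = make_calcium_cohort({"control": 1.0, "treated": 1.6},
                                         n_per_group=4, seed=2)
        means = {}
        for grp in ("control", "treated"):
            vals = []
            for rec in records:
                if rec["group"] != grp:
                    continue
                _, summary = analyze_trace(rec["trace"])
                vals.append(summary.beat_to_beat_m)
            means[grp] = np.mean(vals)
        assert means["treated"] < means["control"]  # faster rhythm, shorter b2b
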