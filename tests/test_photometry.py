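"""ΔF/F normalization, isosbestic subtraction, peak detection, linking, and
peri-event quantification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.ndimage import gaussian_filter1d

from photoperant import FormatError, PhotometryGenConfig, TaskConfig, AgentConfig
from photoperant import events as ev
from photoperant import photometry as ph
from photoperant import simulate as sim
from photoperant.core import NormalizedTrace, Trial
from photoperant.core import make_event_frame


def rolling_mean_oracle(f, n_win):
    """Independent nested-loop centered rolling mean with edge shrinkage."""
    n = len(f)
    half = (n_win - 1) // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        acc = 0.0
        for j in range(lo, hi):
            acc += f[j]
        out[i] = acc / (hi - lo)
    return out


def peak_scan_oracle(x, thr, times):
    """Independent scan: walk the trace, track each contiguous excursion
    above thr, record its maximum."""
    peaks = []
    in_exc, best, best_t = False, -np.inf, None
    for v, t in zip(x, times):
        if v > thr:
            if not in_exc:
                in_exc, best, best_t = True, v, t
            elif v > best:
                best, best_t = v, t
        elif in_exc:
            peaks.append((best_t, best))
            in_exc = False
    if in_exc:
        peaks.append((best_t, best))
    return peaks


def make_trace(dff, fs=100.0):
    dff = np.asarray(dff, dtype=float)
    return NormalizedTrace(time_s=np.arange(len(dff)) / fs, dff=dff,
                           sample_rate_hz=fs, session_sd=float(np.std(dff)))


class TestNormalizeDff:
    def test_constant_trace_is_zero(self):
        out = ph.normalize_dff(np.full(500, 7.3), 100.0, window_s=1.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-14)

    def test_small_multiplicative_modulation_recovered(self):
        # F = B (1 + eps) on a slow baseline: output ~ eps to first order
        fs, eps = 100.0, 1e-4
        f = 50.0 * (1.0 + eps * np.sin(2 * np.pi * 5 * np.arange(3000) / fs))
        out = ph.normalize_dff(f, fs, window_s=2.0)
        assert np.max(np.abs(out)) == pytest.approx(eps, rel=0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_nested_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        f = rng.uniform(1.0, 10.0, n)
        fs = 1.0
        window_s = float(rng.integers(3, 9))
        n_win = int(round(window_s * fs))
        if n_win % 2 == 0:
            n_win += 1
        b = rolling_mean_oracle(f, n_win)
        expected = (f - b) / b
        got = ph.normalize_dff(f, fs, window_s=window_s)
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    @given(st.lists(st.floats(0.5, 100.0), min_size=4, max_size=40),
           st.integers(1, 4))
    def test_scaling_invariance(self, values, scale):
        """Ratio normalization is invariant to a positive gain on raw F."""
        f = np.asarray(values)
        a = ph.normalize_dff(f, 1.0, window_s=3.0)
        b = ph.normalize_dff(scale * f, 1.0, window_s=3.0)
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-12)

    def test_nonpositive_baseline_rejected(self):
        f = np.array([1.0, -5.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            ph.normalize_dff(f, 1.0, window_s=3.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ph.normalize_dff(np.array([1.0]), 1.0)


class TestIsosbesticSubtract:
    def test_zero_isosbestic_is_identity(self):
        d465 = np.sin(np.linspace(0, 10, 200))
        out = ph.isosbestic_subtract(d465, np.zeros(200), sample_rate_hz=20.0)
        np.testing.assert_array_equal(out.dff, d465)

    @given(st.floats(-0.5, 0.5))
    def test_common_component_cancels(self, c):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 0.1, 100), rng.normal(0, 0.1, 100)
        base = ph.isosbestic_subtract(a, b, sample_rate_hz=10.0).dff
        shifted = ph.isosbestic_subtract(a + c, b + c, sample_rate_hz=10.0).dff
        np.testing.assert_allclose(shifted, base, atol=1e-12)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ph.isosbestic_subtract(np.zeros(10), np.zeros(11))

    def test_fitted_gain_removes_scaled_artifact(self):
        rng = np.random.default_rng(1)
        art = rng.normal(0, 0.05, 2000)
        d465, d405 = art.copy(), 0.5 * art
        out = ph.isosbestic_subtract(d465, d405, sample_rate_hz=100.0,
                                     fit_gain=True)
        assert np.var(out.dff) < 1e-3 * np.var(art)
        assert out.provenance["gain_405"] == pytest.approx(2.0)


class TestReadPhotometry:
    def test_single_sample_rejected(self, tmp_path):
        p = tmp_path / "one.csv"
        p.write_text("# sync_offset_s=0\ntime_s,F405,F465\n0.0,1.0,2.0\n")
        with pytest.raises(FormatError):
            ph.read_photometry(str(p))

    def test_missing_channel_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("time_s,F465\n0.0,2.0\n0.01,2.0\n")
        with pytest.raises(FormatError):
            ph.read_photometry(str(p))

    def test_small_jitter_accepted_with_note(self, tmp_path):
        t = np.arange(100) * 0.01
        t[50] += 5e-5  # 0.5% of the sampling interval
        df = pd.DataFrame({"time_s": t, "F405": 1.0, "F465": 2.0})
        p = tmp_path / "jit.csv"
        df.to_csv(p, index=False)
        rec = ph.read_photometry(str(p))
        assert any("jitter" in w for w in rec.provenance)

    def test_large_jitter_rejected(self, tmp_path):
        t = np.arange(100) * 0.01
        t[50] += 0.004
        df = pd.DataFrame({"time_s": t, "F405": 1.0, "F465": 2.0})
        p = tmp_path / "jit.csv"
        df.to_csv(p, index=False)
        with pytest.raises(FormatError):
            ph.read_photometry(str(p))

    def test_sync_offset_applied_at_load(self, tmp_path):
        p = tmp_path / "off.csv"
        p.write_text("# sync_offset_s=2.5\n# sample_rate_hz=100\n"
                     "time_s,F405,F465\n0.0,1.0,2.0\n0.01,1.0,2.0\n")
        rec = ph.read_photometry(str(p))
        assert rec.time_s[0] == pytest.approx(2.5)


class TestDetectPeaks:
    def test_single_bump_found_at_apex(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 0.01, 5000)
        bump = 5 * np.std(noise) * np.exp(-0.5 * ((np.arange(5000) - 2500) / 30) ** 2)
        trace = make_trace(noise * 0 + bump + noise * 0)  # noise-free bump
        trace.session_sd = float(np.std(noise))
        peaks = ph.detect_peaks(trace, smooth_sigma_s=0.0)
        assert len(peaks) == 1
        assert peaks["time_s"].iloc[0] == pytest.approx(25.0, abs=0.02)

    def test_constant_trace_yields_no_peaks(self):
        peaks = ph.detect_peaks(make_trace(np.zeros(100)))
        assert len(peaks) == 0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        trace = make_trace(rng.normal(0, 1, 3000))
        counts = [len(ph.detect_peaks(trace, threshold_sd=k, smooth_sigma_s=0.0))
                  for k in (1.0, 1.5, 2.0, 2.5, 3.0)]
        assert counts == sorted(counts, reverse=True)

    @pytest.mark.parametrize("seed", [0, 7])
    def test_matches_bruteforce_excursion_scan(self, seed):
        """Peak set equals an independent walk over the same (smoothed)
        realization."""
        rng = np.random.default_rng(seed)
        trace = make_trace(rng.normal(0, 1, 4000))
        sigma_s = 0.05
        peaks = ph.detect_peaks(trace, threshold_sd=2.0, smooth_sigma_s=sigma_s)
        sm = gaussian_filter1d(trace.dff, sigma_s * trace.sample_rate_hz)
        oracle = peak_scan_oracle(sm, 2.0 * trace.session_sd, trace.time_s)
        assert len(peaks) == len(oracle)
        for (t, a), (_, row) in zip(oracle, peaks.iterrows()):
            assert row["time_s"] == pytest.approx(t)
            assert row["amplitude"] == pytest.approx(a)

    def test_smoothing_rejects_sample_noise_but_keeps_transients(self):
        """With the default matched-timescale denoising, a white-noise trace
        produces no events while a transient-bearing trace does."""
        rng = np.random.default_rng(5)
        noise = rng.normal(0, 0.004, 20000)
        assert len(ph.detect_peaks(make_trace(noise))) == 0
        k = sim.transient_kernel(np.arange(0, 8, 0.01), 0.1, 0.8)
        with_tr = noise.copy()
        with_tr[5000:5000 + len(k)] += 0.08 * k
        assert len(ph.detect_peaks(make_trace(with_tr))) == 1


class TestLinking:
    @staticmethod
    def anchors(rows):
        return pd.DataFrame(rows, columns=["time_s", "kind"])

    def test_peak_shortly_after_press_links(self):
        peaks = pd.DataFrame({"time_s": [10.3], "amplitude": [0.1]})
        out = ph.link_peaks_to_behavior(
            peaks, self.anchors([(10.0, "lever_press")]), 2.0)
        assert out["linked_event"].iloc[0] == "lever_press"
        assert out["lag_s"].iloc[0] == pytest.approx(0.3)

    def test_peak_without_candidate_stays_unlinked(self):
        peaks = pd.DataFrame({"time_s": [50.0], "amplitude": [0.1]})
        out = ph.link_peaks_to_behavior(
            peaks, self.anchors([(10.0, "lever_press")]), 2.0)
        assert out["linked_event"].iloc[0] is None

    def test_each_anchor_claims_at_most_one_peak(self):
        peaks = pd.DataFrame({"time_s": [10.2, 10.4], "amplitude": [0.1, 0.2]})
        out = ph.link_peaks_to_behavior(
            peaks, self.anchors([(10.0, "lever_press")]), 2.0)
        assert (out["linked_event"] == "lever_press").sum() == 1
        # the nearer peak wins
        assert out.loc[out["time_s"] == 10.2, "linked_event"].iloc[0] == "lever_press"

    def test_equidistant_candidates_resolve_to_earlier_anchor(self):
        peaks = pd.DataFrame({"time_s": [11.0], "amplitude": [0.1]})
        out = ph.link_peaks_to_behavior(
            peaks, self.anchors([(10.5, "lever_press"), (10.5, "lick_bout_onset")]),
            2.0)
        assert out["linked_time_s"].iloc[0] == pytest.approx(10.5)
        assert out["linked_event"].iloc[0] == "lever_press"

    def test_noise_free_recovery_is_complete(self):
        """Without noise or artifacts every ground-truth transient is detected
        and attributed to its generating behavioral event. The agent separates
        press and consumption by ~3 s so neighbouring transients decay below
        threshold between events (excursion-based detection reports merged
        excursions as one event by design)."""
        task = TaskConfig(phase="II")
        agent = AgentConfig(press_to_lick_init_s=3.0,
                            press_to_lick_asymptote_s=3.0,
                            latency_cv=0.1, extra_press_prob=0.0)
        log, truth = sim.run_task_state_machine(
            task, agent, day=5, rng=np.random.default_rng(23))
        cfg = PhotometryGenConfig(noise_sd=0.0, artifact_rate_hz=0.0)
        rec, truth = sim.generate_photometry(log, truth, cfg,
                                             rng=np.random.default_rng(24))
        trace = ph.process_recording(rec)
        peaks = ph.detect_peaks(trace)
        linked = ph.link_peaks_to_behavior(peaks, ph.behavior_anchors(log))
        hits = {(r.linked_event, round(r.linked_time_s, 4))
                for r in linked.dropna(subset=["linked_event"]).itertuples()}
        for tr in truth.transients.itertuples():
            assert (tr.linked_behavior, round(tr.time_s, 4)) in hits


class TestPeriEvent:
    @staticmethod
    def tone_trial(i, t0, outcome="rewarded"):
        return Trial(trial_idx=i, phase="I", start_time_s=t0, end_time_s=t0 + 20,
                     cue_window=(t0, t0 + 5),
                     events=make_event_frame([(t0, "tone_on", np.nan)]),
                     outcome=outcome)

    def test_identical_trials_mean_equals_each_row(self):
        fs = 100.0
        t = np.arange(0, 60, 1 / fs)
        dff = np.tile(np.sin(2 * np.pi * np.arange(fs * 20) / fs / 5.0), 3)
        trace = NormalizedTrace(t, dff, fs, float(np.std(dff)))
        trials = [self.tone_trial(0, 5.0), self.tone_trial(1, 25.0)]
        pem = ph.build_peri_event_matrix(trace, trials, "tone_on", 2.0, 8.0)
        assert pem.matrix.shape == (2, 1000)
        np.testing.assert_allclose(pem.matrix[0], pem.matrix[1], atol=1e-12)
        mean, _, n = pem.group_mean()
        assert n == 2
        np.testing.assert_allclose(mean, pem.matrix[0], atol=1e-12)

    def test_no_qualifying_trials_gives_explicit_empty_shape(self):
        trace = make_trace(np.zeros(1000))
        trials = [self.tone_trial(0, 5.0)]
        pem = ph.build_peri_event_matrix(trace, trials, "lever_press", 2.0, 8.0)
        assert pem.matrix.shape == (0, 1000)

    def test_clipped_windows_flagged_not_silently_padded(self):
        trace = make_trace(np.zeros(500))  # 5 s at 100 Hz
        trials = [self.tone_trial(0, 1.0), self.tone_trial(1, 3.0)]
        pem = ph.build_peri_event_matrix(trace, trials, "tone_on", 2.0, 3.0)
        assert not pem.complete[0]          # needs data before t=-1
        assert not pem.complete[1]          # needs data beyond the recording
        assert np.isnan(pem.matrix[0, 0])

    def test_window_amplitude_monotone_row(self):
        fs = 100.0
        dff = np.linspace(0, 1, 3000)
        trace = NormalizedTrace(np.arange(3000) / fs, dff, fs, 1.0)
        pem = ph.build_peri_event_matrix(trace, [self.tone_trial(0, 10.0)],
                                         "tone_on", 2.0, 8.0)
        wa = ph.window_peak_amplitude(pem, (0.0, 2.0))
        # last bin strictly inside [0, 2): t = 11.99 s
        assert wa["amplitude"].iloc[0] == pytest.approx(dff[1199])

    def test_window_amplitude_zero_row(self):
        trace = make_trace(np.zeros(3000))
        pem = ph.build_peri_event_matrix(trace, [self.tone_trial(0, 10.0)],
                                         "tone_on", 2.0, 8.0)
        wa = ph.window_peak_amplitude(pem, (0.0, 2.0))
        assert wa["amplitude"].iloc[0] == 0.0

    def test_window_outside_span_rejected(self):
        trace = make_trace(np.zeros(3000))
        pem = ph.build_peri_event_matrix(trace, [self.tone_trial(0, 10.0)],
                                         "tone_on", 2.0, 8.0)
        with pytest.raises(ValueError):
            ph.window_peak_amplitude(pem, (7.0, 12.0))

    def test_tone_alignment_of_no_transient_session_is_flat(self):
        """Anesthesia-like regime: the tone-aligned group mean shows no
        event-locked structure — nowhere near the peak-event criterion, and
        only a chance-level fraction of bins beyond 2 SEM."""
        task = TaskConfig(phase="I")
        log, truth = sim.run_task_state_machine(
            task, AgentConfig(), day=8, rng=np.random.default_rng(31),
            n_trials=10)
        cfg = PhotometryGenConfig(transient_amp_rewarded=0.0,
                                  transient_amp_nonrewarded=0.0,
                                  consumption_dip_amp=0.0)
        rec, _ = sim.generate_photometry(log, truth, cfg,
                                         rng=np.random.default_rng(32))
        trace = ph.process_recording(rec)
        trials = ev.segment_trials(log)
        pem = ph.build_peri_event_matrix(trace, trials, "tone_on", 2.0, 8.0)
        mean, sem, n = pem.group_mean()
        assert n >= 8
        assert np.nanmax(np.abs(mean)) < 2 * trace.session_sd
        assert np.mean(np.abs(mean) > 2 * sem) < 0.15


class TestAmplitudeTables:
    def test_single_peak_day_has_missing_sem(self):
        df = pd.DataFrame({"day": [1], "linked_event": ["lever_press"],
                           "amplitude": [0.42]})
        out = ph.peak_amplitude_by_day(df)
        assert out["mean"].iloc[0] == pytest.approx(0.42)
        assert np.isnan(out["sem"].iloc[0])

    def test_grouped_amplitude_by_outcome(self):
        df = pd.DataFrame({"trial_idx": range(4),
                           "outcome": ["rewarded", "rewarded",
                                       "non_rewarded", "non_rewarded"],
                           "amplitude": [0.3, 0.5, 0.1, 0.1]})
        out = ph.grouped_amplitude(df).set_index("outcome")
        assert out.loc["rewarded", "mean"] == pytest.approx(0.4)
        assert out.loc["non_rewarded", "mean"] == pytest.approx(0.1)

    def test_trend_requires_two_days(self):
        df = pd.DataFrame({"day": [1, 1], "linked_event": ["lever_press"] * 2,
                           "amplitude": [0.1, 0.2]})
        with pytest.raises(ValueError):
            ph.amplitude_day_trend(df)
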