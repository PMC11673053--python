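"""Two-channel photometry processing: ΔF/F normalization, isosbestic
subtraction, peak-event detection, behavioral linking, and peri-event
quantification.

Normalization is the ratio form (F - F0) / F0 with F0 a centered rolling
mean of the trace, so scaling the raw fluorescence by any positive constant
leaves ΔF/F unchanged. The 405 nm (isosbestic) ΔF/F is subtracted from the
465 nm ΔF/F to remove shared movement artifacts; peak events are contiguous
supra-threshold excursions of the result exceeding 2 session standard
deviations.
"""

from __future__ import annotations

import io
from typing import Optional

import numpy as np
import pandas as pd

from . import events as _events
from .core import EventLog, NormalizedTrace, PeriEventMatrix, PhotometryRecording, Trial
from .errors import FormatError

DEFAULT_WINDOW_S = 30.0
DEFAULT_THRESHOLD_SD = 2.0
DEFAULT_SMOOTH_SIGMA_S = 0.05
DEFAULT_ASSOCIATION_WINDOW_S = 2.0


def read_photometry(path: str) -> PhotometryRecording:
    """Read a photometry CSV (`time_s, F405, F465` plus `# key=value`
    metadata). The sync offset is applied to the time axis once, at load."""
    with open(path) as fh:
        raw = fh.read().splitlines()
    meta = _events._parse_meta([ln for ln in raw if ln.startswith("#")])
    body = "\n".join(ln for ln in raw if not ln.startswith("#"))
    df = pd.read_csv(io.StringIO(body), float_precision="round_trip")
    for col in ("time_s", "F405", "F465"):
        if col not in df.columns:
            raise FormatError(f"photometry file {path} is missing column {col!r}")
    if len(df) < 2:
        raise FormatError("recording too short to analyze (need >= 2 samples)")

    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    med = np.median(dt)
    if med <= 0:
        raise FormatError("non-increasing time axis")
    jitter = np.max(np.abs(dt - med)) / med
    provenance = []
    if jitter > 0.01:
        raise FormatError(f"sampling jitter {jitter:.3f} exceeds 1% of the "
                          "sampling interval")
    if jitter > 0:
        provenance.append(f"timestamp jitter up to {jitter:.2e} of the sampling "
                          "interval; accepted")
    fs = float(meta.get("sample_rate_hz", 1.0 / med))
    offset = float(meta.get("sync_offset_s", 0.0))
    return PhotometryRecording(
        time_s=t + offset, F405=df["F405"].to_numpy(dtype=float),
        F465=df["F465"].to_numpy(dtype=float), sample_rate_hz=fs,
        sync_offset_s=offset, mouse=meta.get("mouse", ""),
        phase=meta.get("phase", ""), day=int(meta.get("day", 0)),
        test=int(meta.get("test", 0)), provenance=provenance)


def rolling_baseline(f: np.ndarray, sample_rate_hz: float,
                     window_s: float = DEFAULT_WINDOW_S) -> np.ndarray:
    """Centered rolling mean with the window shrinking at the edges.

    The window length in samples is forced odd so the window is symmetric
    around each sample away from the edges.
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    n_win = int(round(window_s * sample_rate_hz))
    n_win = max(1, n_win)
    if n_win % 2 == 0:
        n_win += 1
    s = pd.Series(np.asarray(f, dtype=float))
    return s.rolling(window=n_win, center=True, min_periods=1).mean().to_numpy()


def normalize_dff(f: np.ndarray, sample_rate_hz: float,
                  window_s: float = DEFAULT_WINDOW_S) -> np.ndarray:
    """ΔF/F: (F - F0) / F0 with F0 the centered rolling mean of F."""
    f = np.asarray(f, dtype=float)
    if len(f) < 2:
        raise ValueError("trace too short to normalize")
    b = rolling_baseline(f, sample_rate_hz, window_s)
    if np.any(b <= 0):
        raise ValueError("rolling baseline is non-positive; raw fluorescence "
                         "must be positive")
    return (f - b) / b


def isosbestic_subtract(dff465: np.ndarray, dff405: np.ndarray,
                        time_s: Optional[np.ndarray] = None,
                        sample_rate_hz: float = 0.0,
                        fit_gain: bool = False,
                        provenance: Optional[dict] = None) -> NormalizedTrace:
    """Subtract the isosbestic ΔF/F from the calcium-dependent ΔF/F.

    With ``fit_gain`` the 405 channel is first scaled by its least-squares
    regression coefficient onto the 465 channel (common practice when channel
    gains are not matched); the default is unit-gain subtraction.
    """
    dff465 = np.asarray(dff465, dtype=float)
    dff405 = np.asarray(dff405, dtype=float)
    if dff465.shape != dff405.shape:
        raise ValueError("channel grids differ")
    gain = 1.0
    if fit_gain:
        denom = float(np.dot(dff405, dff405))
        gain = float(np.dot(dff405, dff465)) / denom if denom > 0 else 0.0
    dff = dff465 - gain * dff405
    if time_s is None:
        time_s = np.arange(len(dff)) / (sample_rate_hz or 1.0)
    prov = {"gain_405": gain, "fit_gain": fit_gain}
    if provenance:
        prov.update(provenance)
    return NormalizedTrace(time_s=np.asarray(time_s, dtype=float), dff=dff,
                           sample_rate_hz=sample_rate_hz or
                           float(1.0 / np.median(np.diff(time_s))),
                           session_sd=float(np.std(dff)), provenance=prov)


def process_recording(rec: PhotometryRecording,
                      window_s: float = DEFAULT_WINDOW_S,
                      fit_gain: bool = False) -> NormalizedTrace:
    """Normalize both channels and subtract 405 from 465."""
    d465 = normalize_dff(rec.F465, rec.sample_rate_hz, window_s)
    d405 = normalize_dff(rec.F405, rec.sample_rate_hz, window_s)
    return isosbestic_subtract(d465, d405, time_s=rec.time_s,
                               sample_rate_hz=rec.sample_rate_hz,
                               fit_gain=fit_gain,
                               provenance={"window_s": window_s})


def robust_sd(x: np.ndarray) -> float:
    """1.4826 x median absolute deviation, a robust SD estimate."""
    x = np.asarray(x, dtype=float)
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def detect_peaks(trace: NormalizedTrace,
                 threshold_sd: float = DEFAULT_THRESHOLD_SD,
                 smooth_sigma_s: float = DEFAULT_SMOOTH_SIGMA_S,
                 robust: bool = False) -> pd.DataFrame:
    """Calcium peak events: one per contiguous supra-threshold excursion.

    The trace is denoised with a short Gaussian kernel (sigma ~ half the
    transient rise time) before thresholding, so sample-to-sample noise does
    not register as events; the threshold itself is ``threshold_sd`` times
    the session SD of the *unsmoothed* subtracted trace (or its MAD-based
    robust counterpart). Returns a frame with columns time_s, amplitude.
    """
    sd = robust_sd(trace.dff) if robust else trace.session_sd
    thr = threshold_sd * sd
    sm = trace.smoothed(smooth_sigma_s).dff if smooth_sigma_s > 0 else trace.dff
    above = sm > thr
    times, amps = [], []
    if above.any() and thr > 0:
        edges = np.diff(above.astype(int))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1
        if above[0]:
            starts = np.r_[0, starts]
        if above[-1]:
            ends = np.r_[ends, len(above)]
        for s0, s1 in zip(starts, ends):
            k = s0 + int(np.argmax(sm[s0:s1]))
            times.append(trace.time_s[k])
            amps.append(sm[k])
    return pd.DataFrame({"time_s": times, "amplitude": amps})


def behavior_anchors(log: EventLog,
                     bout_gap_s: float = _events.DEFAULT_BOUT_GAP_S) -> pd.DataFrame:
    """Behavioral instances peaks can be attributed to: every lever press and
    every lick-bout onset."""
    rows = [(t, "lever_press") for t in log.times_of("lever_press")]
    rows += [(t, "lick_bout_onset")
             for t in _events.lick_bout_onsets(log.times_of("lick"), bout_gap_s)]
    df = pd.DataFrame(rows, columns=["time_s", "kind"])
    return df.sort_values("time_s", kind="mergesort").reset_index(drop=True)


def link_peaks_to_behavior(peaks: pd.DataFrame, anchors: pd.DataFrame,
                           association_window_s: float = DEFAULT_ASSOCIATION_WINDOW_S
                           ) -> pd.DataFrame:
    """Attribute peaks to behavioral events.

    A peak can link to an anchor event at time e if e <= peak < e + window;
    assignment is globally nearest-first (smallest lag wins) and one-to-one:
    each anchor claims at most one peak. Equidistant candidates resolve to
    the earlier anchor. Unlinked peaks are kept with a null link.
    """
    out = peaks.copy().reset_index(drop=True)
    out["linked_event"] = pd.Series([None] * len(out), dtype=object)
    out["linked_time_s"] = np.nan
    out["lag_s"] = np.nan
    if len(out) == 0 or len(anchors) == 0:
        return out
    cands = []
    for pi, pt in enumerate(out["time_s"].to_numpy()):
        for ai, (at, kind) in enumerate(zip(anchors["time_s"].to_numpy(),
                                            anchors["kind"].to_numpy())):
            lag = pt - at
            if 0 <= lag < association_window_s:
                cands.append((lag, at, pi, ai, kind))
    peak_used = set()
    anchor_used = set()
    for lag, at, pi, ai, kind in sorted(cands, key=lambda c: (c[0], c[1])):
        if pi in peak_used or ai in anchor_used:
            continue
        peak_used.add(pi)
        anchor_used.add(ai)
        out.loc[pi, "linked_event"] = kind
        out.loc[pi, "linked_time_s"] = at
        out.loc[pi, "lag_s"] = lag
    return out


def build_peri_event_matrix(trace: NormalizedTrace, trials: list[Trial],
                            align_on: str, pre_s: float = 2.0,
                            post_s: float = 8.0,
                            bout_gap_s: float = _events.DEFAULT_BOUT_GAP_S
                            ) -> PeriEventMatrix:
    """Trials x time matrix aligned to a per-trial event onset.

    ``align_on`` is one of 'trial_start' (= tone onset in the cued phases,
    opening press in the free-operant phase), 'tone_on', 'lever_press' (first
    press of the trial) or 'lick_bout_onset' (first bout onset of the trial).
    Trials lacking the event are skipped. Extraction is nearest-sample on the
    recording's own grid; rows whose window leaves the recording are kept but
    flagged incomplete and NaN-padded, never silently clipped.
    """
    fs = trace.sample_rate_hz
    n_bins = int(round((pre_s + post_s) * fs))
    rel = np.arange(n_bins) / fs - pre_s
    rows, outcomes, idxs, complete = [], [], [], []
    n = len(trace.dff)
    for tr in trials:
        t_align = _alignment_time(tr, align_on, bout_gap_s)
        if t_align is None:
            continue
        i0 = int(round((t_align - pre_s) * fs))
        row = np.full(n_bins, np.nan)
        lo, hi = max(i0, 0), min(i0 + n_bins, n)
        if hi > lo:
            row[lo - i0:hi - i0] = trace.dff[lo:hi]
        rows.append(row)
        outcomes.append(tr.outcome)
        idxs.append(tr.trial_idx)
        complete.append(i0 >= 0 and i0 + n_bins <= n)
    matrix = np.vstack(rows) if rows else np.empty((0, n_bins))
    return PeriEventMatrix(align_event=align_on, time_s=rel, matrix=matrix,
                           outcomes=outcomes, trial_idx=idxs,
                           complete=np.asarray(complete, dtype=bool),
                           sample_rate_hz=fs)


def _alignment_time(trial: Trial, align_on: str, bout_gap_s: float):
    if align_on in ("trial_start", "tone_on"):
        return trial.start_time_s
    if align_on == "lever_press":
        presses = trial.times_of("lever_press")
        return float(presses[0]) if presses.size else None
    if align_on == "lick_bout_onset":
        onsets = _events.lick_bout_onsets(trial.times_of("lick"), bout_gap_s)
        return float(onsets[0]) if onsets.size else None
    raise ValueError(f"unknown alignment event {align_on!r}")


def window_peak_amplitude(matrix: PeriEventMatrix,
                          window: tuple[float, float]) -> pd.DataFrame:
    """Per-trial maximum of the aligned trace within [t0, t1) relative to
    the alignment event (e.g. the first 2 s of the tone)."""
    t0, t1 = window
    dt = 1.0 / matrix.sample_rate_hz if matrix.sample_rate_hz else np.inf
    if t0 < matrix.time_s[0] - dt / 2 or t1 > matrix.time_s[-1] + dt:
        raise ValueError("window outside the peri-event span")
    sel = (matrix.time_s >= t0) & (matrix.time_s < t1)
    if not sel.any():
        raise ValueError("window contains no bins")
    rows = []
    for r in range(matrix.n_trials):
        seg = matrix.matrix[r, sel]
        amp = np.nan if np.all(np.isnan(seg)) else float(np.nanmax(seg))
        rows.append({"trial_idx": matrix.trial_idx[r],
                     "outcome": matrix.outcomes[r], "amplitude": amp})
    return pd.DataFrame(rows)


def grouped_amplitude(amplitudes: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SEM of per-trial amplitudes by outcome class."""
    g = amplitudes.groupby("outcome")["amplitude"]
    return pd.DataFrame({"mean": g.mean(), "sem": g.sem(ddof=1),
                         "n": g.count()}).reset_index()


def peak_amplitude_by_day(linked_peaks: pd.DataFrame) -> pd.DataFrame:
    """Tidy mean ± SEM of linked-peak amplitudes per (day, behavior kind).

    ``linked_peaks`` must carry 'day', 'linked_event' and 'amplitude'
    columns (unlinked peaks are ignored).
    """
    df = linked_peaks.dropna(subset=["linked_event"])
    g = df.groupby(["day", "linked_event"])["amplitude"]
    out = pd.DataFrame({"mean": g.mean(), "sem": g.sem(ddof=1), "n": g.count()})
    return out.reset_index()


def amplitude_day_trend(linked_peaks: pd.DataFrame, alpha: float = 0.05):
    """OLS slope of linked-peak amplitude against training day.

    Returns (slope, (ci_low, ci_high)); the interval containing zero is the
    no-trend regime.
    """
    import statsmodels.api as sm

    df = linked_peaks.dropna(subset=["linked_event", "amplitude"])
    if df["day"].nunique() < 2:
        raise ValueError("need at least two days to estimate a trend")
    X = sm.add_constant(df["day"].to_numpy(dtype=float))
    fit = sm.OLS(df["amplitude"].to_numpy(dtype=float), X).fit()
    lo, hi = fit.conf_int(alpha=alpha)[1]
    return float(fit.params[1]), (float(lo), float(hi))
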