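"""Behavioral event-log parsing, trial segmentation, outcome classification,
and the session-level behavior metrics.

Conventions: all windows are half-open [start, end) in seconds; a lick
exactly at tone offset is outside the cue. A "rewarded lick" is a lick whose
timestamp matches a reward_delivery within 1 ms — the rig logs them jointly —
rather than re-deriving spout state, which is robust to truncated logs.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .core import (EVENT_KINDS, REWARD_LICK_TOL_S, EventLog, Trial,
                   make_event_frame)
from .errors import FormatError

#: A lick starts a new bout if it is preceded by at least this long without
#: licking.
DEFAULT_BOUT_GAP_S = 1.0

_TIME_TOL_S = 1e-6


def _parse_meta(lines: list[str]) -> dict:
    meta = {}
    for ln in lines:
        body = ln.lstrip("#").strip()
        if "=" in body:
            k, v = body.split("=", 1)
            meta[k.strip()] = v.strip()
    return meta


def read_event_log(path: str) -> EventLog:
    """Read a tab-separated event log written by the simulator (or the rig).

    Malformed data lines are skipped and collected into ``log.warnings``;
    an unmatched tone_on at end-of-file is auto-closed at session end with a
    warning. Missing metadata or non-monotone timestamps raise FormatError.
    """
    with open(path) as fh:
        raw = fh.read().splitlines()
    meta_lines = [ln for ln in raw if ln.startswith("#")]
    meta = _parse_meta(meta_lines)
    for key in ("mouse", "phase", "day", "test"):
        if key not in meta:
            raise FormatError(f"event log {path} is missing metadata key {key!r}")

    warnings: list[str] = []
    records = []
    body = [ln for ln in raw if ln and not ln.startswith("#")]
    if body and body[0].split("\t")[0] != "time_s":
        raise FormatError(f"event log {path} lacks the time_s/event/value header")
    for i, ln in enumerate(body[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != 3:
            warnings.append(f"line {i}: expected 3 fields, got {len(parts)}")
            continue
        try:
            t = float(parts[0])
        except ValueError:
            warnings.append(f"line {i}: unparsable time {parts[0]!r}")
            continue
        kind = parts[1]
        if kind not in EVENT_KINDS:
            warnings.append(f"line {i}: unknown event kind {kind!r}")
            continue
        v = float(parts[2]) if parts[2] != "" else np.nan
        records.append((t, kind, v))

    events = pd.DataFrame(records, columns=["time_s", "event", "value"])
    times = events["time_s"].to_numpy()
    if len(times) > 1 and np.any(np.diff(times) < -_TIME_TOL_S):
        raise FormatError(f"event log {path} has non-monotone timestamps")

    duration = float(meta.get("duration_s",
                              times[-1] + 1.0 if len(times) else 0.0))
    extra = {k: float(v) for k, v in meta.items()
             if k in ("tone_duration_s", "trial_duration_s", "reward_window_s")}
    log = EventLog(mouse=meta["mouse"], phase=meta["phase"], day=int(meta["day"]),
                   test=int(meta["test"]), events=events, duration_s=duration,
                   sync_offset_s=float(meta.get("sync_offset_s", 0.0)),
                   extra=extra, warnings=warnings)
    _validate_tones(log)
    _validate_rewards(log)
    return log


def _validate_tones(log: EventLog) -> None:
    """tone_on/tone_off must strictly alternate; an unmatched tone_on at the
    end of the session is auto-closed at session end."""
    tones = log.events[log.events["event"].isin(["tone_on", "tone_off"])]
    expected = "tone_on"
    for _, row in tones.iterrows():
        if row["event"] != expected:
            raise FormatError(
                f"tone events do not alternate: unexpected {row['event']} "
                f"at t={row['time_s']}")
        expected = "tone_off" if expected == "tone_on" else "tone_on"
    if expected == "tone_off":  # dangling tone_on
        log.warnings.append("unmatched tone_on at end of log; auto-closed at session end")
        closed = pd.concat([log.events,
                            pd.DataFrame([{"time_s": log.duration_s,
                                           "event": "tone_off", "value": np.nan}])],
                           ignore_index=True)
        log.events = make_event_frame(closed[["time_s", "event", "value"]]
                                      .itertuples(index=False, name=None))


def _validate_rewards(log: EventLog) -> None:
    licks = log.times_of("lick")
    for t in log.times_of("reward_delivery"):
        if licks.size == 0 or np.min(np.abs(licks - t)) > REWARD_LICK_TOL_S:
            log.warnings.append(
                f"reward_delivery at t={t} has no coincident lick")


def rewarded_lick_mask(lick_times: np.ndarray, reward_times: np.ndarray) -> np.ndarray:
    """Boolean mask over licks: True where a reward_delivery shares the
    timestamp within 1 ms."""
    if lick_times.size == 0:
        return np.zeros(0, dtype=bool)
    if reward_times.size == 0:
        return np.zeros(lick_times.size, dtype=bool)
    d = np.abs(lick_times[:, None] - reward_times[None, :])
    return (d <= REWARD_LICK_TOL_S).any(axis=1)


def lick_bout_onsets(lick_times: np.ndarray,
                     gap_s: float = DEFAULT_BOUT_GAP_S) -> np.ndarray:
    """Onset of each licking bout: the first lick, plus any lick preceded by
    at least ``gap_s`` without licks."""
    lick_times = np.sort(np.asarray(lick_times, dtype=float))
    if lick_times.size == 0:
        return lick_times
    starts = np.ones(lick_times.size, dtype=bool)
    starts[1:] = np.diff(lick_times) >= gap_s
    return lick_times[starts]


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_trials(log: EventLog, trial_duration_s: Optional[float] = None) -> list[Trial]:
    """Split a session into trials.

    Phases I/III: one trial per tone_on, spanning to the next tone_on (or
    session end); the trial span includes the post-tone interval, so
    out-of-tone licks belong to the preceding trial. Phase II: one trial per
    opening press — a press not inside a prior trial's span — lasting
    ``trial_duration_s`` (default from the log metadata, else 10 s).
    """
    if log.phase in ("I", "III"):
        trials = _segment_cued(log)
    elif log.phase == "II":
        if trial_duration_s is None:
            trial_duration_s = log.extra.get("trial_duration_s", 10.0)
        trials = _segment_operant(log, trial_duration_s)
    else:
        raise FormatError(f"unknown phase {log.phase!r}")
    for tr in trials:
        tr.outcome = classify_trial(tr)
    return trials


def _slice(log: EventLog, start: float, end: float) -> pd.DataFrame:
    ev = log.events
    return ev[(ev["time_s"] >= start) & (ev["time_s"] < end)].reset_index(drop=True)


def _segment_cued(log: EventLog) -> list[Trial]:
    tone_on = log.times_of("tone_on")
    tone_off = log.times_of("tone_off")
    trials = []
    for i, t0 in enumerate(tone_on):
        end = tone_on[i + 1] if i + 1 < len(tone_on) else max(log.duration_s, t0)
        cue_end = tone_off[i] if i < len(tone_off) else min(t0 + 5.0, end)
        ev = _slice(log, t0, end)
        reward_window = None
        if log.phase == "III":
            ins = ev.loc[ev["event"] == "spout_in", "time_s"].to_numpy()
            outs = ev.loc[ev["event"] == "spout_out", "time_s"].to_numpy()
            if ins.size:
                reward_window = (float(ins[0]),
                                 float(outs[0]) if outs.size else end)
        elif log.phase == "I":
            reward_window = (float(t0), float(cue_end))
        trials.append(Trial(trial_idx=i, phase=log.phase, start_time_s=float(t0),
                            end_time_s=float(end), cue_window=(float(t0), float(cue_end)),
                            reward_window=reward_window, events=ev))
    return trials


def _segment_operant(log: EventLog, trial_duration_s: float) -> list[Trial]:
    presses = log.times_of("lever_press")
    opens = []
    trial_end = -np.inf
    for p in presses:
        if p >= trial_end:
            opens.append(p)
            trial_end = p + trial_duration_s
    reward_window_s = log.extra.get("reward_window_s", 5.0)
    trials = []
    for i, p in enumerate(opens):
        end = p + trial_duration_s
        trials.append(Trial(trial_idx=i, phase="II", start_time_s=float(p),
                            end_time_s=float(end), cue_window=None,
                            reward_window=(float(p), float(p + reward_window_s)),
                            events=_slice(log, p, end)))
    return trials


def pre_trial_events(log: EventLog, trials: list[Trial]) -> pd.DataFrame:
    """Events before the first trial (plus, for Phase II, any between-trial
    events after a trial's 10 s span closed)."""
    ev = log.events
    if not trials:
        return ev.copy()
    mask = np.ones(len(ev), dtype=bool)
    for tr in trials:
        mask &= ~((ev["time_s"] >= tr.start_time_s) & (ev["time_s"] < tr.end_time_s))
    return ev[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_trial(trial: Trial) -> str:
    """Deterministic outcome class.

    Rewarded iff the trial contains at least one rewarded lick. Otherwise:
    cued-operant trials with zero presses are "no_presses"; classical
    trials with zero licks are "no_licks"; everything else (licks outside
    the cue, presses without consumption) is "non_rewarded".
    """
    licks = trial.times_of("lick")
    rewards = trial.times_of("reward_delivery")
    if rewarded_lick_mask(licks, rewards).any():
        return "rewarded"
    if trial.phase == "III" and trial.n_presses == 0:
        return "no_presses"
    if trial.phase == "I" and licks.size == 0:
        return "no_licks"
    return "non_rewarded"


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def compute_metrics(trials: list[Trial], phase: str) -> pd.DataFrame:
    """Per-trial behavior metrics: latencies (NaN when the event is absent),
    counts, and the outcome class."""
    rows = []
    for tr in trials:
        licks = tr.times_of("lick")
        presses = tr.times_of("lever_press")
        lat_lick = float(licks[0] - tr.start_time_s) if licks.size else np.nan
        lat_press = float(presses[0] - tr.start_time_s) if presses.size else np.nan
        lat_p2l = np.nan
        if presses.size:
            after = licks[licks >= presses[0]]
            if after.size:
                lat_p2l = float(after[0] - presses[0])
        rows.append({"trial_idx": tr.trial_idx, "phase": phase,
                     "start_time_s": tr.start_time_s,
                     "outcome": tr.outcome if tr.outcome else classify_trial(tr),
                     "n_licks": tr.n_licks, "n_presses": tr.n_presses,
                     "latency_first_lick_s": lat_lick,
                     "latency_first_press_s": lat_press,
                     "latency_press_to_first_lick_s": lat_p2l})
    return pd.DataFrame(rows)


METRIC_COLUMNS = ("latency_first_lick_s", "latency_first_press_s",
                  "latency_press_to_first_lick_s", "n_licks", "n_presses",
                  "pct_successful_trials")


def summarize_test(per_trial: pd.DataFrame, phase: str,
                   session_start_s: float = 0.0) -> pd.Series:
    """One row per test: trial means of the per-trial metrics (missing
    latencies excluded, not zero-filled) and the percentage of rewarded
    trials. For the free-operant phase the press latency is the time from
    test start to the first press, since every trial starts at a press."""
    if len(per_trial) == 0:
        raise ValueError("summarize_test requires at least one trial")
    out = {
        "n_trials": len(per_trial),
        "latency_first_lick_s": per_trial["latency_first_lick_s"].mean(),
        "latency_first_press_s": per_trial["latency_first_press_s"].mean(),
        "latency_press_to_first_lick_s": per_trial["latency_press_to_first_lick_s"].mean(),
        "n_licks": per_trial["n_licks"].mean(),
        "n_presses": per_trial["n_presses"].mean(),
        "pct_successful_trials": 100.0 * (per_trial["outcome"] == "rewarded").mean(),
    }
    if phase == "II":
        out["latency_first_press_s"] = float(
            per_trial["start_time_s"].min() - session_start_s)
    return pd.Series(out)


def aggregate_by_day(per_test: pd.DataFrame) -> pd.DataFrame:
    """Cohort summary: grand mean ± SEM across mice for each (day, test).

    ``per_test`` must have one row per (mouse, day, test) plus metric
    columns; duplicates raise ValueError. SEM uses n = number of animals
    (NaN when a single mouse contributes).
    """
    keys = ["mouse", "day", "test"]
    for k in keys:
        if k not in per_test.columns:
            raise ValueError(f"per_test table lacks key column {k!r}")
    if per_test.duplicated(subset=keys).any():
        dup = per_test[per_test.duplicated(subset=keys)].iloc[0]
        raise ValueError(f"duplicate (mouse, day, test) key: "
                         f"({dup['mouse']}, {dup['day']}, {dup['test']})")
    metrics = [c for c in METRIC_COLUMNS if c in per_test.columns]
    g = per_test.groupby(["day", "test"])[metrics]
    mean = g.mean().add_suffix("_mean")
    sem = g.sem(ddof=1).add_suffix("_sem")  # denominator: number of mice
    n = g.count().iloc[:, 0].rename("n_mice")
    return pd.concat([mean, sem, n], axis=1).reset_index()


# ---------------------------------------------------------------------------
# independent contingency replay
# ---------------------------------------------------------------------------

def check_contingency(log: EventLog, reward_window_s: float = 5.0,
                      trial_duration_s: float = 10.0) -> list[str]:
    """Replay a log against the phase's reward rule; returns violations.

    This is a flat chronological scan, independent of both the simulator's
    forward generation and the trial segmentation above: it re-derives spout
    availability from tones and presses and requires every reward_delivery
    to fall inside it with a coincident lick.
    """
    reward_window_s = log.extra.get("reward_window_s", reward_window_s)
    trial_duration_s = log.extra.get("trial_duration_s", trial_duration_s)
    violations = []
    licks = log.times_of("lick")
    tone_on = log.times_of("tone_on")
    tone_off = log.times_of("tone_off")

    def in_tone(t: float) -> bool:
        return any(a <= t < b for a, b in zip(tone_on, tone_off))

    spout_until = -np.inf
    trial_until = -np.inf
    for _, row in log.events.iterrows():
        t, kind = float(row["time_s"]), row["event"]
        if kind == "lever_press":
            if log.phase == "II" and t >= trial_until:
                trial_until = t + trial_duration_s
                spout_until = t + reward_window_s
            elif log.phase == "III" and in_tone(t) and t >= spout_until:
                spout_until = t + reward_window_s
        elif kind == "reward_delivery":
            if licks.size == 0 or np.min(np.abs(licks - t)) > REWARD_LICK_TOL_S:
                violations.append(f"reward at t={t} without a coincident lick")
            if log.phase == "I":
                if not in_tone(t):
                    violations.append(f"reward at t={t} outside the tone window")
            else:
                if not t < spout_until:
                    violations.append(f"reward at t={t} with the spout unavailable")
    return violations
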