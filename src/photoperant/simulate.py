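"""Synthetic operant sessions: a virtual learning mouse driving the task
state machine, a generative two-channel photometry model, and an optional
pose-trajectory generator. Every stochastic draw goes through one seeded
generator per session, so identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd

from .config import AgentConfig, PhotometryGenConfig, TaskConfig
from .core import EventLog, PhotometryRecording, PoseTrack, SimGroundTruth, make_event_frame
from .errors import ConfigurationError

# event timestamps are quantized to 0.1 ms so that written logs round-trip
# exactly through the text format
TIME_DECIMALS = 4

_PHASE_CODE = {"I": 1, "II": 2, "III": 3}


def session_rng(seed: int, phase: str, day: int, test: int,
                mouse_index: int = 0, stream: int = 0) -> np.random.Generator:
    """One deterministic generator per (seed, mouse, phase, day, test, stream)."""
    return np.random.default_rng(
        [int(seed), int(mouse_index), _PHASE_CODE[phase], int(day), int(test), int(stream)])


def learning_schedule(agent: AgentConfig, day: int) -> tuple[float, float]:
    """Expected action latency and engagement probability on a training day.

    latency(day) = asymptote + (init - asymptote) * exp(-(day-1)/tau);
    engagement interpolates init -> final on the same exponential, so the
    latency is non-increasing and the engagement non-decreasing in day.
    """
    if day < 1:
        raise ConfigurationError("day must be >= 1")
    decay = float(np.exp(-(day - 1) / agent.learning_tau_days))
    latency = agent.latency_asymptote_s + (agent.latency_init_s - agent.latency_asymptote_s) * decay
    engage = agent.engage_prob_final + (agent.engage_prob_init - agent.engage_prob_final) * decay
    return latency, engage


def _schedule_value(init: float, asymptote: float, tau: float, day: int) -> float:
    return asymptote + (init - asymptote) * float(np.exp(-(day - 1) / tau))


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Log-normal draw with the given mean and coefficient of variation."""
    if cv <= 0:
        return mean
    s2 = np.log1p(cv * cv)
    return float(rng.lognormal(np.log(mean) - s2 / 2.0, np.sqrt(s2)))


def _q(t: float) -> float:
    return round(float(t), TIME_DECIMALS)


class _SessionBuilder:
    """Accumulates events, trials, and ground-truth transients."""

    def __init__(self, task: TaskConfig, agent: AgentConfig):
        self.task = task
        self.agent = agent
        self.records: list[tuple[float, str, float]] = []
        self.trials: list[dict] = []
        self.transients: list[dict] = []

    def add(self, t: float, kind: str, value: float = np.nan) -> None:
        self.records.append((_q(t), kind, value))

    def add_press(self, t: float, rng: np.random.Generator) -> float:
        lo, hi = self.agent.press_force_range
        t = _q(t)
        self.add(t, "lever_press", round(float(rng.uniform(lo, hi)), 2))
        return t

    def add_bout(self, onset: float, window: Optional[tuple[float, float]],
                 lick_span: Optional[tuple[float, float]] = None):
        """Regular lick train; licks inside ``window`` are rewarded (the rig
        logs the reward at the lick's own timestamp). ``lick_span`` restricts
        when licking is physically possible (spout retracted outside it).
        Returns (lick_times, n_rewarded)."""
        agent = self.agent
        n = max(1, int(round(agent.bout_duration_s * agent.lick_rate_hz)))
        times, n_rew = [], 0
        for k in range(n):
            t = _q(onset + k / agent.lick_rate_hz)
            if lick_span is not None and not (lick_span[0] <= t < lick_span[1]):
                continue
            times.append(t)
            self.add(t, "lick")
            if window is not None and window[0] <= t < window[1]:
                self.add(t, "reward_delivery", 5.0)  # uL of sucrose solution
                n_rew += 1
        return times, n_rew

    def add_transient(self, t: float, behavior: str, trial_idx: int) -> None:
        self.transients.append({"time_s": _q(t), "amplitude": np.nan,
                                "linked_behavior": behavior, "trial_idx": trial_idx})

    def finish_trial(self, trial_idx: int, start: float, latency: float,
                     outcome: str) -> None:
        self.trials.append({"trial_idx": trial_idx, "start_s": _q(start),
                            "latency_s": latency, "outcome": outcome})
        for tr in self.transients:
            if tr["trial_idx"] == trial_idx:
                tr["outcome"] = outcome

    def build(self, mouse: str, day: int, test: int, duration: float) -> tuple[EventLog, SimGroundTruth]:
        events = make_event_frame(self.records)
        log = EventLog(mouse=mouse, phase=self.task.phase, day=day, test=test,
                       events=events, duration_s=float(duration),
                       extra={"tone_duration_s": self.task.tone_duration_s,
                              "trial_duration_s": self.task.trial_duration_s,
                              "reward_window_s": self.task.reward_window_s})
        tr = pd.DataFrame(self.transients,
                          columns=["time_s", "amplitude", "linked_behavior",
                                   "trial_idx", "outcome"]).sort_values(
                              "time_s", kind="mergesort").reset_index(drop=True)
        trials = pd.DataFrame(self.trials,
                              columns=["trial_idx", "start_s", "latency_s", "outcome"])
        return log, SimGroundTruth(transients=tr, trials=trials)


def run_task_state_machine(task: TaskConfig, agent: AgentConfig, day: int,
                           test_index: int = 1, mouse: str = "m01",
                           rng: Optional[np.random.Generator] = None,
                           n_trials: Optional[int] = None) -> tuple[EventLog, SimGroundTruth]:
    """Simulate one test session under the phase's reward contingency.

    Phase I: licks are rewarded only while the tone plays. Phase II: a lever
    press outside an open trial opens a ``trial_duration_s`` trial with the
    spout available for ``reward_window_s``. Phase III: only a press inside
    the tone window opens the spout.
    """
    if not 1 <= day <= task.days:
        raise ConfigurationError(f"day must be within 1..{task.days}, got {day}")
    if rng is None:
        rng = session_rng(agent.rng_seed, task.phase, day, test_index)

    b = _SessionBuilder(task, agent)
    b.add(0.0, "sync")
    exp_latency, engage_p = learning_schedule(agent, day)

    if task.phase == "II":
        duration = _run_phase2(b, task, agent, day, rng)
    else:
        if n_trials is None:
            lo, hi = task.trials_per_test
            n_trials = int(rng.integers(lo, hi + 1))
        if task.phase == "I":
            _run_phase1(b, task, agent, n_trials, exp_latency, engage_p, rng)
        else:
            _run_phase3(b, task, agent, day, n_trials, exp_latency, engage_p, rng)
        duration = task.start_offset_s + n_trials * task.trial_period_s

    return b.build(mouse, day, test_index, duration)


def _run_phase1(b: _SessionBuilder, task: TaskConfig, agent: AgentConfig,
                n_trials: int, exp_latency: float, engage_p: float,
                rng: np.random.Generator) -> None:
    b.add(0.0, "spout_in")  # spout always accessible in classical conditioning
    for i in range(n_trials):
        t0 = task.start_offset_s + i * task.trial_period_s
        t_end = t0 + task.trial_period_s
        tone_off = t0 + task.tone_duration_s
        b.add(t0, "tone_on")
        b.add(tone_off, "tone_off")
        engaged = rng.random() < engage_p
        latency = np.nan
        onset = None
        if engaged:
            lat = _lognormal(rng, exp_latency, agent.latency_cv)
            onset = min(t0 + lat, t_end - agent.bout_duration_s - 0.2)
            latency = onset - t0
        elif rng.random() < agent.stray_action_prob:
            lo = tone_off + 1.0
            hi = t_end - agent.bout_duration_s - 0.5
            if hi > lo:
                onset = float(rng.uniform(lo, hi))
        if onset is not None:
            licks, n_rew = b.add_bout(onset, (t0, tone_off))
            b.add_transient(licks[0], "lick_bout_onset", i)
            outcome = "rewarded" if n_rew else "non_rewarded"
            if np.isnan(latency):
                latency = licks[0] - t0
        else:
            outcome = "no_licks"
        b.finish_trial(i, t0, latency, outcome)


def _run_phase2(b: _SessionBuilder, task: TaskConfig, agent: AgentConfig,
                day: int, rng: np.random.Generator) -> float:
    duration = task.test_duration_s
    exp_first, _ = learning_schedule(agent, day)
    mean_ipi = _schedule_value(agent.press_interval_init_s,
                               agent.press_interval_asymptote_s,
                               agent.learning_tau_days, day)
    p2l = _schedule_value(agent.press_to_lick_init_s,
                          agent.press_to_lick_asymptote_s,
                          agent.learning_tau_days, day)

    # press bout times: first press after the scheduled latency, then a
    # renewal process whose mean interval shrinks with learning
    t = _lognormal(rng, exp_first, agent.latency_cv)
    first_press_latency = t
    trial_idx = -1
    trial_end = -np.inf
    pending: Optional[dict] = None
    while t < duration - 1.0:
        t_press = b.add_press(t, rng)
        if t_press >= trial_end:
            # opening press: new trial, spout available for reward_window_s
            if pending is not None:
                b.finish_trial(**pending)
            trial_idx += 1
            trial_end = t_press + task.trial_duration_s
            window = (t_press, t_press + task.reward_window_s)
            b.add(t_press, "spout_in")
            b.add(window[1], "spout_out")
            b.add_transient(t_press, "lever_press", trial_idx)
            n_rew = 0
            lat = np.nan
            if rng.random() < agent.consume_prob:
                onset = t_press + _lognormal(rng, p2l, agent.latency_cv)
                if onset < window[1] - 0.05:
                    licks, n_rew = b.add_bout(onset, (window[0], window[1] - 1e-3),
                                              lick_span=(window[0], window[1] - 1e-3))
                    b.add_transient(licks[0], "lick_bout_onset", trial_idx)
                    lat = licks[0] - t_press
            pending = {"trial_idx": trial_idx, "start": t_press,
                       "latency": first_press_latency if trial_idx == 0 else lat,
                       "outcome": "rewarded" if n_rew else "non_rewarded"}
        else:
            # in-trial press: logged on the current trial, does not reopen it
            b.add_transient(t_press, "lever_press", trial_idx)
        step = _lognormal(rng, mean_ipi, agent.latency_cv)
        if rng.random() < agent.extra_press_prob:
            step = min(step, float(rng.uniform(1.0, task.trial_duration_s - 1.0)))
        t = t_press + max(step, 0.5)
    if pending is not None:
        b.finish_trial(**pending)
    return duration


def _run_phase3(b: _SessionBuilder, task: TaskConfig, agent: AgentConfig,
                day: int, n_trials: int, exp_latency: float, engage_p: float,
                rng: np.random.Generator) -> None:
    p2l = _schedule_value(agent.press_to_lick_init_s,
                          agent.press_to_lick_asymptote_s,
                          agent.learning_tau_days, day)
    for i in range(n_trials):
        t0 = task.start_offset_s + i * task.trial_period_s
        t_end = t0 + task.trial_period_s
        tone_off = t0 + task.tone_duration_s
        b.add(t0, "tone_on")
        b.add(tone_off, "tone_off")
        engaged = rng.random() < engage_p
        latency = np.nan
        outcome = "no_presses"
        if engaged:
            lat = _lognormal(rng, exp_latency, agent.latency_cv)
            t_press = b.add_press(min(t0 + lat, t_end - 1.0), rng)
            latency = t_press - t0
            b.add_transient(t_press, "lever_press", i)
            outcome = "non_rewarded"
            if t_press < tone_off:
                # press inside the cue opens the spout
                window = (t_press, min(t_press + task.reward_window_s, t_end))
                b.add(window[0], "spout_in")
                b.add(window[1], "spout_out")
                if rng.random() < agent.consume_prob:
                    onset = t_press + _lognormal(rng, p2l, agent.latency_cv)
                    if onset < window[1] - 0.05:
                        licks, n_rew = b.add_bout(onset, (window[0], window[1] - 1e-3),
                                                  lick_span=(window[0], window[1] - 1e-3))
                        b.add_transient(licks[0], "lick_bout_onset", i)
                        if n_rew:
                            outcome = "rewarded"
        elif rng.random() < agent.stray_action_prob:
            # disengaged stray press in the interval: no spout, no reward
            t_press = b.add_press(float(rng.uniform(tone_off + 0.5, t_end - 0.5)), rng)
            b.add_transient(t_press, "lever_press", i)
            outcome = "non_rewarded"
        b.finish_trial(i, t0, latency, outcome)


# ---------------------------------------------------------------------------
# photometry generation
# ---------------------------------------------------------------------------

def transient_kernel(t: np.ndarray, tau_rise_s: float, tau_decay_s: float) -> np.ndarray:
    """Unit-peak double-exponential calcium transient kernel.

    K(t) = (1 - exp(-t/tau_r)) * exp(-t/tau_d) for t >= 0, scaled so that
    max K = 1; hence a ground-truth amplitude A is directly the peak ΔF/F
    contribution of the transient.
    """
    t = np.asarray(t, dtype=float)
    g = np.where(t >= 0, (1.0 - np.exp(-np.maximum(t, 0) / tau_rise_s))
                 * np.exp(-np.maximum(t, 0) / tau_decay_s), 0.0)
    t_peak = tau_rise_s * np.log1p(tau_decay_s / tau_rise_s)
    peak = (1.0 - np.exp(-t_peak / tau_rise_s)) * np.exp(-t_peak / tau_decay_s)
    return g / peak


def _add_kernels(signal: np.ndarray, fs: float, times, amps,
                 tau_r: float, tau_d: float) -> None:
    """Add unit-peak kernels (scaled by amps) in place, windowed to 10 decay
    constants for speed."""
    n = len(signal)
    span = int(np.ceil((tau_r + 10 * tau_d) * fs))
    for t0, a in zip(times, amps):
        i0 = int(np.floor(t0 * fs))
        i1 = min(i0 + span, n)
        if i1 <= 0 or i0 >= n:
            continue
        i0c = max(i0, 0)
        rel = np.arange(i0c, i1) / fs - t0
        signal[i0c:i1] += a * transient_kernel(rel, tau_r, tau_d)


def generate_photometry(log: EventLog, truth: SimGroundTruth,
                        cfg: PhotometryGenConfig,
                        rng: Optional[np.random.Generator] = None
                        ) -> tuple[PhotometryRecording, SimGroundTruth]:
    """Generate the raw two-channel recording for a simulated session.

    465 nm: baseline * bleach(t) * (1 + transients + consumption dips +
    artifact + noise). 405 nm (isosbestic): same bleach, shared fractional
    artifact scaled by ``artifact_gain_405`` and independent noise, but no
    calcium transients. The ground truth is returned with transient
    amplitudes filled in and the realized artifact/bleach series attached.
    """
    if log.n_events == 0:
        raise ValueError("cannot generate photometry for an empty event log")
    if rng is None:
        rng = session_rng(cfg.rng_seed, log.phase, log.day, log.test, stream=1)

    fs = cfg.sample_rate_hz
    n = int(round(log.duration_s * fs))
    t = np.arange(n) / fs
    provenance = []
    if fs < 2.0 / cfg.tau_rise_s:
        provenance.append(
            f"sample rate {fs} Hz resolves tau_rise {cfg.tau_rise_s}s with "
            "fewer than 2 samples; transient peaks will be undersampled")

    # assign generative amplitudes by trial outcome, with optional day ramp
    day_gain = 1.0 + cfg.amp_day_ramp * (log.day - 1)
    tr = truth.transients.copy()
    amp = np.where(tr["outcome"].to_numpy() == "rewarded",
                   cfg.transient_amp_rewarded, cfg.transient_amp_nonrewarded) * day_gain
    tr["amplitude"] = amp

    s = np.zeros(n)
    _add_kernels(s, fs, tr["time_s"].to_numpy(), amp, cfg.tau_rise_s, cfg.tau_decay_s)

    # consumption-period depression: follows the onset of rewarded lick bouts
    if cfg.consumption_dip_amp != 0.0:
        bouts = tr[(tr["linked_behavior"] == "lick_bout_onset")
                   & (tr["outcome"] == "rewarded")]
        _add_kernels(s, fs, bouts["time_s"].to_numpy() + cfg.dip_delay_s,
                     np.full(len(bouts), cfg.consumption_dip_amp),
                     cfg.dip_tau_rise_s, cfg.dip_tau_decay_s)

    # shared motion artifact: sparse biphasic bumps as fractional modulation
    a = np.zeros(n)
    if cfg.artifact_rate_hz > 0 and cfg.artifact_amp != 0.0:
        n_art = rng.poisson(cfg.artifact_rate_hz * log.duration_s)
        times = np.sort(rng.uniform(0.0, log.duration_s, n_art))
        amps = (cfg.artifact_amp * rng.normal(1.0, 0.3, n_art)
                * rng.choice([-1.0, 1.0], n_art))
        _add_kernels(a, fs, times, amps, cfg.artifact_tau_rise_s, cfg.artifact_tau_decay_s)

    bleach = np.exp(-t / cfg.bleach_tau_s)
    noise465 = rng.normal(0.0, cfg.noise_sd, n) if cfg.noise_sd > 0 else 0.0
    noise405 = rng.normal(0.0, cfg.noise_sd, n) if cfg.noise_sd > 0 else 0.0
    F465 = cfg.baseline_F465 * bleach * (1.0 + s + a + noise465)
    F405 = cfg.baseline_F405 * bleach * (1.0 + cfg.artifact_gain_405 * a + noise405)

    rec = PhotometryRecording(time_s=t, F405=F405, F465=F465, sample_rate_hz=fs,
                              sync_offset_s=0.0, mouse=log.mouse, phase=log.phase,
                              day=log.day, test=log.test, provenance=provenance)
    new_truth = SimGroundTruth(transients=tr, trials=truth.trials,
                               artifact=a, bleach=bleach, time_s=t)
    return rec, new_truth


# ---------------------------------------------------------------------------
# pose generation
# ---------------------------------------------------------------------------

BODYPARTS = ("head", "paw_front_left", "paw_front_right",
             "paw_rear_left", "paw_rear_right", "rear", "tail")

_PART_OFFSETS = {
    "head": (0.0, 0.0),
    "paw_front_left": (-12.0, 10.0),
    "paw_front_right": (12.0, 10.0),
    "paw_rear_left": (-14.0, 38.0),
    "paw_rear_right": (14.0, 38.0),
    "rear": (0.0, 45.0),
    "tail": (0.0, 70.0),
}


def generate_pose_track(log: EventLog, task: TaskConfig, agent: AgentConfig,
                        rng: Optional[np.random.Generator] = None) -> PoseTrack:
    """Head-anchored random exploration that approaches the spout around lick
    bouts and the lever around presses; other body parts trail the head with
    fixed offsets plus jitter."""
    if rng is None:
        rng = session_rng(agent.rng_seed, log.phase, log.day, log.test, stream=2)
    geo = task.geometry
    fps = task.frame_rate_hz
    n = int(round(log.duration_s * fps))
    dt = 1.0 / fps

    # target schedule: spout around licks, lever around presses, else wander
    target = np.empty((n, 2))
    wander = np.array([geo.width / 2, geo.height / 2])
    next_resample = 0.0
    licks = log.times_of("lick")
    presses = log.times_of("lever_press")
    for k in range(n):
        tk = k * dt
        if licks.size and np.any((licks - 1.0 <= tk) & (tk <= licks + 0.3)):
            target[k] = geo.spout_xy
        elif presses.size and np.any((presses - 1.0 <= tk) & (tk <= presses + 0.5)):
            target[k] = geo.lever_xy
        else:
            if tk >= next_resample:
                wander = np.array([rng.uniform(0.05, 0.95) * geo.width,
                                   rng.uniform(0.05, 0.95) * geo.height])
                next_resample = tk + rng.uniform(2.0, 5.0)
            target[k] = wander

    # head follows the target with a short relaxation time plus diffusion
    tau, sigma = 0.4, 25.0
    head = np.empty((n, 2))
    head[0] = target[0]
    steps = rng.normal(0.0, sigma * np.sqrt(dt), (n - 1, 2)) if n > 1 else None
    for k in range(1, n):
        head[k] = head[k - 1] + (dt / tau) * (target[k] - head[k - 1]) + steps[k - 1]
    head[:, 0] = np.clip(head[:, 0], 0, geo.width)
    head[:, 1] = np.clip(head[:, 1], 0, geo.height)

    cols, arrays = [], []
    for part in BODYPARTS:
        off = np.asarray(_PART_OFFSETS[part])
        xy = head + off + rng.normal(0.0, 2.0, (n, 2))
        xy[:, 0] = np.clip(xy[:, 0], 0, geo.width)
        xy[:, 1] = np.clip(xy[:, 1], 0, geo.height)
        conf = np.minimum(1.0, rng.beta(20.0, 1.0, n))
        dropout = rng.random(n) < 0.02
        conf[dropout] = rng.uniform(0.0, 0.3, dropout.sum())
        for name, arr in (("x", xy[:, 0]), ("y", xy[:, 1]), ("likelihood", conf)):
            cols.append((part, name))
            arrays.append(arr)
    data = pd.DataFrame(dict(zip(range(len(arrays)), arrays)))
    data.columns = pd.MultiIndex.from_tuples(cols, names=["bodyparts", "coords"])
    return PoseTrack(frame_rate_hz=fps, data=data)


# ---------------------------------------------------------------------------
# session output
# ---------------------------------------------------------------------------

def _meta_lines(log: EventLog) -> list[str]:
    pairs = {"mouse": log.mouse, "phase": log.phase, "day": log.day,
             "test": log.test, "duration_s": log.duration_s,
             "sync_offset_s": log.sync_offset_s, **log.extra}
    return [f"# {k}={v}" for k, v in pairs.items()]


def write_event_log(log: EventLog, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(_meta_lines(log)) + "\n")
        fh.write("time_s\tevent\tvalue\n")
        for t, e, v in log.events.itertuples(index=False):
            vs = "" if pd.isna(v) else f"{v:g}"
            fh.write(f"{t:.4f}\t{e}\t{vs}\n")


def write_photometry(rec: PhotometryRecording, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mouse={rec.mouse}\n# phase={rec.phase}\n# day={rec.day}\n"
                 f"# test={rec.test}\n# sample_rate_hz={rec.sample_rate_hz}\n"
                 f"# sync_offset_s={rec.sync_offset_s}\n")
        df = pd.DataFrame({"time_s": rec.time_s, "F405": rec.F405, "F465": rec.F465})
        df.to_csv(fh, index=False)


def write_pose(pose: PoseTrack, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# frame_rate_hz={pose.frame_rate_hz}\n")
        pose.data.to_csv(fh, index=True, index_label="frame")


def write_session(log: EventLog, recording: Optional[PhotometryRecording],
                  pose: Optional[PoseTrack], truth: Optional[SimGroundTruth],
                  out_dir: str) -> dict:
    """Write one session's files; returns {name: path}. Formats round-trip
    losslessly through the events/photometry/tracking readers."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {"events": os.path.join(out_dir, "events.tsv")}
    write_event_log(log, paths["events"])
    if recording is not None:
        paths["photometry"] = os.path.join(out_dir, "photometry.csv")
        write_photometry(recording, paths["photometry"])
    if pose is not None:
        paths["pose"] = os.path.join(out_dir, "pose.csv")
        write_pose(pose, paths["pose"])
    if truth is not None:
        paths["truth_transients"] = os.path.join(out_dir, "truth_transients.csv")
        truth.transients.to_csv(paths["truth_transients"], index=False)
        paths["truth_trials"] = os.path.join(out_dir, "truth_trials.csv")
        truth.trials.to_csv(paths["truth_trials"], index=False)
    return paths
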