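"""Configuration dataclasses for the task, the virtual agent, and the signal generator.

All durations are in seconds on a single master clock with t = 0 at session
start. The behavioral sync pulse is represented as an explicit offset that is
applied once when a recording is loaded, so behavior and photometry share a
timebase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from .errors import ConfigurationError

PHASES = ("I", "II", "III")

#: Training days per phase: 8 for classical conditioning, 6 for free operant,
#: 5 for cued operant.
DEFAULT_DAYS = {"I": 8, "II": 6, "III": 5}


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass(frozen=True)
class BoxGeometry:
    """Operant-box geometry in camera pixel coordinates (origin top-left,
    y increasing downward, the usual image convention)."""

    width: float = 600.0
    height: float = 450.0
    spout_xy: tuple[float, float] = (300.0, 40.0)
    lever_xy: tuple[float, float] = (140.0, 40.0)

    def __post_init__(self) -> None:
        _require(self.width > 0 and self.height > 0, "box dimensions must be positive")
        for name, (x, y) in (("spout", self.spout_xy), ("lever", self.lever_xy)):
            _require(0 <= x <= self.width and 0 <= y <= self.height,
                     f"{name} coordinates must lie inside the box")


@dataclass(frozen=True)
class TaskConfig:
    """Timing parameters of the three-phase operant task.

    Phase I (classical conditioning): a 5 s tone followed by a 15 s interval;
    licks during the tone are rewarded. Phase II (operant): no tone; each
    lever press outside an open trial starts a 10 s trial and makes the spout
    available for ``reward_window_s``; tests last 5 min. Phase III (cued
    operant): tones as in Phase I, but only a press during the tone opens
    the spout.
    """

    phase: str = "I"
    tone_duration_s: float = 5.0
    intertrial_interval_s: float = 15.0
    reward_window_s: float = 5.0
    trial_duration_s: float = 10.0
    trials_per_test: tuple[int, int] = (5, 10)
    tests_per_day: int = 2
    days: int | None = None
    test_duration_s: float = 300.0
    start_offset_s: float = 2.0
    frame_rate_hz: float = 30.0
    geometry: BoxGeometry = field(default_factory=BoxGeometry)

    def __post_init__(self) -> None:
        _require(self.phase in PHASES, f"phase must be one of {PHASES}, got {self.phase!r}")
        for name in ("tone_duration_s", "intertrial_interval_s", "reward_window_s",
                     "trial_duration_s", "test_duration_s", "frame_rate_hz"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(self.start_offset_s >= 0, "start_offset_s must be >= 0")
        lo, hi = self.trials_per_test
        _require(1 <= lo <= hi, "trials_per_test lower bound must be >= 1 and <= upper bound")
        _require(self.tests_per_day >= 1, "tests_per_day must be >= 1")
        if self.days is None:
            object.__setattr__(self, "days", DEFAULT_DAYS[self.phase])
        _require(self.days >= 1, "days must be >= 1")
        _require(self.reward_window_s <= self.trial_duration_s,
                 "reward_window_s cannot exceed trial_duration_s")

    @property
    def trial_period_s(self) -> float:
        """Tone-to-tone spacing for the cued phases."""
        return self.tone_duration_s + self.intertrial_interval_s


@dataclass(frozen=True)
class AgentConfig:
    """Virtual learning mouse.

    The expected action latency relaxes exponentially from ``latency_init_s``
    to ``latency_asymptote_s`` with time constant ``learning_tau_days``;
    engagement probability rises from ``engage_prob_init`` to
    ``engage_prob_final`` on the same time constant. Individual latencies are
    drawn log-normal around the schedule with coefficient of variation
    ``latency_cv``. Licking is modeled as regular trains at ``lick_rate_hz``
    lasting ``bout_duration_s``.
    """

    latency_init_s: float = 8.0
    latency_asymptote_s: float = 1.5
    learning_tau_days: float = 2.0
    engage_prob_init: float = 0.4
    engage_prob_final: float = 0.95
    lick_rate_hz: float = 8.0
    bout_duration_s: float = 2.0
    press_force_range: tuple[float, float] = (10.0, 40.0)
    latency_cv: float = 0.3
    # time from a lever press to the first lick of the consumption bout
    press_to_lick_init_s: float = 4.0
    press_to_lick_asymptote_s: float = 1.0
    # mean interval between lever-press bouts in the free-operant phase
    press_interval_init_s: float = 75.0
    press_interval_asymptote_s: float = 20.0
    # probability of a stray (out-of-cue) lick bout / press on disengaged trials
    stray_action_prob: float = 0.4
    # probability an in-trial extra press occurs in the free-operant phase
    extra_press_prob: float = 0.2
    # probability the agent consumes (licks) after opening the spout
    consume_prob: float = 0.9
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("engage_prob_init", "engage_prob_final", "stray_action_prob",
                     "extra_press_prob", "consume_prob"):
            _require(0.0 <= getattr(self, name) <= 1.0, f"{name} must lie in [0, 1]")
        _require(self.latency_asymptote_s <= self.latency_init_s,
                 "latency_asymptote_s must not exceed latency_init_s")
        _require(self.latency_asymptote_s > 0, "latencies must be positive")
        _require(self.learning_tau_days > 0, "learning_tau_days must be > 0")
        _require(self.lick_rate_hz > 0, "lick_rate_hz must be > 0")
        _require(self.bout_duration_s > 0, "bout_duration_s must be > 0")
        _require(self.latency_cv >= 0, "latency_cv must be >= 0")
        _require(self.press_to_lick_asymptote_s <= self.press_to_lick_init_s,
                 "press_to_lick_asymptote_s must not exceed press_to_lick_init_s")
        _require(self.press_interval_asymptote_s <= self.press_interval_init_s,
                 "press_interval_asymptote_s must not exceed press_interval_init_s")
        lo, hi = self.press_force_range
        _require(0 < lo <= hi, "press_force_range must be positive and ordered")


@dataclass(frozen=True)
class PhotometryGenConfig:
    """Generative model of the two-channel recording.

    The calcium-dependent channel is ``baseline_F465 * bleach(t) *
    (1 + transients + dips + artifact + noise)``; the isosbestic channel
    carries the same fractional artifact (scaled by ``artifact_gain_405``)
    and noise but no transients. Transient kernels are double exponentials
    normalized to unit peak, so ground-truth amplitudes are directly in
    ΔF/F units.
    """

    sample_rate_hz: float = 100.0
    transient_amp_rewarded: float = 0.08
    transient_amp_nonrewarded: float = 0.04
    tau_rise_s: float = 0.1
    tau_decay_s: float = 0.8
    consumption_dip_amp: float = -0.015
    dip_tau_rise_s: float = 0.5
    dip_tau_decay_s: float = 2.0
    dip_delay_s: float = 0.5
    bleach_tau_s: float = 3000.0
    artifact_rate_hz: float = 0.1
    artifact_amp: float = 0.01
    artifact_gain_405: float = 1.0
    artifact_tau_rise_s: float = 0.02
    artifact_tau_decay_s: float = 0.1
    noise_sd: float = 0.003
    baseline_F465: float = 100.0
    baseline_F405: float = 80.0
    # per-day multiplicative amplitude ramp: amp * (1 + ramp * (day - 1))
    amp_day_ramp: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        _require(self.sample_rate_hz > 0, "sample_rate_hz must be > 0")
        _require(self.tau_rise_s < self.tau_decay_s, "tau_rise_s must be < tau_decay_s")
        _require(self.tau_rise_s > 0, "tau_rise_s must be > 0")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")
        _require(self.bleach_tau_s > 0, "bleach_tau_s must be > 0")
        _require(self.artifact_rate_hz >= 0, "artifact_rate_hz must be >= 0")
        _require(self.baseline_F465 > 0 and self.baseline_F405 > 0,
                 "baseline fluorescence must be positive")
        _require(self.consumption_dip_amp <= 0, "consumption_dip_amp is a depression (<= 0)")


def replace_fields(cfg, **overrides):
    """Return a copy of a frozen config dataclass with fields replaced.

    Unknown field names raise :class:`ConfigurationError` (rather than the
    bare TypeError dataclasses.replace would give), naming the bad key.
    """
    import dataclasses

    valid = {f.name for f in fields(cfg)}
    for key in overrides:
        if key not in valid:
            raise ConfigurationError(
                f"unknown {type(cfg).__name__} parameter: {key!r}")
    return dataclasses.replace(cfg, **overrides)
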