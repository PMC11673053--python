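"""In-memory containers shared by the simulator and the analysis modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Recognized behavioral event kinds, with a deterministic secondary sort
#: order for events sharing a timestamp (e.g. a rewarded lick and its
#: reward_delivery are logged at the same instant).
EVENT_ORDER = {
    "sync": 0,
    "tone_on": 1,
    "lever_press": 2,
    "spout_in": 3,
    "lick": 4,
    "reward_delivery": 5,
    "spout_out": 6,
    "tone_off": 7,
}
EVENT_KINDS = tuple(EVENT_ORDER)

#: Trial outcome classes.
OUTCOMES = ("rewarded", "non_rewarded", "no_licks", "no_presses")

#: Timestamp tolerance (s) for treating a lick and a reward_delivery as the
#: same rig event.
REWARD_LICK_TOL_S = 1e-3


def make_event_frame(records) -> pd.DataFrame:
    """Build a chronologically sorted event table from (time_s, event, value)
    records, breaking timestamp ties by the rig's logging order."""
    df = pd.DataFrame(records, columns=["time_s", "event", "value"])
    df["time_s"] = df["time_s"].astype(float)
    df["value"] = df["value"].astype(float)
    # stable two-key sort: time first, then the rig's logging order
    df = df.assign(_o=df["event"].map(EVENT_ORDER)).sort_values(
        ["time_s", "_o"], kind="mergesort").drop(columns="_o")
    return df.reset_index(drop=True)


@dataclass
class EventLog:
    """Ordered, timestamped behavioral events for one test session.

    ``events`` has columns ``time_s`` (float, seconds from session start),
    ``event`` (one of :data:`EVENT_KINDS`) and ``value`` (press force or
    reward volume; NaN otherwise).
    """

    mouse: str
    phase: str
    day: int
    test: int
    events: pd.DataFrame
    duration_s: float
    sync_offset_s: float = 0.0
    extra: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.events[self.events["event"] == kind]

    def times_of(self, kind: str) -> np.ndarray:
        return self.of_kind(kind)["time_s"].to_numpy()

    @property
    def n_events(self) -> int:
        return len(self.events)

    def equals(self, other: "EventLog") -> bool:
        meta = (self.mouse == other.mouse and self.phase == other.phase
                and self.day == other.day and self.test == other.test
                and self.duration_s == other.duration_s
                and self.sync_offset_s == other.sync_offset_s)
        if not meta or len(self.events) != len(other.events):
            return False
        a, b = self.events.reset_index(drop=True), other.events.reset_index(drop=True)
        same_val = (a["value"].fillna(-1.0).to_numpy()
                    == b["value"].fillna(-1.0).to_numpy()).all()
        return bool((a["time_s"].to_numpy() == b["time_s"].to_numpy()).all()
                    and (a["event"].to_numpy() == b["event"].to_numpy()).all()
                    and same_val)


@dataclass
class Trial:
    """One segmented trial: its windows, contained events, and outcome."""

    trial_idx: int
    phase: str
    start_time_s: float
    end_time_s: float
    cue_window: Optional[tuple[float, float]] = None     # [start, end)
    reward_window: Optional[tuple[float, float]] = None  # [start, end)
    events: pd.DataFrame = None
    outcome: Optional[str] = None

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.events[self.events["event"] == kind]

    def times_of(self, kind: str) -> np.ndarray:
        return self.of_kind(kind)["time_s"].to_numpy()

    @property
    def n_licks(self) -> int:
        return int((self.events["event"] == "lick").sum())

    @property
    def n_presses(self) -> int:
        return int((self.events["event"] == "lever_press").sum())


@dataclass
class SimGroundTruth:
    """The simulator's hidden record, used for recovery tests.

    ``transients`` columns: time_s, amplitude (ΔF/F; NaN until the signal
    generator runs), linked_behavior (lever_press | lick_bout_onset),
    trial_idx, outcome. ``trials`` columns: trial_idx, start_s, latency_s,
    outcome.
    """

    transients: pd.DataFrame
    trials: pd.DataFrame
    artifact: Optional[np.ndarray] = None   # fractional artifact series a(t)
    bleach: Optional[np.ndarray] = None
    time_s: Optional[np.ndarray] = None


@dataclass
class PhotometryRecording:
    """Time-aligned isosbestic (405 nm) and calcium-dependent (465 nm)
    channels on a uniform grid."""

    time_s: np.ndarray
    F405: np.ndarray
    F465: np.ndarray
    sample_rate_hz: float
    sync_offset_s: float = 0.0
    mouse: str = ""
    phase: str = ""
    day: int = 0
    test: int = 0
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.time_s) == len(self.F405) == len(self.F465)):
            raise ValueError("channel lengths differ")

    @property
    def n_samples(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        return float(self.n_samples / self.sample_rate_hz)


@dataclass
class NormalizedTrace:
    """ΔF/F after per-channel normalization and isosbestic subtraction."""

    time_s: np.ndarray
    dff: np.ndarray
    sample_rate_hz: float
    session_sd: float
    provenance: dict = field(default_factory=dict)

    def smoothed(self, sigma_s: float) -> "NormalizedTrace":
        """Gaussian-smoothed copy (session_sd is kept from the unsmoothed
        trace: the peak threshold is defined on the raw subtracted signal)."""
        from scipy.ndimage import gaussian_filter1d

        sigma = sigma_s * self.sample_rate_hz
        out = gaussian_filter1d(self.dff, sigma) if sigma > 0 else self.dff.copy()
        prov = dict(self.provenance)
        prov["smooth_sigma_s"] = sigma_s
        return NormalizedTrace(self.time_s, out, self.sample_rate_hz,
                               self.session_sd, prov)


@dataclass
class PeriEventMatrix:
    """Trials x time matrix of ΔF/F aligned to a behavioral event at t = 0."""

    align_event: str
    time_s: np.ndarray            # relative grid, [-pre, post)
    matrix: np.ndarray            # (n_trials, n_bins), NaN where unavailable
    outcomes: list                # per-row outcome label
    trial_idx: list               # per-row source trial index
    complete: np.ndarray          # per-row bool, False if window clipped
    sample_rate_hz: float = 0.0

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    def group_mean(self, outcome: Optional[str] = None,
                   complete_only: bool = True):
        """Mean and SEM across rows (optionally one outcome class).

        Returns (mean, sem, n_rows); both arrays are NaN where no row
        contributes.
        """
        rows = np.ones(self.n_trials, dtype=bool)
        if outcome is not None:
            rows &= np.asarray([o == outcome for o in self.outcomes])
        if complete_only:
            rows &= self.complete
        sub = self.matrix[rows]
        n = sub.shape[0]
        if n == 0:
            empty = np.full(self.n_bins, np.nan)
            return empty, empty.copy(), 0
        mean = np.nanmean(sub, axis=0)
        if n > 1:
            sem = np.nanstd(sub, axis=0, ddof=1) / np.sqrt(n)
        else:
            sem = np.full(self.n_bins, np.nan)
        return mean, sem, n


@dataclass
class PoseTrack:
    """Per-frame body-part coordinates with tracking confidence.

    ``data`` has a two-level column index (bodypart, {x, y, likelihood}) and
    one row per frame; ``time_s`` gives each frame's timestamp.
    """

    frame_rate_hz: float
    data: pd.DataFrame

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    @property
    def bodyparts(self) -> list:
        return list(self.data.columns.get_level_values(0).unique())


@dataclass
class OccupancyMap:
    """Normalized 2D visit-fraction histogram for one body part."""

    part: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    H: np.ndarray          # shape (n_x_bins, n_y_bins), sums to 1
    n_frames: int
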