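"""Body-part tracking tables: occupancy maps, distance-to-target series, and
their correlation with the calcium trace.

Pose files follow the common pose-estimation export layout (two header rows:
bodypart, then x/y/likelihood per part) in image coordinates (origin
top-left, y downward); frames below the confidence threshold are masked per
part, never interpolated.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import NormalizedTrace, OccupancyMap, PoseTrack
from .errors import FormatError

DEFAULT_MIN_CONFIDENCE = 0.6


def read_pose(path: str, min_confidence: float = DEFAULT_MIN_CONFIDENCE,
              frame_rate_hz: Optional[float] = None) -> PoseTrack:
    """Read a pose CSV; coordinates with likelihood < min_confidence are
    masked (set to NaN). A leading scorer header row, as written by some
    exporters, is tolerated."""
    with open(path) as fh:
        raw = fh.read().splitlines()
    meta = {}
    data_lines = []
    for ln in raw:
        if ln.startswith("#"):
            body = ln.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
        else:
            data_lines.append(ln)
    if not data_lines:
        raise FormatError(f"pose file {path} is empty")

    import io
    # skip a scorer row if present (three header rows instead of two)
    first_fields = data_lines[0].split(",")
    header_rows = [0, 1]
    if first_fields and first_fields[0].strip().lower() == "scorer":
        header_rows = [1, 2]
        data_lines = data_lines[1:]
    try:
        df = pd.read_csv(io.StringIO("\n".join(data_lines)),
                         header=[0, 1], index_col=0)
    except Exception as exc:
        raise FormatError(f"unrecognized pose layout in {path}: {exc}") from exc
    coords = set(df.columns.get_level_values(1))
    if not {"x", "y", "likelihood"} <= coords:
        raise FormatError(f"pose file {path} lacks x/y/likelihood columns")

    df = df.astype(float)
    for part in df.columns.get_level_values(0).unique():
        bad = df[(part, "likelihood")] < min_confidence
        df.loc[bad, (part, "x")] = np.nan
        df.loc[bad, (part, "y")] = np.nan
    if frame_rate_hz is None:
        frame_rate_hz = float(meta.get("frame_rate_hz", 30.0))
    return PoseTrack(frame_rate_hz=frame_rate_hz, data=df.reset_index(drop=True))


def masked_fraction(track: PoseTrack, part: str) -> float:
    x = track.data[(part, "x")]
    return float(x.isna().mean())


def occupancy_map(track: PoseTrack, part: str, bins: int = 20,
                  extent: Optional[tuple[float, float, float, float]] = None
                  ) -> OccupancyMap:
    """Normalized 2D visit-fraction histogram of one body part.

    ``extent`` is (x_min, x_max, y_min, y_max); by default the data range.
    Raises ValueError when every frame is masked.
    """
    x = track.data[(part, "x")].to_numpy()
    y = track.data[(part, "y")].to_numpy()
    ok = ~(np.isnan(x) | np.isnan(y))
    if not ok.any():
        raise ValueError(f"no unmasked frames for body part {part!r}")
    rng = None
    if extent is not None:
        rng = [[extent[0], extent[1]], [extent[2], extent[3]]]
    H, xe, ye = np.histogram2d(x[ok], y[ok], bins=bins, range=rng)
    H = H / H.sum()
    return OccupancyMap(part=part, x_edges=xe, y_edges=ye, H=H,
                        n_frames=int(ok.sum()))


def distance_to_target(track: PoseTrack, part: str,
                       target_xy: tuple[float, float]) -> pd.Series:
    """Per-frame Euclidean distance from a body part to a fixed target
    (spout or lever); masked frames are NaN. Indexed by frame time."""
    x = track.data[(part, "x")].to_numpy()
    y = track.data[(part, "y")].to_numpy()
    d = np.hypot(x - target_xy[0], y - target_xy[1])
    return pd.Series(d, index=track.time_s, name=f"distance_{part}")


def resample_to_grid(series: pd.Series, grid_s: np.ndarray) -> np.ndarray:
    """Linear interpolation of a (possibly gappy) frame-indexed series onto a
    photometry time grid; NaN outside the covered span or inside all-masked
    stretches longer than two frames."""
    t = series.index.to_numpy(dtype=float)
    v = series.to_numpy(dtype=float)
    ok = ~np.isnan(v)
    if ok.sum() < 2:
        return np.full(len(grid_s), np.nan)
    out = np.interp(grid_s, t[ok], v[ok], left=np.nan, right=np.nan)
    # blank long masked gaps rather than bridging them
    dt = np.median(np.diff(t))
    tok = t[ok]
    gaps = np.flatnonzero(np.diff(tok) > 2.5 * dt)
    for g in gaps:
        out[(grid_s > tok[g]) & (grid_s < tok[g + 1])] = np.nan
    return out


def correlate_with_calcium(distance: pd.Series, trace: NormalizedTrace,
                           method: str = "spearman", n_shuffle: int = 200,
                           min_shift_s: float = 1.0,
                           rng: Optional[np.random.Generator] = None) -> dict:
    """Correlation between a distance series and ΔF/F on the common grid.

    The null distribution preserves autocorrelation by circularly shifting
    the distance series (never by less than ``min_shift_s``) rather than
    i.i.d. shuffling. A constant input yields r = NaN (undefined), not 0.
    Returns {'r', 'p', 'n', 'method'}.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    d = resample_to_grid(distance, trace.time_s)
    ok = ~np.isnan(d)
    n = int(ok.sum())
    if n < 10:
        raise ValueError(f"only {n} overlapping samples; need >= 10")
    d_ok, f_ok = d[ok], trace.dff[ok]
    if np.ptp(d_ok) == 0 or np.ptp(f_ok) == 0:
        return {"r": np.nan, "p": np.nan, "n": n, "method": method}

    corr = (stats.spearmanr if method == "spearman"
            else lambda a, b: stats.pearsonr(a, b))
    r = float(corr(d_ok, f_ok)[0])

    min_shift = max(1, int(round(min_shift_s * trace.sample_rate_hz)))
    if min_shift >= n:
        raise ValueError("series too short for the circular-shift null")
    null = np.empty(n_shuffle)
    for k in range(n_shuffle):
        shift = int(rng.integers(min_shift, n - min_shift + 1))
        null[k] = corr(np.roll(d_ok, shift), f_ok)[0]
    p = float((np.sum(np.abs(null) >= abs(r)) + 1) / (n_shuffle + 1))
    return {"r": r, "p": p, "n": n, "method": method}
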