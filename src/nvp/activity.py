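"""Home-cage activity from pose-tracking tables.

Pose-estimation exports (frame, label, x, y, likelihood) are filtered by
label likelihood, converted to per-frame displacement of the mouse centroid
plus the wheel marker, summed over 10-minute windows, trimmed of the top
and bottom 1% of the window distribution (tracking-failure outliers), and
aggregated to daily totals and per-clock-hour means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MOUSE_LABELS = ("head", "left_headplate", "right_headplate", "tail")
WHEEL_LABELS = ("wheel_inner", "wheel_outer")


def read_pose_csv(path) -> pd.DataFrame:
    """Read a pose table: tidy (frame,label,x,y,likelihood) or the common
    3-row multi-header export layout (scorer / bodyparts / coords)."""
    head = pd.read_csv(path, nrows=4, header=None)
    if str(head.iloc[0, 0]).lower() in ("frame", "0") and "label" in head.iloc[0].values:
        return pd.read_csv(path)
    first_cell = str(head.iloc[0, 0]).lower()
    if first_cell in ("scorer",):
        wide = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        rows = []
        for bp in wide.columns.get_level_values(1).unique():
            sub = wide.xs(bp, axis=1, level=1)
            sub.columns = sub.columns.get_level_values(-1)
            for frame, r in sub.iterrows():
                rows.append((int(frame), bp, r["x"], r["y"], r["likelihood"]))
        return pd.DataFrame(rows, columns=["frame", "label", "x", "y",
                                           "likelihood"])
    return pd.read_csv(path)


def filter_tracking(table: pd.DataFrame,
                    likelihood_threshold: float = 1.0) -> tuple[pd.DataFrame, float]:
    """Drop rows with likelihood below the threshold.

    The default threshold of 1.0 keeps only perfectly confident labels —
    deliberately strict; the removed fraction is returned so its effect is
    visible.  Raises if nothing survives.
    """
    keep = table["likelihood"] >= likelihood_threshold
    removed = 1.0 - keep.mean() if len(table) else 0.0
    out = table[keep].reset_index(drop=True)
    if out.empty:
        raise ValueError(
            f"likelihood threshold {likelihood_threshold} removed every row; "
            "review the threshold")
    return out, float(removed)


def frame_distance(table: pd.DataFrame, px_per_cm: float,
                   n_frames: int | None = None) -> np.ndarray:
    """Per-frame travelled distance in cm.

    Mouse centroid = mean of available body-part labels per frame; wheel
    marker = mean of available wheel labels.  Per-frame distance =
    |delta centroid| + |delta wheel|; frames lacking one of the two
    contribute only the other, and gaps from filtered frames are bridged by
    differencing across the gap.
    """
    if px_per_cm <= 0:
        raise ValueError("px_per_cm must be positive")
    frames = table["frame"].to_numpy()
    if n_frames is None:
        n_frames = int(frames.max()) + 1 if len(frames) else 0

    def centroid_series(labels):
        sub = table[table["label"].isin(labels)]
        g = sub.groupby("frame")[["x", "y"]].mean()
        return g

    dist = np.zeros(n_frames)
    for labels in (MOUSE_LABELS, WHEEL_LABELS):
        g = centroid_series(labels)
        if len(g) < 2:
            continue
        idx = g.index.to_numpy()
        xy = g[["x", "y"]].to_numpy()
        step = np.linalg.norm(np.diff(xy, axis=0), axis=1) / px_per_cm
        # attribute each displacement to the later frame of the pair
        dist_frames = idx[1:]
        dist[dist_frames[dist_frames < n_frames]] += \
            step[dist_frames < n_frames]
    return dist


@dataclass
class ActivitySummary:
    window_sums: np.ndarray        # cm per 10-min window (untrimmed)
    retained_windows: np.ndarray   # bool per window after trimming
    daily_totals: np.ndarray       # cm per complete 24 h day
    hourly_means: np.ndarray       # cm per hour-of-day (24,)
    frames_used_fraction: float


def summarize_activity(per_frame_cm: np.ndarray, fps: float,
                       window_min: float = 10.0, trim: float = 0.01,
                       frames_used_fraction: float = 1.0) -> ActivitySummary:
    """10-minute window sums, 1%-trimmed, with daily totals and an
    hour-of-day profile.

    Trimming removes floor(trim * n_windows) windows from each tail of the
    window-sum distribution (so with fewer than 1/trim windows nothing is
    removed — warned).  Daily totals and hourly means use surviving windows
    only; enlarging the trim can therefore never increase a daily total.
    """
    frames_per_window = int(round(window_min * 60 * fps))
    n_win = len(per_frame_cm) // frames_per_window
    if n_win < 1:
        raise ValueError("need at least one complete 10-minute window")
    sums = per_frame_cm[: n_win * frames_per_window] \
        .reshape(n_win, frames_per_window).sum(axis=1)

    k = int(np.floor(trim * n_win))
    retained = np.ones(n_win, dtype=bool)
    if k == 0 and trim > 0:
        log.warning("only %d windows; %.0f%% trim removes none", n_win,
                    100 * trim)
    if k > 0:
        order = np.argsort(sums, kind="stable")
        retained[order[:k]] = False
        retained[order[-k:]] = False

    windows_per_day = int(round(24 * 60 / window_min))
    n_days = n_win // windows_per_day
    daily = []
    for d in range(n_days):
        sl = slice(d * windows_per_day, (d + 1) * windows_per_day)
        daily.append(sums[sl][retained[sl]].sum())
    daily = np.array(daily)

    windows_per_hour = max(int(round(60 / window_min)), 1)
    hourly = np.zeros(24)
    counts = np.zeros(24)
    for w in range(n_win):
        if not retained[w]:
            continue
        hour = (w // windows_per_hour) % 24
        hourly[hour] += sums[w]
        counts[hour] += 1.0 / windows_per_hour  # hours of data in this bin
    with np.errstate(invalid="ignore", divide="ignore"):
        hourly_means = np.where(counts > 0, hourly / counts, np.nan)

    return ActivitySummary(window_sums=sums, retained_windows=retained,
                           daily_totals=daily, hourly_means=hourly_means,
                           frames_used_fraction=frames_used_fraction)
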