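"""Baseline behavioural metrics: occupancy entropy and activity.

Exploration is quantified as the Shannon entropy (base 2) of an ant's
occupancy over a square grid tiling the arena (default 25 x 25 bins of
2 x 2 mm, about one body length per bin):

    H = -sum_x p(x) * log2 p(x)

where p(x) is the proportion of frames spent in bin x. H is 0 for an ant
that never leaves one cell and log2(625) ~ 9.288 bits for perfectly uniform
use of the full grid.

Activity is measured from per-frame speeds (Euclidean displacement times
fps): the proportion of frames moving faster than 1 mm/s, and the mean
duration of active bouts (maximal runs of consecutive active frames).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GridSpec", "compute_entropy", "compute_activity", "baseline_metrics"]


@dataclass(frozen=True)
class GridSpec:
    """Square occupancy grid centred on the arena."""

    bins_per_side: int = 25
    bin_size: float = 2.0
    center: tuple[float, float] = (0.0, 0.0)

    @property
    def half_extent(self) -> float:
        return self.bins_per_side * self.bin_size / 2.0

    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        h = self.half_extent
        ex = np.linspace(self.center[0] - h, self.center[0] + h, self.bins_per_side + 1)
        ey = np.linspace(self.center[1] - h, self.center[1] + h, self.bins_per_side + 1)
        return ex, ey


def compute_entropy(
    x: np.ndarray, y: np.ndarray, grid: GridSpec = GridSpec()
) -> float:
    """Shannon entropy (bits) of the occupancy distribution of one ant.

    Frames are assigned to the grid cell containing their position;
    positions outside the grid square (should not occur after
    preprocessing) are clamped into the nearest edge cell. Returns NaN if
    no finite positions remain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if not ok.any():
        return float("nan")
    ex, ey = grid.edges()
    eps = 1e-9
    xc = np.clip(x[ok], ex[0] + eps, ex[-1] - eps)
    yc = np.clip(y[ok], ey[0] + eps, ey[-1] - eps)
    counts, _, _ = np.histogram2d(xc, yc, bins=[ex, ey])
    p = counts[counts > 0].ravel()
    p = p / p.sum()
    return float(-(p * np.log2(p)).sum())


def _segment_bounds(frames: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index ranges of runs of consecutive frame numbers."""
    if len(frames) == 0:
        return []
    breaks = np.flatnonzero(np.diff(frames) != 1) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [len(frames)]))
    return list(zip(starts, ends))


def compute_activity(
    frames: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    fps: float = 20.0,
    speed_threshold: float = 1.0,
) -> tuple[float, float, int]:
    """Proportion of time active and mean active-bout duration for one ant.

    A frame is active iff its speed (displacement from the previous frame
    within the same contiguous segment, times fps) exceeds
    ``speed_threshold`` (mm/s). The first frame of each contiguous segment
    has no defined speed and is excluded from the denominator. A bout is a
    maximal run of consecutive active frames; an ant with no bouts gets
    mean bout 0. Returns (prop_active, mean_bout_seconds, n_classified);
    metrics are NaN when fewer than 2 consecutive frames exist.
    """
    frames = np.asarray(frames)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(frames)
    frames, x, y = frames[order], x[order], y[order]

    active_runs: list[int] = []
    n_classified = 0
    n_active = 0
    for a, b in _segment_bounds(frames):
        if b - a < 2:
            continue
        speed = np.hypot(np.diff(x[a:b]), np.diff(y[a:b])) * fps
        act = speed > speed_threshold
        n_classified += len(act)
        n_active += int(act.sum())
        # run lengths of consecutive active frames
        padded = np.concatenate(([False], act, [False]))
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        active_runs.extend((ends - starts).tolist())

    if n_classified == 0:
        return float("nan"), float("nan"), 0
    prop_active = n_active / n_classified
    mean_bout = (float(np.mean(active_runs)) / fps) if active_runs else 0.0
    return prop_active, mean_bout, n_classified


def baseline_metrics(
    traj: pd.DataFrame,
    grid: GridSpec = GridSpec(),
    fps: float = 20.0,
    speed_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-ant baseline metrics from a (preprocessed) trajectory table.

    Returns one row per (colony_id, ant_id) with columns ``entropy``,
    ``prop_active``, ``mean_bout`` and ``n_classified``.
    """
    rows = []
    for (colony, ant), g in traj.groupby(["colony_id", "ant_id"], sort=True):
        h = compute_entropy(g["x"].to_numpy(), g["y"].to_numpy(), grid)
        prop, bout, n = compute_activity(
            g["frame"].to_numpy(), g["x"].to_numpy(), g["y"].to_numpy(),
            fps=fps, speed_threshold=speed_threshold,
        )
        rows.append(
            {
                "colony_id": colony,
                "ant_id": ant,
                "entropy": h,
                "prop_active": prop,
                "mean_bout": bout,
                "n_classified": n,
            }
        )
    return pd.DataFrame(rows)
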