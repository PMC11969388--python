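"""Trajectory table I/O and preprocessing.

Tracking output is a per-frame position table (colony_id, ant_id, frame,
x, y) at fixed frame rate; detections can be missing (NaN coordinates or
absent rows) or aberrant (physically impossible jumps). Preprocessing
classifies every frame of each ant's record as kept, interpolated or
removed:

* a position implying a speed above ``v_max`` from the last accepted
  position is aberrant and treated as missing;
* runs of at most ``max_gap`` consecutive missing frames bounded by
  accepted positions are filled by linear interpolation;
* longer runs (and unbounded leading/trailing runs) are removed.

The operation is idempotent and returns a per-ant report of what happened
to every frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "read_trajectories",
    "write_trajectories",
    "preprocess",
    "PreprocessReport",
]

REQUIRED_COLUMNS = ("colony_id", "ant_id", "frame", "x", "y")


def read_trajectories(path, offset: tuple[float, float] | None = None) -> pd.DataFrame:
    """Read a trajectory CSV into a typed table.

    Unparseable or empty coordinates become NaN (missing detections), not
    dropped rows. ``offset`` is subtracted from (x, y), converting e.g. a
    pixel-corner origin to arena-centred coordinates. Duplicate
    (colony, ant, frame) rows violate the table contract and raise.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file {path} is missing required column(s): {missing}")
    df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    df["frame"] = df["frame"].astype(np.int64)
    df["x"] = pd.to_numeric(df["x"], errors="coerce").astype(float)
    df["y"] = pd.to_numeric(df["y"], errors="coerce").astype(float)
    if offset is not None:
        df["x"] -= offset[0]
        df["y"] -= offset[1]
    dup = df.duplicated(subset=["colony_id", "ant_id", "frame"])
    if dup.any():
        first = df.loc[dup.idxmax(), ["colony_id", "ant_id", "frame"]].tolist()
        raise ValueError(f"duplicated (colony, ant, frame) rows, first at {first}")
    return df


def write_trajectories(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


@dataclass
class PreprocessReport:
    """Per-ant accounting of preprocessing.

    For each (colony, ant): ``n_frames`` spanned frames, ``n_kept`` valid
    positions accepted as-is, ``n_aberrant`` positions rejected on the
    speed criterion, ``n_missing`` frames with no accepted detection
    (missing input + aberrant + absent rows in the spanned range),
    ``n_interpolated`` of those filled, ``n_removed`` left absent.
    ``n_kept + n_interpolated + n_removed == n_frames`` always.
    """

    per_ant: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def totals(self) -> dict:
        cols = ["n_frames", "n_kept", "n_aberrant", "n_missing", "n_interpolated", "n_removed"]
        return {c: int(self.per_ant[c].sum()) for c in cols}

    def to_json(self, path) -> None:
        payload = {
            "params": self.params,
            "totals": self.totals,
            "per_ant": self.per_ant.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _flag_aberrant(frames: np.ndarray, x: np.ndarray, y: np.ndarray,
                   valid: np.ndarray, v_max: float, fps: float) -> np.ndarray:
    """Sequentially reject positions implying speed > v_max from the last
    accepted position. Returns a boolean mask of aberrant frames."""
    aberrant = np.zeros(len(frames), dtype=bool)
    idx = np.flatnonzero(valid)
    if len(idx) == 0:
        return aberrant
    # fast path: all consecutive-valid speeds within bound
    fi = frames[idx]
    d = np.hypot(np.diff(x[idx]), np.diff(y[idx]))
    dt = np.diff(fi) / fps
    if not (d > v_max * dt).any():
        return aberrant
    last = idx[0]
    for i in idx[1:]:
        dt_i = (frames[i] - frames[last]) / fps
        dist = float(np.hypot(x[i] - x[last], y[i] - y[last]))
        if dist > v_max * dt_i:
            aberrant[i] = True
        else:
            last = i
    return aberrant


def _preprocess_one(
    g: pd.DataFrame, max_gap: int, v_max: float, fps: float,
    arena_diameter: float | None,
) -> tuple[pd.DataFrame, dict]:
    frames_in = g["frame"].to_numpy()
    lo, hi = int(frames_in.min()), int(frames_in.max())
    full = np.arange(lo, hi + 1)
    x = np.full(len(full), np.nan)
    y = np.full(len(full), np.nan)
    pos = frames_in - lo
    x[pos] = g["x"].to_numpy()
    y[pos] = g["y"].to_numpy()

    valid = np.isfinite(x) & np.isfinite(y)
    if arena_diameter is not None:
        r = np.hypot(x, y)
        outside = valid & (r > arena_diameter / 2.0 + 1e-9)
    else:
        outside = np.zeros(len(full), dtype=bool)
    aberrant = _flag_aberrant(full, x, y, valid & ~outside, v_max, fps) | outside
    accepted = valid & ~aberrant
    x = np.where(accepted, x, np.nan)
    y = np.where(accepted, y, np.nan)

    # fill short gaps bounded by accepted positions
    interpolated = np.zeros(len(full), dtype=bool)
    acc_idx = np.flatnonzero(accepted)
    for a, b in zip(acc_idx[:-1], acc_idx[1:]):
        gap = b - a - 1
        if 0 < gap <= max_gap:
            t = np.arange(a + 1, b)
            x[t] = np.interp(t, [a, b], [x[a], x[b]])
            y[t] = np.interp(t, [a, b], [y[a], y[b]])
            interpolated[t] = True

    kept_mask = accepted | interpolated
    removed = ~kept_mask
    out = pd.DataFrame(
        {
            "colony_id": g["colony_id"].iloc[0],
            "ant_id": g["ant_id"].iloc[0],
            "frame": full[kept_mask],
            "x": x[kept_mask],
            "y": y[kept_mask],
            "interpolated": interpolated[kept_mask],
        }
    )
    report = {
        "colony_id": g["colony_id"].iloc[0],
        "ant_id": g["ant_id"].iloc[0],
        "n_frames": len(full),
        "n_kept": int(accepted.sum()),
        "n_aberrant": int(aberrant.sum()),
        "n_missing": int((~accepted).sum()),
        "n_interpolated": int(interpolated.sum()),
        "n_removed": int(removed.sum()),
    }
    return out, report


def preprocess(
    traj: pd.DataFrame,
    max_gap: int = 10,
    v_max: float = 50.0,
    fps: float = 20.0,
    arena_diameter: float | None = None,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Clean a trajectory table; see module docstring for the contract.

    Parameters
    ----------
    max_gap
        Longest run of consecutive missing frames (default 10 = 0.5 s at
        20 fps) that is linearly interpolated; longer runs are removed.
    v_max
        Aberrance threshold in mm/s (default 50, roughly 20 body lengths/s).
    arena_diameter
        If given, accepted positions must also lie inside the arena.

    Returns the cleaned table (with an ``interpolated`` flag column) and a
    :class:`PreprocessReport`.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if v_max <= 0:
        raise ValueError("v_max must be > 0")
    if traj.empty:
        empty = traj.iloc[0:0].copy()
        empty["interpolated"] = pd.Series(dtype=bool)
        return empty, PreprocessReport(
            per_ant=pd.DataFrame(
                columns=["colony_id", "ant_id", "n_frames", "n_kept", "n_aberrant",
                         "n_missing", "n_interpolated", "n_removed"]
            ),
            params={"max_gap": max_gap, "v_max": v_max, "fps": fps},
        )
    outs, reports = [], []
    for _, g in traj.groupby(["colony_id", "ant_id"], sort=True):
        o, r = _preprocess_one(g, max_gap, v_max, fps, arena_diameter)
        outs.append(o)
        reports.append(r)
    cleaned = pd.concat(outs, ignore_index=True)
    report = PreprocessReport(
        per_ant=pd.DataFrame(reports),
        params={"max_gap": max_gap, "v_max": v_max, "fps": fps,
                "arena_diameter": arena_diameter},
    )
    return cleaned, report
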