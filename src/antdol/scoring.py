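"""Defence-event aggregation and the per-ant defence score.

Events are timed annotations per ant per trial: *encounters* (point
contacts with the intruder) and *stings* (stereotyped stinging attempts
with a duration in seconds). The per-ant defence score is

    score = (n_stings / n_encounters) * ln(1 + total sting seconds)

The sting count is normalised by encounters so the score measures the
propensity to attack per contact rather than contact opportunity; the
logarithm stops very long stings from dominating. Ants that never stung
score 0, and ants that never encountered the intruder are assigned 0.

The simpler normalised sting rate (n_stings / n_encounters) is kept as a
comparison metric. Colony-level defence efficiency is the total number of
stings the intruder received across all trials.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_COLUMNS",
    "read_events",
    "aggregate_events",
    "defence_score",
    "norm_sting_rate",
    "score_records",
    "pooled_scores",
    "colony_mean_score",
    "colony_efficiency",
]

EVENT_COLUMNS = ("colony_id", "trial", "ant_id", "event_type", "onset", "offset")
EVENT_TYPES = ("encounter", "sting")

#: column mapping for a minimal BORIS-style export dialect
BORIS_DIALECT = {
    "subject": "ant_id",
    "behavior": "event_type",
    "start": "onset",
    "stop": "offset",
}


def read_events(
    path,
    dialect: dict[str, str] | None = None,
    trial_duration: float | None = None,
    behaviour_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read an event CSV in the native schema or a mapped dialect.

    ``dialect`` maps file column names to the native names (see
    ``BORIS_DIALECT`` for a minimal BORIS-export-like mapping; the file
    must still carry colony_id and trial columns, possibly via the
    mapping). ``behaviour_map`` renames annotation labels onto
    {encounter, sting}. Rows violating the event invariants
    (0 <= onset <= offset <= trial_duration, known event type) raise.
    """
    df = pd.read_csv(path)
    if dialect:
        df = df.rename(columns=dialect)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event file {path} is missing required column(s): {missing}")
    df = df.loc[:, list(EVENT_COLUMNS)].copy()
    if behaviour_map:
        df["event_type"] = df["event_type"].map(lambda b: behaviour_map.get(b, b))
    df["trial"] = df["trial"].astype(int)
    df["onset"] = df["onset"].astype(float)
    df["offset"] = df["offset"].astype(float)
    bad_type = ~df["event_type"].isin(EVENT_TYPES)
    if bad_type.any():
        raise ValueError(
            f"unknown event type(s): {sorted(df.loc[bad_type, 'event_type'].unique())}"
        )
    bad = (df["onset"] < 0) | (df["offset"] < df["onset"])
    if trial_duration is not None:
        bad |= df["offset"] > trial_duration
    if bad.any():
        raise ValueError(f"{int(bad.sum())} event row(s) violate 0 <= onset <= offset bounds")
    return df


def defence_score(n_stings, n_encounters, sting_seconds):
    """Per-ant defence score; vectorised over array inputs.

    ``(n_stings / n_encounters) * ln(1 + sting_seconds)``, with 0 assigned
    whenever the ant had no encounters.
    """
    s = np.asarray(n_stings, dtype=float)
    e = np.asarray(n_encounters, dtype=float)
    d = np.asarray(sting_seconds, dtype=float)
    if (s < 0).any() or (e < 0).any() or (d < 0).any():
        raise ValueError("counts and durations must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(e > 0, np.divide(s, np.where(e > 0, e, 1.0)) * np.log1p(d), 0.0)
    return out if out.ndim else float(out)


def norm_sting_rate(n_stings, n_encounters):
    """Normalised sting rate n_stings / n_encounters (0 when no encounters)."""
    s = np.asarray(n_stings, dtype=float)
    e = np.asarray(n_encounters, dtype=float)
    if (s < 0).any() or (e < 0).any():
        raise ValueError("counts must be non-negative")
    out = np.where(e > 0, np.divide(s, np.where(e > 0, e, 1.0)), 0.0)
    return out if out.ndim else float(out)


def aggregate_events(
    events: pd.DataFrame, roster: pd.DataFrame, n_trials: int = 3
) -> pd.DataFrame:
    """Per (colony, trial, ant) counts: n_encounters, n_stings, sting_seconds.

    Every roster ant appears in every trial, with (0, 0, 0) if it logged no
    events. Events referencing an ant or colony absent from the roster are
    a hard error.
    """
    key = ["colony_id", "ant_id"]
    roster = roster.loc[:, key].drop_duplicates()
    if not events.empty:
        known = set(map(tuple, roster.itertuples(index=False)))
        ev_ids = set(map(tuple, events.loc[:, key].drop_duplicates().itertuples(index=False)))
        unknown = ev_ids - known
        if unknown:
            raise ValueError(f"events reference unknown (colony, ant): {sorted(unknown)[:5]}")

    grid = roster.merge(pd.DataFrame({"trial": np.arange(1, n_trials + 1)}), how="cross")
    if events.empty:
        agg = pd.DataFrame(columns=key + ["trial", "n_encounters", "n_stings", "sting_seconds"])
    else:
        ev = events.copy()
        ev["duration"] = ev["offset"] - ev["onset"]
        agg = (
            ev.assign(
                is_enc=(ev["event_type"] == "encounter"),
                is_sting=(ev["event_type"] == "sting"),
                sting_dur=np.where(ev["event_type"] == "sting", ev["duration"], 0.0),
            )
            .groupby(key + ["trial"], as_index=False)
            .agg(
                n_encounters=("is_enc", "sum"),
                n_stings=("is_sting", "sum"),
                sting_seconds=("sting_dur", "sum"),
            )
        )
    out = grid.merge(agg, on=key + ["trial"], how="left")
    for c in ("n_encounters", "n_stings"):
        out[c] = pd.to_numeric(out[c], errors="coerce").fillna(0).astype(int)
    out["sting_seconds"] = pd.to_numeric(out["sting_seconds"], errors="coerce").fillna(0.0)
    return out.sort_values(["colony_id", "trial", "ant_id"]).reset_index(drop=True)


def score_records(aggregates: pd.DataFrame) -> pd.DataFrame:
    """Attach defence score and normalised sting rate to aggregates.

    Also flags records where n_stings > n_encounters (repeated stings
    within one contact are legal but worth surfacing).
    """
    out = aggregates.copy()
    out["score"] = defence_score(
        out["n_stings"], out["n_encounters"], out["sting_seconds"]
    )
    out["norm_sting_rate"] = norm_sting_rate(out["n_stings"], out["n_encounters"])
    out["stings_exceed_encounters"] = out["n_stings"] > out["n_encounters"]
    return out


def pooled_scores(aggregates: pd.DataFrame) -> pd.DataFrame:
    """Pool counts across trials per ant, then score the pooled sums.

    Returns records with ``trial = "pooled"``.
    """
    pooled = (
        aggregates.groupby(["colony_id", "ant_id"], as_index=False)
        .agg(
            n_encounters=("n_encounters", "sum"),
            n_stings=("n_stings", "sum"),
            sting_seconds=("sting_seconds", "sum"),
        )
        .assign(trial="pooled")
    )
    return score_records(
        pooled[["colony_id", "ant_id", "trial", "n_encounters", "n_stings", "sting_seconds"]]
    )


def colony_mean_score(records: pd.DataFrame, roster: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean score over all colony members, per trial.

    Zeros count. A colony member missing from the records is a hard error.
    """
    counts = roster.groupby("colony_id")["ant_id"].nunique()
    got = records.groupby(["colony_id", "trial"])["ant_id"].nunique()
    for (colony, trial), n in got.items():
        if n != counts.get(colony, 0):
            raise ValueError(
                f"colony {colony} trial {trial}: {n} records for "
                f"{counts.get(colony, 0)} members"
            )
    return (
        records.groupby(["colony_id", "trial"], as_index=False)["score"]
        .mean()
        .rename(columns={"score": "mean_score"})
    )


def colony_efficiency(events: pd.DataFrame, design: pd.DataFrame | None = None) -> pd.DataFrame:
    """Total stings received by the intruder per colony across all trials.

    With a design table, colonies that never stung are listed with 0.
    """
    if events.empty:
        out = pd.DataFrame(columns=["colony_id", "total_stings"])
    else:
        stings = events[events["event_type"] == "sting"]
        out = stings.groupby("colony_id").size().rename("total_stings").reset_index()
    if design is not None:
        out = design[["colony_id"]].merge(out, on="colony_id", how="left")
    out["total_stings"] = (
        pd.to_numeric(out["total_stings"], errors="coerce").fillna(0).astype(int)
    )
    return out
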