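"""Synthetic colony-defence experiments.

The generative model has three layers:

1. **Individual heterogeneity** — each ant carries a latent response
   threshold ``theta_i`` (log-normal) and an activity propensity ``a_i``
   (log-normal, median 1). The two are jointly Gaussian on the log scale;
   a positive ``coupling`` makes more-active ants more aggressive (lower
   threshold), the default ``coupling = 0`` decouples them.
2. **Baseline movement** — a two-state (inactive/active) correlated random
   walk inside a circular arena with reflecting boundary. Active ants step
   at their characteristic speed with a persistent, diffusing heading;
   inactive ants do not move. Switching probabilities scale with ``a_i``.
3. **Defence trials** — intruder encounters arrive as a Poisson process at
   a rate proportional to ``a_i``; at each encounter the ant stings with
   Hill-type probability ``s**h / (s**h + theta_i**h)``; sting durations
   are exponential.

All randomness flows from ``numpy.random.SeedSequence(scenario.seed)`` so a
scenario + seed reproduces every table bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenario import SimScenario, design_table

__all__ = [
    "draw_individuals",
    "sting_probability",
    "simulate_baseline_trajectory",
    "simulate_defence_trial",
    "simulate_experiment",
    "SimulatedExperiment",
]

_CHUNK_FRAMES = 4000  # frame-loop RNG is pre-drawn in chunks of this many frames


def sting_probability(stimulus: float, theta, steepness: float):
    """Hill-type response-threshold function P(sting | encounter).

    Equals 0.5 when the stimulus matches the threshold exactly; approaches a
    step function as ``steepness`` grows.
    """
    theta = np.asarray(theta, dtype=float)
    s = float(stimulus) ** steepness
    return s / (s + theta**steepness)


def draw_individuals(
    scenario: SimScenario, n_ants: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw per-ant latent parameters for one colony.

    Returns a frame with columns ``theta`` (response threshold),
    ``activity`` (propensity ``a_i``), ``p_on``/``p_off`` (per-frame state
    switching), ``speed`` (active speed, mm/s) and ``p_sting``.

    ``log a_i`` and ``-log theta_i`` are jointly Gaussian at correlation
    ``coupling``; switching-on probability scales with ``a_i``, switching-off
    with ``1/a_i``, speed with ``sqrt(a_i)``.
    """
    if n_ants <= 0:
        raise ValueError("n_ants must be positive")
    rho = scenario.coupling
    u = rng.standard_normal(n_ants)
    w = rng.standard_normal(n_ants)
    v = rho * u + np.sqrt(1.0 - rho**2) * w
    activity = np.exp(scenario.activity_sd * u)
    theta = np.exp(np.log(scenario.threshold_mean) - scenario.threshold_sd * v)
    p_on = np.clip(scenario.p_active_on * activity, 0.0, 1.0)
    p_off = np.clip(scenario.p_active_off / activity, 0.0, 1.0)
    speed = scenario.speed_active_mean * np.sqrt(activity)
    return pd.DataFrame(
        {
            "theta": theta,
            "activity": activity,
            "p_on": p_on,
            "p_off": p_off,
            "speed": speed,
            "p_sting": sting_probability(scenario.stimulus, theta, scenario.threshold_steepness),
        }
    )


def _reflect_radial(x: np.ndarray, y: np.ndarray, radius: float) -> None:
    """Fold points outside the circle back across the boundary, in place."""
    r = np.hypot(x, y)
    out = r > radius
    if out.any():
        scale = (2.0 * radius - r[out]) / r[out]
        # a pathological step > 2*radius would fold past the centre; clamp
        scale = np.clip(scale, -1.0, 1.0)
        x[out] *= scale
        y[out] *= scale


def simulate_baseline_trajectory(
    scenario: SimScenario,
    ants: pd.DataFrame,
    rng: np.random.Generator,
    colony_id: str = "c01",
    ant_ids: list[str] | None = None,
    colony_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate the tracked baseline hour for a batch of ants.

    The batch may span several colonies (``colony_ids`` aligned with the
    rows of ``ants``); ants do not interact at baseline, so batching only
    amortises the frame loop.

    The walk is advanced frame by frame for all ants at once: inactive ants
    hold position exactly; active ants step ``speed/fps`` along a heading
    that diffuses with per-frame s.d. ``turn_sd``; the circular wall
    reflects. Optional detection dropouts (``missing_rate`` -> NaN
    coordinates) and aberrant jumps (``jump_rate`` -> teleport to a random
    arena point) exercise downstream preprocessing.

    Returns a trajectory table (colony_id, ant_id, frame, x, y).
    """
    n = len(ants)
    if ant_ids is None:
        ant_ids = [f"{colony_id}_a{k}" for k in range(1, n + 1)]
    n_frames = int(round(scenario.baseline_duration * scenario.fps))
    radius = scenario.arena_diameter / 2.0

    p_on = ants["p_on"].to_numpy()
    p_off = ants["p_off"].to_numpy()
    step = ants["speed"].to_numpy() / scenario.fps

    # start at a uniform point in the arena with the stationary activity state
    r0 = radius * np.sqrt(rng.random(n))
    a0 = rng.random(n) * 2 * np.pi
    x = r0 * np.cos(a0)
    y = r0 * np.sin(a0)
    heading = rng.random(n) * 2 * np.pi
    with np.errstate(invalid="ignore"):
        p_stationary = np.where(p_on + p_off > 0, p_on / (p_on + p_off), 0.0)
    active = rng.random(n) < p_stationary

    xs = np.empty((n_frames, n))
    ys = np.empty((n_frames, n))
    xs[0], ys[0] = x, y

    t = 1
    while t < n_frames:
        m = min(_CHUNK_FRAMES, n_frames - t)
        u_switch = rng.random((m, n))
        turns = rng.standard_normal((m, n)) * scenario.turn_sd
        for i in range(m):
            active = np.where(active, u_switch[i] >= p_off, u_switch[i] < p_on)
            heading = heading + turns[i]
            dx = np.where(active, step * np.cos(heading), 0.0)
            dy = np.where(active, step * np.sin(heading), 0.0)
            x = x + dx
            y = y + dy
            _reflect_radial(x, y, radius)
            xs[t + i], ys[t + i] = x, y
        t += m

    if scenario.jump_rate > 0:
        jumps = rng.random((n_frames, n)) < scenario.jump_rate
        k = int(jumps.sum())
        if k:
            rj = radius * np.sqrt(rng.random(k))
            aj = rng.random(k) * 2 * np.pi
            xs[jumps] = rj * np.cos(aj)
            ys[jumps] = rj * np.sin(aj)
    if scenario.missing_rate > 0:
        drop = rng.random((n_frames, n)) < scenario.missing_rate
        xs[drop] = np.nan
        ys[drop] = np.nan

    frames = np.arange(n_frames)
    col = (
        np.repeat(np.asarray(colony_ids, dtype=object), n_frames)
        if colony_ids is not None
        else colony_id
    )
    return pd.DataFrame(
        {
            "colony_id": col,
            "ant_id": np.repeat(ant_ids, n_frames),
            "frame": np.tile(frames, n),
            "x": xs.T.ravel(),
            "y": ys.T.ravel(),
        }
    )


def simulate_defence_trial(
    scenario: SimScenario,
    ants: pd.DataFrame,
    trial: int,
    rng: np.random.Generator,
    colony_id: str = "c01",
    ant_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate one defence trial's event log for a colony.

    Encounters are point events (onset == offset); each sting is nested at
    its triggering encounter's onset with an exponential duration, clipped
    at the trial end. Rows are sorted by onset with encounters preceding
    their stings.
    """
    if not 1 <= trial <= scenario.n_trials:
        raise ValueError(f"trial must lie in 1..{scenario.n_trials}, got {trial}")
    n = len(ants)
    if ant_ids is None:
        ant_ids = [f"{colony_id}_a{k}" for k in range(1, n + 1)]
    T = scenario.trial_duration
    rate = scenario.encounter_rate_scale * ants["activity"].to_numpy() * (T / 60.0)
    n_enc = rng.poisson(rate)
    records: list[dict] = []
    for j in range(n):
        k = int(n_enc[j])
        if k == 0:
            continue
        times = np.sort(rng.random(k) * T)
        stings = rng.random(k) < ants["p_sting"].iloc[j]
        durations = rng.exponential(scenario.sting_duration_mean, size=k)
        for t, is_sting, d in zip(times, stings, durations):
            records.append(
                {
                    "colony_id": colony_id,
                    "trial": trial,
                    "ant_id": ant_ids[j],
                    "event_type": "encounter",
                    "onset": t,
                    "offset": t,
                }
            )
            if is_sting:
                records.append(
                    {
                        "colony_id": colony_id,
                        "trial": trial,
                        "ant_id": ant_ids[j],
                        "event_type": "sting",
                        "onset": t,
                        "offset": min(t + d, T),
                    }
                )
    cols = ["colony_id", "trial", "ant_id", "event_type", "onset", "offset"]
    if not records:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(records, columns=cols)
    # stable sort keeps each sting immediately after its encounter
    return df.sort_values(["onset"], kind="stable").reset_index(drop=True)


@dataclass
class SimulatedExperiment:
    """All tables produced by one synthetic experiment."""

    scenario: SimScenario
    design: pd.DataFrame
    latents: pd.DataFrame  # per-ant theta, activity, ... with colony_id/ant_id
    events: pd.DataFrame
    trajectories: pd.DataFrame | None


def simulate_experiment(
    scenario: SimScenario, include_trajectories: bool = True
) -> SimulatedExperiment:
    """Run the full factorial experiment defined by a scenario.

    Spawns an independent RNG stream per colony (latents, baseline, each
    trial) from ``scenario.seed``, so the event tables are identical whether
    or not trajectories are generated.
    """
    design = design_table(scenario)
    ss = np.random.SeedSequence(scenario.seed)
    traj_seed, *colony_seeds = ss.spawn(len(design) + 1)

    latent_frames = []
    event_frames = []
    for (row, cseed) in zip(design.itertuples(index=False), colony_seeds):
        streams = cseed.spawn(1 + scenario.n_trials)
        rng_lat = np.random.default_rng(streams[0])
        ants = draw_individuals(scenario, int(row.group_size), rng_lat)
        ant_ids = [f"{row.colony_id}_a{k}" for k in range(1, len(ants) + 1)]
        lat = ants.copy()
        lat.insert(0, "ant_id", ant_ids)
        lat.insert(0, "colony_id", row.colony_id)
        latent_frames.append(lat)

        for trial in range(1, scenario.n_trials + 1):
            rng_tr = np.random.default_rng(streams[trial])
            event_frames.append(
                simulate_defence_trial(
                    scenario, ants, trial, rng_tr, colony_id=row.colony_id, ant_ids=ant_ids
                )
            )

    latents = pd.concat(latent_frames, ignore_index=True)
    events = pd.concat(event_frames, ignore_index=True) if event_frames else pd.DataFrame()
    trajectories = None
    if include_trajectories:
        rng_traj = np.random.default_rng(traj_seed)
        trajectories = simulate_baseline_trajectory(
            scenario,
            latents,
            rng_traj,
            ant_ids=latents["ant_id"].tolist(),
            colony_ids=latents["colony_id"].to_numpy(),
        )
    return SimulatedExperiment(
        scenario=scenario,
        design=design,
        latents=latents,
        events=events,
        trajectories=trajectories,
    )
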