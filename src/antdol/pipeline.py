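"""End-to-end pipeline: simulate/load -> preprocess -> metrics -> score
-> DOL statistics -> group-size resampling.

A :class:`PipelineConfig` carries every stage parameter (defaults match
the study design: 25 x 25 grid of 2 mm bins, 1 mm/s speed threshold,
1000 resampling iterations, 3 trials, group sizes {4, 8}). Running a
config twice produces bit-identical artefacts; a manifest records the
config hash, seed and per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import dol, metrics, resampling, scoring, trajectory
from .scenario import SimScenario, roster
from .simulate import simulate_experiment

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("antdol")


@dataclass
class PipelineConfig:
    """All knobs for one pipeline run.

    Either a scenario (synthetic mode) or explicit input paths
    (trajectories, events, design CSVs) must be provided.
    """

    scenario: SimScenario | None = None
    trajectories_path: str | None = None
    events_path: str | None = None
    design_path: str | None = None

    max_gap: int = 10
    v_max: float = 50.0
    fps: float = 20.0
    bins_per_side: int = 25
    bin_size: float = 2.0
    speed_threshold: float = 1.0
    n_trials: int = 3
    stratify: tuple[str, ...] = ("group_size", "brood")
    resample_iterations: int = 1000
    subsample_size: int = 4
    large_size: int = 8
    small_size: int = 4
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenario"] = self.scenario.to_dict() if self.scenario else None
        d["stratify"] = list(self.stratify)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("scenario") is not None:
            d["scenario"] = SimScenario.from_dict(d["scenario"])
        if "stratify" in d:
            d["stratify"] = tuple(d["stratify"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown pipeline parameters: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    log.info("stage: %s", name)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage in dependency order, writing artefacts to out_dir.

    Returns the manifest dict (also written as manifest.json). Any stage
    failure raises with the stage name prefixed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    def run(name, fn):
        _stage(name)
        try:
            return fn()
        except Exception as exc:  # annotate failures with the stage name
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    # -- inputs ------------------------------------------------------------
    if config.scenario is not None:
        def simulate():
            scen = config.scenario.replace(seed=config.seed)
            exp = simulate_experiment(scen, include_trajectories=True)
            exp.trajectories.to_csv(out / "trajectories.csv", index=False)
            exp.events.to_csv(out / "events.csv", index=False)
            exp.design.to_csv(out / "design.csv", index=False)
            return exp.trajectories, exp.events, exp.design
        traj, events, design = run("simulate", simulate)
    else:
        def load():
            for name, path in (
                ("trajectories", config.trajectories_path),
                ("events", config.events_path),
                ("design", config.design_path),
            ):
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"missing input: {name} ({path})")
            t = trajectory.read_trajectories(config.trajectories_path)
            e = scoring.read_events(config.events_path)
            d = pd.read_csv(config.design_path)
            return t, e, d
        traj, events, design = run("load", load)
    manifest["stages"]["inputs"] = {
        "trajectory_rows": len(traj), "event_rows": len(events), "colonies": len(design)
    }

    # -- preprocess --------------------------------------------------------
    def do_preprocess():
        cleaned, report = trajectory.preprocess(
            traj, max_gap=config.max_gap, v_max=config.v_max, fps=config.fps
        )
        cleaned.to_csv(out / "trajectories_clean.csv", index=False)
        report.to_json(out / "preprocess_report.json")
        return cleaned, report
    cleaned, report = run("preprocess", do_preprocess)
    manifest["stages"]["preprocess"] = report.totals

    # -- baseline metrics --------------------------------------------------
    def do_metrics():
        grid = metrics.GridSpec(config.bins_per_side, config.bin_size)
        m = metrics.baseline_metrics(
            cleaned, grid=grid, fps=config.fps, speed_threshold=config.speed_threshold
        )
        m.to_csv(out / "baseline_metrics.csv", index=False)
        return m
    base = run("metrics", do_metrics)
    manifest["stages"]["metrics"] = {"ants": len(base)}

    # -- defence scoring ---------------------------------------------------
    def do_score():
        ants = roster(design)
        agg = scoring.aggregate_events(events, ants, n_trials=config.n_trials)
        per_trial = scoring.score_records(agg)
        pooled = scoring.pooled_scores(agg)
        eff = scoring.colony_efficiency(events, design)
        per_trial.to_csv(out / "defence_records.csv", index=False)
        pooled.to_csv(out / "defence_records_pooled.csv", index=False)
        eff.to_csv(out / "defence_efficiency.csv", index=False)
        return per_trial, pooled, eff
    per_trial, pooled, eff = run("score", do_score)
    manifest["stages"]["score"] = {
        "records": len(per_trial), "pooled": len(pooled),
        "total_stings": int(eff["total_stings"].sum()),
    }

    # -- DOL statistics ----------------------------------------------------
    def do_dol():
        cons = pd.concat(
            [
                dol.consistency_analysis(per_trial, design, stratify_by=s)
                for s in config.stratify
            ],
            ignore_index=True,
        )
        summary = dol.behavioural_variation(
            pd.concat([per_trial, pooled], ignore_index=True)
        )
        colony_table, ant_table = dol.assemble_model_table(base, per_trial, pooled, design)
        cons.to_csv(out / "consistency.csv", index=False)
        summary.to_csv(out / "dol_summary.csv", index=False)
        colony_table.to_csv(out / "model_colony_table.csv", index=False)
        ant_table.to_csv(out / "model_ant_table.csv", index=False)
        return cons, summary
    cons, summary = run("dol", do_dol)
    manifest["stages"]["dol"] = {"consistency_rows": len(cons), "summary_rows": len(summary)}

    # -- group-size resampling --------------------------------------------
    def do_resample():
        large_ids = design.loc[design["group_size"] == config.large_size, "colony_id"]
        small_ids = design.loc[design["group_size"] == config.small_size, "colony_id"]
        if large_ids.empty or small_ids.empty:
            log.info("resample: skipped (need both size-%s and size-%s colonies)",
                     config.large_size, config.small_size)
            return None
        large_scores = pooled[pooled["colony_id"].isin(large_ids)]
        res = resampling.resample_variation(
            large_scores,
            subsample_size=config.subsample_size,
            n_iterations=config.resample_iterations,
            seed=config.seed,
            large_size=config.large_size,
        )
        small_var = summary[
            (summary["trial"] == "pooled") & summary["colony_id"].isin(small_ids)
        ]
        res = resampling.compare_observed(res, small_var)
        res.to_json(out / "resample.json")
        return res
    res = run("resample", do_resample)
    if res is not None:
        manifest["stages"]["resample"] = {
            "ci": [res.ci_low, res.ci_high],
            "observed_small_mean": res.observed_small_mean,
            "flag": res.flag,
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
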