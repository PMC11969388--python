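"""Scenario definition for synthetic colony-defence experiments.

A :class:`SimScenario` bundles every generative parameter of the synthetic
experiment: the factorial design (group size x brood treatment), trial
structure, arena geometry, the response-threshold model of stinging, and the
two-state movement model. Together with a seed it fully determines every
simulated table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import pandas as pd
import yaml

__all__ = ["SimScenario", "design_table", "roster"]


@dataclass(frozen=True)
class SimScenario:
    """Generative parameters for one synthetic experiment.

    Defaults mirror the study design: six replicate colonies per treatment,
    group sizes 4 and 8, three brood treatments, a one-hour tracked baseline
    at 20 frames/s in a 5 cm circular arena, and three 20-minute defence
    trials.

    Parameters
    ----------
    threshold_mean, threshold_sd, threshold_steepness
        Response-threshold model: per-ant thresholds ``theta_i`` are
        log-normal with median ``threshold_mean`` and log-scale spread
        ``threshold_sd``; on each intruder encounter the ant stings with
        probability ``s**h / (s**h + theta_i**h)`` where ``s`` is
        ``stimulus`` and ``h`` is ``threshold_steepness``.
    encounter_rate_scale
        Encounters per minute per unit activity propensity; encounters form
        a Poisson process, so more active ants meet the intruder more often.
    coupling
        Correlation (on the latent Gaussian scale) between activity
        propensity and aggression (low threshold). 0 = no behavioural
        syndrome, the regime the study observed.
    p_active_on, p_active_off
        Per-frame two-state (inactive/active) switching probabilities at the
        colony mean; per-ant values are scaled by activity propensity.
    missing_rate, jump_rate
        Optional per-frame rates of dropped detections and aberrant position
        jumps, to exercise trajectory preprocessing. Both default off.
    """

    n_colonies_per_treatment: int = 6
    group_sizes: tuple[int, ...] = (4, 8)
    brood_treatments: tuple[str, ...] = ("none", "larvae", "pupae")
    n_trials: int = 3
    trial_duration: float = 1200.0
    baseline_duration: float = 3600.0
    fps: float = 20.0
    arena_diameter: float = 50.0

    threshold_mean: float = 1.0
    threshold_sd: float = 1.0
    threshold_steepness: float = 2.0
    stimulus: float = 1.0
    encounter_rate_scale: float = 0.75
    sting_duration_mean: float = 45.0

    p_active_on: float = 0.005
    p_active_off: float = 0.01
    speed_active_mean: float = 5.0
    turn_sd: float = 0.5
    activity_sd: float = 0.2
    coupling: float = 0.0

    missing_rate: float = 0.0
    jump_rate: float = 0.0

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = {
            "n_colonies_per_treatment": self.n_colonies_per_treatment,
            "n_trials": self.n_trials,
            "trial_duration": self.trial_duration,
            "baseline_duration": self.baseline_duration,
            "fps": self.fps,
            "arena_diameter": self.arena_diameter,
            "threshold_mean": self.threshold_mean,
            "threshold_steepness": self.threshold_steepness,
            "stimulus": self.stimulus,
            "sting_duration_mean": self.sting_duration_mean,
            "speed_active_mean": self.speed_active_mean,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        nonneg = {
            "threshold_sd": self.threshold_sd,
            "activity_sd": self.activity_sd,
            "encounter_rate_scale": self.encounter_rate_scale,
            "missing_rate": self.missing_rate,
            "jump_rate": self.jump_rate,
            "turn_sd": self.turn_sd,
        }
        for name, value in nonneg.items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        for name, value in (("p_active_on", self.p_active_on), ("p_active_off", self.p_active_off)):
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if not -1 <= self.coupling <= 1:
            raise ValueError(f"coupling must lie in [-1, 1], got {self.coupling}")
        if not all(g > 0 for g in self.group_sizes):
            raise ValueError("group sizes must be strictly positive")
        if len(set(self.group_sizes)) != len(self.group_sizes):
            raise ValueError("group sizes must be distinct")
        if len(set(self.brood_treatments)) != len(self.brood_treatments):
            raise ValueError("brood treatments must be distinct")

    def replace(self, **kwargs) -> "SimScenario":
        return dataclasses.replace(self, **kwargs)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_sizes"] = list(self.group_sizes)
        d["brood_treatments"] = list(self.brood_treatments)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimScenario":
        d = dict(d)
        if "group_sizes" in d:
            d["group_sizes"] = tuple(d["group_sizes"])
        if "brood_treatments" in d:
            d["brood_treatments"] = tuple(d["brood_treatments"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown scenario parameters: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimScenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def design_table(scenario: SimScenario) -> pd.DataFrame:
    """Factorial colony design: one row per colony with its treatment.

    Colony ids are ``c01, c02, ...`` in (group size, brood, replicate) order.
    """
    rows = []
    i = 0
    for size in scenario.group_sizes:
        for brood in scenario.brood_treatments:
            for _ in range(scenario.n_colonies_per_treatment):
                i += 1
                rows.append({"colony_id": f"c{i:02d}", "group_size": size, "brood": brood})
    return pd.DataFrame(rows)


def roster(design: pd.DataFrame) -> pd.DataFrame:
    """Expand a design table into one row per ant (``<colony>_a<k>``)."""
    required = {"colony_id", "group_size"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    rows = [
        {"colony_id": r.colony_id, "ant_id": f"{r.colony_id}_a{k}"}
        for r in design.itertuples(index=False)
        for k in range(1, int(r.group_size) + 1)
    ]
    return pd.DataFrame(rows)
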