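"""Sampling-effect control for the group-size comparison.

Behavioural variation (within-colony SD of defence scores) is expected to
rise with group size for purely statistical reasons: a sample of 4 scores
estimates spread more noisily than a sample of 8. To separate a real
group-size effect from this sampling artefact, pseudo-colonies of size 4
are built by drawing 4 members (without replacement) from each real
size-8 colony; each iteration yields the mean pseudo-colony SD, and 1000
iterations give a 95% percentile interval. Observed size-4 variation
falling outside that interval cannot be explained by sampling alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ResampleResult", "resample_variation", "compare_observed"]


@dataclass
class ResampleResult:
    """Outcome of the pseudo-colony resampling null."""

    n_iterations: int
    subsample_size: int
    iteration_means: np.ndarray
    ci_low: float
    ci_high: float
    observed_small_mean: float | None = None
    flag: bool | None = None

    def to_dict(self, include_iterations: bool = False) -> dict:
        d = {
            "n_iterations": self.n_iterations,
            "subsample_size": self.subsample_size,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "observed_small_mean": self.observed_small_mean,
            "flag": self.flag,
        }
        if include_iterations:
            d["iteration_means"] = self.iteration_means.tolist()
        return d

    def to_json(self, path, include_iterations: bool = False) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(include_iterations), fh, indent=2)


def resample_variation(
    large_scores: pd.DataFrame,
    subsample_size: int = 4,
    n_iterations: int = 1000,
    seed: int | np.random.Generator = 0,
    large_size: int = 8,
) -> ResampleResult:
    """Resample pseudo-small colonies from large colonies.

    ``large_scores`` holds one (pooled) score per member of each size-8
    colony (columns colony_id, score). Each iteration draws one subsample
    of ``subsample_size`` members without replacement from every large
    colony, computes each pseudo-colony's sample SD, and averages across
    pseudo-colonies. The 95% CI is the closed (2.5th, 97.5th) percentile
    interval of the iteration means. Deterministic under a fixed seed.
    """
    if subsample_size < 2 or subsample_size >= large_size:
        raise ValueError(f"subsample_size must lie in 2..{large_size - 1}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    groups = []
    for colony, g in large_scores.groupby("colony_id"):
        if len(g) != large_size:
            raise ValueError(
                f"colony {colony} has {len(g)} member scores, expected {large_size}"
            )
        groups.append(g["score"].to_numpy())
    if not groups:
        raise ValueError("no large colonies supplied")
    scores = np.stack(groups)  # (n_colonies, large_size)
    n_col = scores.shape[0]

    # (n_iterations, n_colonies, subsample_size) indices without replacement
    idx = np.argsort(rng.random((n_iterations, n_col, large_size)), axis=-1)[..., :subsample_size]
    sub = np.take_along_axis(scores[None, :, :], idx, axis=-1)
    sds = sub.std(axis=-1, ddof=1)
    iteration_means = sds.mean(axis=-1)
    ci_low, ci_high = np.percentile(iteration_means, [2.5, 97.5])
    return ResampleResult(
        n_iterations=n_iterations,
        subsample_size=subsample_size,
        iteration_means=iteration_means,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
    )


def compare_observed(result: ResampleResult, small_variation) -> ResampleResult:
    """Compare observed small-colony variation with the resampling CI.

    ``small_variation`` is the per-colony (pooled) variation of the real
    small colonies (array-like or the ``variation`` column of a summary
    frame). The flag fires iff the mean observed variation lies outside
    the closed interval [ci_low, ci_high]. Returns a new result carrying
    the decision.
    """
    if isinstance(small_variation, pd.DataFrame):
        small_variation = small_variation["variation"].to_numpy()
    v = np.asarray(small_variation, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no small-colony variation values supplied")
    observed = float(v.mean())
    flag = not (result.ci_low <= observed <= result.ci_high)
    return ResampleResult(
        n_iterations=result.n_iterations,
        subsample_size=result.subsample_size,
        iteration_means=result.iteration_means,
        ci_low=result.ci_low,
        ci_high=result.ci_high,
        observed_small_mean=observed,
        flag=flag,
    )
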