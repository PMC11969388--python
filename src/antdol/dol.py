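"""Division-of-labour statistics.

Division of labour in defence is quantified along two axes:

* **Within-individual consistency** — defence scores are ranked within
  each colony in each trial (ties share the lowest rank), ranks are pooled
  across colonies within a stratum (a group size or a brood treatment),
  and successive trials (1 vs 2, 2 vs 3) are compared with Spearman rank
  correlations. The resulting family of p-values is Benjamini-Hochberg
  adjusted. Colonies that showed no defence at all (zero colony-wide
  stings) in both trials of a pair are excluded from that pair.
* **Between-individual variation** — the sample standard deviation of
  member defence scores within a colony, per trial and pooled across
  trials.

The module also assembles tidy, model-ready tables (one row per
colony-trial and one row per ant) for external mixed-model fitting.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "rank_within_colony",
    "spearman",
    "bh_adjust",
    "consistency_analysis",
    "behavioural_variation",
    "assemble_model_table",
]

TRIAL_PAIRS = ((1, 2), (2, 3))


def rank_within_colony(scores, method: str = "min") -> np.ndarray:
    """Ascending 1-based ranks of scores within one colony-trial.

    The default "min" method gives every tied score the smallest rank of
    its tie group (four all-zero scores all rank 1).
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) == 0:
        raise ValueError("need at least one score to rank")
    return stats.rankdata(scores, method=method)


def spearman(x, y, p_method: str = "t") -> tuple[float, float]:
    """Tie-corrected Spearman correlation with a two-sided p-value.

    The coefficient is the Pearson correlation of (average) ranks. The
    p-value uses the t-distribution approximation by default;
    ``p_method="exact"`` enumerates all permutations (n <= 8 only).
    Zero variance in either vector leaves both values NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho = float(stats.spearmanr(x, y).statistic)
    if p_method == "t":
        res = stats.spearmanr(x, y)
        return rho, float(res.pvalue)
    if p_method == "exact":
        if n > 8:
            raise ValueError("exact permutation p-value only for n <= 8")
        ry = stats.rankdata(y, method="average")
        count = 0
        total = 0
        for perm in permutations(ry):
            r = float(stats.spearmanr(x, np.asarray(perm)).statistic)
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        return rho, count / total
    raise ValueError(f"unknown p_method {p_method!r}")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    NaN entries (tests that could not be computed) pass through as NaN and
    do not count towards the family size.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _colony_total_stings(records: pd.DataFrame) -> pd.DataFrame:
    return (
        records.groupby(["colony_id", "trial"], as_index=False)["n_stings"]
        .sum()
        .rename(columns={"n_stings": "colony_stings"})
    )


def consistency_analysis(
    records: pd.DataFrame,
    design: pd.DataFrame,
    stratify_by: str = "group_size",
    rank_method: str = "min",
    p_method: str = "t",
    pool_colonies: bool = True,
) -> pd.DataFrame:
    """Inter-trial Spearman consistency of defence ranks, per stratum.

    ``records`` must hold per-trial score records (columns colony_id,
    trial, ant_id, n_stings, score). For each level of ``stratify_by``
    ("group_size" or "brood") and each successive trial pair, ants' scores
    are ranked within their colony in each trial, colonies with zero
    colony-wide stings in both trials of the pair are excluded, the ranks
    are pooled across the stratum's remaining colonies, and a Spearman
    test is run. The family of p-values within the stratification is then
    BH-adjusted.

    With ``pool_colonies=False`` a correlation is instead computed per
    colony and the per-colony coefficients averaged (p-values are not
    defined for this variant and are NaN).

    Returns one row per stratum x trial pair with rho, p, p_adj, n and a
    ``computable`` flag.
    """
    if stratify_by not in ("group_size", "brood"):
        raise ValueError("stratify_by must be 'group_size' or 'brood'")
    rec = records.merge(design[["colony_id", stratify_by]], on="colony_id", how="left")
    if rec[stratify_by].isna().any():
        missing = rec.loc[rec[stratify_by].isna(), "colony_id"].unique()
        raise ValueError(f"colonies missing from design: {sorted(missing)}")
    totals = _colony_total_stings(records).set_index(["colony_id", "trial"])["colony_stings"]

    rows = []
    for stratum in sorted(rec[stratify_by].unique(), key=str):
        sub = rec[rec[stratify_by] == stratum]
        for (t1, t2) in TRIAL_PAIRS:
            xs, ys, per_colony = [], [], []
            for colony, g in sub.groupby("colony_id"):
                s1 = totals.get((colony, t1), 0)
                s2 = totals.get((colony, t2), 0)
                if s1 == 0 and s2 == 0:
                    continue  # never defended in this pair of trials
                g1 = g[g["trial"] == t1].sort_values("ant_id")
                g2 = g[g["trial"] == t2].sort_values("ant_id")
                if len(g1) == 0 or len(g1) != len(g2):
                    raise ValueError(f"colony {colony}: unmatched ants across trials {t1},{t2}")
                r1 = rank_within_colony(g1["score"].to_numpy(), method=rank_method)
                r2 = rank_within_colony(g2["score"].to_numpy(), method=rank_method)
                xs.append(r1)
                ys.append(r2)
                if not pool_colonies and len(r1) >= 3 and np.ptp(r1) > 0 and np.ptp(r2) > 0:
                    per_colony.append(spearman(r1, r2, p_method="t")[0])
            row = {
                "stratum": stratum,
                "stratify_by": stratify_by,
                "trial_pair": f"{t1}v{t2}",
                "rho": float("nan"),
                "p": float("nan"),
                "n": int(sum(len(v) for v in xs)),
                "computable": False,
            }
            if pool_colonies:
                if xs and row["n"] >= 3:
                    x = np.concatenate(xs)
                    y = np.concatenate(ys)
                    if np.ptp(x) > 0 and np.ptp(y) > 0:
                        rho, p = spearman(x, y, p_method=p_method)
                        if np.isfinite(rho):
                            row.update(rho=rho, p=p, computable=True)
            else:
                if per_colony:
                    row.update(rho=float(np.nanmean(per_colony)), computable=True)
            rows.append(row)
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def behavioural_variation(records: pd.DataFrame) -> pd.DataFrame:
    """Within-colony variation and mean of defence scores.

    ``records`` may mix per-trial and pooled rows (the ``trial`` column
    distinguishes them). Variation is the sample standard deviation
    (n - 1 denominator) over colony members; it is NaN for colonies with
    fewer than two members.
    """
    out = (
        records.groupby(["colony_id", "trial"], as_index=False)["score"]
        .agg(variation=lambda s: s.std(ddof=1), mean_score="mean", n_ants="size")
    )
    return out


def assemble_model_table(
    metrics: pd.DataFrame,
    per_trial_records: pd.DataFrame,
    pooled_records: pd.DataFrame,
    design: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy tables ready for external (mixed-)model fitting.

    Returns ``(colony_table, ant_table)``:

    * colony_table — one row per colony x trial (per-trial and pooled)
      with variation, mean score, group size, brood and colony id;
    * ant_table — one row per ant with baseline metrics (entropy,
      prop_active, mean_bout), trial-1 encounters and score, pooled score,
      and the colony covariates, for the syndrome analyses.

    Ids that do not match across inputs are a hard error.
    """
    all_records = pd.concat([per_trial_records, pooled_records], ignore_index=True)
    summaries = behavioural_variation(all_records)
    colony_table = summaries.merge(design, on="colony_id", how="left", validate="m:1")
    if colony_table["group_size"].isna().any():
        bad = colony_table.loc[colony_table["group_size"].isna(), "colony_id"].unique()
        raise ValueError(f"colonies missing from design: {sorted(bad)}")

    t1 = per_trial_records[per_trial_records["trial"] == 1].loc[
        :, ["colony_id", "ant_id", "n_encounters", "score"]
    ].rename(columns={"n_encounters": "encounters_trial1", "score": "score_trial1"})
    pooled = pooled_records.loc[:, ["colony_id", "ant_id", "score"]].rename(
        columns={"score": "score_pooled"}
    )
    ant_table = (
        metrics.merge(t1, on=["colony_id", "ant_id"], how="outer", indicator=True)
    )
    if (ant_table["_merge"] != "both").any():
        bad = ant_table.loc[ant_table["_merge"] != "both", "ant_id"].tolist()
        raise ValueError(f"ants not matched between metrics and records: {bad[:5]}")
    ant_table = ant_table.drop(columns="_merge").merge(
        pooled, on=["colony_id", "ant_id"], how="left", validate="1:1"
    )
    ant_table = ant_table.merge(design, on="colony_id", how="left", validate="m:1")
    return colony_table, ant_table
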