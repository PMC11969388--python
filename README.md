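# antdol

Quantifying division of labour (DOL) in colony defence for small clonal
ant societies.

When a colony faces an intruder, do all workers defend equally, or do a
few consistent defenders carry the task? `antdol` implements the full
quantitative pipeline for answering that question from individual
tracking and behavioural annotation data:

* **Synthetic experiments** — a generative model of colonies of 4 or 8
  workers (crossed with three brood treatments, six replicates each)
  with heterogeneous response thresholds, a 1 h tracked baseline in a
  5 cm arena at 20 fps, and three 20 min defence trials. Thresholds
  follow the classic fixed-threshold model: at each intruder encounter
  an ant stings with probability *s*ʰ / (*s*ʰ + θᵢʰ).
* **Trajectory preprocessing** — speed-based aberrance detection, linear
  interpolation of short detection gaps, removal of long ones, with a
  full per-frame accounting report.
* **Baseline behavioural metrics** — exploration as occupancy-grid
  Shannon entropy, *H* = −∑ₓ *p*(*x*) log₂ *p*(*x*) over a 25 × 25 grid
  of 2 mm cells, plus proportion of time active (> 1 mm s⁻¹) and mean
  active-bout duration.
* **Defence scoring** — per ant and trial,
  score = (n_stings / n_encounters) × ln(1 + total sting seconds),
  the normalised sting rate, colony mean scores, and colony defence
  efficiency (total stings received by the intruder).
* **DOL statistics** — within-colony min-rank ranking, Spearman
  consistency between successive trials per group size / brood stratum
  with Benjamini–Hochberg correction, and behavioural variation (the
  within-colony SD of scores).
* **Group-size resampling null** — pseudo-colonies of 4 drawn without
  replacement from size-8 colonies (1000 iterations, 95% percentile CI)
  to separate true group-size effects on variation from sampling
  artefacts.

## Worked example

```python
>>> import antdol
>>> antdol.defence_score(13, 18, 629.25)   # a highly defensive ant
4.6555286310491315
```

An ant that stung in 13 of its 18 intruder contacts for 629.25 s in
total scores 4.66; an ant with 14 encounters and no stings scores 0.

A small synthetic experiment, end to end:

```python
import antdol

scen = antdol.SimScenario(n_colonies_per_treatment=3, baseline_duration=600.0, seed=42)
exp = antdol.simulate_experiment(scen)
agg = antdol.aggregate_events(exp.events, antdol.roster(exp.design))
rec = antdol.score_records(agg)
cons = antdol.consistency_analysis(rec, exp.design, stratify_by="group_size")
print(cons.round(4).to_string(index=False))
```

```
 stratum stratify_by trial_pair    rho   p  n  computable  p_adj
       4  group_size        1v2 0.7556 0.0 36        True    0.0
       4  group_size        2v3 0.7778 0.0 36        True    0.0
       8  group_size        1v2 0.7970 0.0 72        True    0.0
       8  group_size        2v3 0.8067 0.0 72        True    0.0
```

Each row is one stratum × successive-trial pair: `rho` is the Spearman
correlation of within-colony defence ranks pooled across the stratum's
colonies (positive and large here because the default scenario has
strong threshold heterogeneity, so the same ants defend in every trial),
`n` the ants entering the test, and `p_adj` the BH-adjusted p-value.

The resampling null then asks whether size-4 colonies are less
behaviourally variable than expected from sampling 4 ants out of 8:

```python
pooled = antdol.pooled_scores(agg)
var = antdol.behavioural_variation(pooled)
design = exp.design
large = pooled[pooled.colony_id.isin(design.loc[design.group_size == 8, "colony_id"])]
res = antdol.resample_variation(large, n_iterations=1000, seed=42)
small = var[var.colony_id.isin(design.loc[design.group_size == 4, "colony_id"])]
res = antdol.compare_observed(res, small)
print(f"CI=({res.ci_low:.3f}, {res.ci_high:.3f}) "
      f"observed={res.observed_small_mean:.3f} flag={res.flag}")
```

```
CI=(1.999, 2.912) observed=2.218 flag=False
```

Here the observed mean variation of the size-4 colonies sits inside the
resampling interval, so this particular simulated experiment shows no
group-size effect beyond sampling (both sizes share one threshold
distribution by construction).

## Command line

Every stage is also a subcommand of the `antdol` CLI:

```bash
antdol simulate --out run/ --seed 1
antdol preprocess --in run/trajectories.csv --out run/clean.csv
antdol metrics --in run/clean.csv --out run/metrics.csv
antdol score --events run/events.csv --design run/design.csv --out run/
antdol dol --records run/defence_records.csv --design run/design.csv --out run/
antdol resample --records run/defence_records_pooled.csv --design run/design.csv \
    --out run/resample.json --n 1000 --seed 1
antdol run-all --out run/ --seed 1      # everything, plus a manifest
```

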