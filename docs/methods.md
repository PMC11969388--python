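# Methods

This note documents the models, conventions and design choices behind
`antdol`: what the synthetic generator emulates, how each metric is
defined, and where genuinely open choices were resolved.

## The experimental design being emulated

The pipeline targets a factorial colony-defence experiment on small
clonal ant colonies: two group sizes (4 and 8 workers) crossed with
three brood treatments (none, larvae, pupae), six replicate colonies per
treatment (36 colonies, 216 ants). Each colony is video-tracked for a
1 h baseline in a 5 cm circular arena at 20 frames s⁻¹, then given three
20 min defence trials in which a dead allospecific intruder is
introduced and every encounter (physical contact) and stinging attempt
(with duration) is annotated per ant.

## Generative model (`antdol.simulate`)

### Individual heterogeneity

Each ant carries two latent traits:

* **response threshold** θᵢ — log-normal with median `threshold_mean`
  (default 1 stimulus unit) and log-scale SD `threshold_sd` (default 1).
  At every encounter the ant stings with the Hill-type probability
  *p*ᵢ = *s*ʰ / (*s*ʰ + θᵢʰ), with stimulus *s* (default 1) and
  steepness *h* (default 2, the conventional exponent in fixed-threshold
  task-allocation models). Threshold heterogeneity is the mechanism that
  produces division of labour: low-θ ants sting on most contacts, high-θ
  ants almost never.
* **activity propensity** aᵢ — log-normal, median 1, log-scale SD
  `activity_sd` (default 0.2). log aᵢ and −log θᵢ are jointly Gaussian
  with correlation `coupling` (default 0). A positive coupling creates a
  behavioural syndrome (active ants are also aggressive); the default 0
  decouples the two axes. Because aᵢ is a log-normal transform of its
  Gaussian latent, the Pearson correlation of (aᵢ, −log θᵢ) is
  attenuated to coupling·σ/√(e^σ² − 1) ≈ 0.99·coupling at σ = 0.2; the
  closed form is used as the test oracle.

### Baseline movement

A two-state (inactive/active) correlated random walk inside the circular
arena. Per frame, an inactive ant becomes active with probability
`p_active_on`·aᵢ and an active ant stops with `p_active_off`/aᵢ
(defaults 0.005 and 0.01 per frame, giving minute-scale bouts and
activity proportions spanning roughly 0.2–0.6 across ants). Active ants
step `speed_active_mean`·√aᵢ / fps (default 5 mm s⁻¹ at the median)
along a heading that diffuses with per-frame SD `turn_sd` = 0.5 rad;
inactive ants are exactly stationary. The wall reflects radially
(positions folded back across the boundary). Optional per-frame
detection dropout (`missing_rate`) and teleporting jumps (`jump_rate`)
exercise preprocessing; both default to 0.

### Defence trials

Encounters arrive per ant as a Poisson process at
`encounter_rate_scale`·aᵢ per minute (default 0.75, i.e. ~15 encounters
per 20 min trial at median activity — reference counts of 14–18
encounters per trial then sit at the typical-to-high end). Each
encounter triggers a sting with probability *p*ᵢ; sting durations are
exponential with mean `sting_duration_mean` = 45 s, matching the
per-sting duration implied by the benchmark tally (629.25 s over 13
stings ≈ 48 s). Stings are nested at their encounter's onset and clipped
at the trial end.

### Why these defaults constitute the "no-syndrome" regime

The defence score's duration term, ln(1 + total sting seconds), grows
with the number of stings and hence with encounter rate, so activity
leaks weakly into the score even at coupling = 0. The defaults keep that
structural leak far below the threshold-driven variance: activity
heterogeneity is modest (log-SD 0.2) relative to threshold heterogeneity
(log-SD 1.0). Under these conditions entropy strongly predicts encounter
counts (median rank correlation ≈ 0.5 across replicate experiments) but
not the defence score (median ≈ 0.03), reproducing the empirical
dissociation between exploration and defensiveness. With coupling near
1 the same machinery produces a clear positive entropy–score
correlation, so the syndrome axis is testable.

### What the generator does *not* emulate

No intruder behaviour (the stimulus is passive), no pheromone
recruitment or social feedback between defenders, no spatial structure
in encounters (brood-piles do not attract guards), no inter-ant
interactions at baseline, and no drift in rates across trials (the
generator holds encounter rates constant because there is no evidence
either way). Passing tests therefore demonstrate that the *statistics*
behave correctly under a threshold-heterogeneity world, not that real
colonies are described by this exact process.

## Preprocessing (`antdol.trajectory`)

The aberrance criterion is speed-based: a position implying
> `v_max` = 50 mm s⁻¹ (~20 body lengths s⁻¹) from the last accepted
position is rejected, sequentially, so an isolated teleport removes only
itself. Runs of ≤ `max_gap` = 10 consecutive missing frames (0.5 s)
bounded by accepted positions are filled linearly; longer or unbounded
runs are removed. Both knobs are config-exposed; the defaults are this
package's own operational choices, not a reproduction of any published
protocol. The per-ant report partitions every frame in the spanned range
into kept/interpolated/removed, and the operation is idempotent
(interpolated frames never exceed `v_max` because the bounding
acceptance already capped the gap-average speed).

## Baseline metrics (`antdol.metrics`)

Entropy uses **log base 2**. With 625 cells the maximum is
log₂ 625 ≈ 9.288 bits; natural log would cap at 6.44, below observed
reference values above 8, so base 2 is the only consistent reading.
The grid is anchored to the 50 mm bounding square centred on the arena;
out-of-square positions (possible only on unpreprocessed data) are
clamped into edge cells. Speeds use the displacement from the previous
frame; the first frame of each contiguous segment is unclassified and
excluded from the activity denominator. Interpolated frames carry
positions and are included. No speed smoothing is applied.

## Defence score (`antdol.scoring`)

score = (n_stings / n_encounters) × **ln**(1 + sting seconds). Natural
log is forced by the benchmark evaluation: (13/18)·ln(630.25) = 4.656 →
4.66, whereas log₂ gives 6.72 and log₁₀ gives 2.02. Zero encounters ⇒
score assigned 0. n_stings may exceed n_encounters (repeated stings
within one contact); such records are flagged, not rejected. Pooled
scores sum counts and durations across trials first and apply the
formula once. All scores are kept at full precision; rounding is
presentation-only.

## DOL statistics (`antdol.dol`)

Within-colony ranks use the **min** method (ties share the lowest rank),
which is what is pooled across a stratum's colonies; the Spearman
coefficient itself is the standard tie-corrected statistic (Pearson on
average ranks), computed on those pooled rank vectors. The two
conventions are not in conflict — min and average ranking are order
isomorphic — and both the rank method and a per-colony (non-pooled)
averaging variant are switchable.

P-values use the t-approximation (matching `cor.test` in the presence of
ties); an exact permutation p is available for n ≤ 8. One BH family =
all trial-pair × stratum tests within one stratification. A colony with
zero colony-wide stings in both trials of a pair "showed no defence" and
is excluded from that pair. Behavioural variation is the sample SD
(n − 1) of member scores, per trial and pooled.

## Resampling null (`antdol.resampling`)

Per iteration, one subsample of 4 members is drawn without replacement
from each size-8 colony; pseudo-colony SDs are averaged across colonies;
1000 iterations give the closed percentile interval (2.5th, 97.5th). The
observed statistic is the mean pooled-across-trials variation of the
real size-4 colonies, and the flag fires iff it falls outside the closed
interval. Reading "averaged across replicate simulated colonies" as one
subsample per colony per iteration is a documented choice; multiple
subsamples per colony would only tighten the iteration means. Under a
null where the small colonies are literal random subsets of the large
ones the flag fires at ≈ its nominal 5% rate.

## Numerical and scale choices

* All randomness flows from `numpy.random.SeedSequence`; a scenario plus
  seed reproduces every table bit-for-bit, and the event stream is
  unchanged whether or not trajectories are generated.
* The statistical test suites run on deliberately scaled problem sizes
  chosen to estimate each property precisely without waste: parameter
  recovery uses the full 6 × 6 × 3-trials design with events only (200
  replicates per threshold-heterogeneity level); resampling calibration
  uses 500 experiments of 18 size-8 colonies at 1000 iterations each;
  the dissociation check uses one colony per treatment with a 10 min
  baseline (200 replicates). Medians over replicates are the reported
  statistics, so these sizes govern Monte-Carlo precision only.
* Percentiles use numpy's default linear interpolation; the CI is
  closed at both ends.
* Degenerate inputs are defined, not special-cased ad hoc: zero
  encounters ⇒ score 0; no active bouts ⇒ mean bout 0; < 2 frames ⇒
  activity undefined (NaN); zero-variance rank vectors ⇒ Spearman
  undefined (NaN), excluded from the BH family.

## Known limitations

* The score's encounter normalisation makes it noisy for ants with very
  few encounters (one sting in one encounter can outrank ten stings in
  twenty); the pooled score mitigates but does not remove this.
* The Poisson encounter model has no refractoriness or clustering;
  empirical encounter streams are likely overdispersed.
* The pseudo-colony CI treats colonies as fixed (no between-colony
  bootstrap), so it controls sampling of *ants*, not of colonies.
* Mixed-model inference on the exported tables (variation ~ group size ×
  brood × trial, etc.) is intentionally out of scope; the pipeline emits
  tidy model-ready tables instead.
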