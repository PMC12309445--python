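# Methods

This note records the models, conventions and numerical choices behind
`cuephys`, in the spirit of a methods section a maintainer can audit.

## Peri-event binning and z-scoring

Spike times are aligned to cue onset and counted in 100 half-open 50 ms
bins covering −1…+4 s; bin 20 starts exactly at the cue.  Bin membership is
`floor((t − t_start)/0.05)` with a 1e-9 guard so that spike times written
as exact decimals land in the intended bin despite float subtraction error.

The z trace normalizes the **trial-averaged** rate trace against a baseline
bin range: μ_b and σ_b are the mean and population SD (divide by n; a
sample-SD switch exists) of the averaged trace over the baseline bins.
Baseline-referenced normalization is the default because the
responsiveness criterion is explicitly baseline-relative; `z_mode =
"full_trace"` normalizes over all 100 bins instead.  Baselines are computed
separately per cue type, since classification tables are reported per cue
type.  A flat baseline (σ_b = 0, e.g. a silent unit) marks the profile
*degenerate*: its z is NaN, classification returns "none" and the unit is
excluded from population-activity averages — this avoids ±∞ z while
keeping the unit in denominator counts.

Sliding windows are means of 4 consecutive z bins advancing one bin (200 ms
advancing 50 ms); a 100-bin trace yields 97 windows.

## Epochs and the responsiveness criterion

| epoch  | analysis window | baseline | windows inside | min. windows m |
|--------|-----------------|----------|----------------|----------------|
| Tone^R | [0, 0.4) s      | [−1, 0) s| 5              | 1              |
| Tone^S | [0.5, 3) s      | [−1, 0) s| 47             | 6              |
| Lever  | [3, 3.4) s      | [2, 3) s | 5              | 1              |

Only windows lying entirely inside the analysis window count, preventing
leakage across epoch boundaries.  The m = 6 criterion for the sustained
tone is interpreted in units of 200 ms windows (the same object the m = 1
transient criteria count).  The Lever epoch recomputes z against the
late-tone baseline [2, 3) s; a consequence worth knowing is that a unit
with sustained tone activation and no lever response is legitimately
classified lever-*inhibited* — its lever-period rate is below its elevated
late-tone baseline.  That is a property of the method, not a bug, and the
simulator's ground-truth comparisons account for it.

If a unit meets both the activated and inhibited criteria, the direction
with more significant windows wins; an exact tie is labeled *ambiguous* and
excluded from both counts by default (a flag counts it in both).

Basal firing rate is the mean rate over the pre-cue second across all
trials.  Putative dopamine typing requires basal rate < 12 Hz and waveform
duration ≥ 1.2 ms; the duration direction follows the wide-waveform
convention for optogenetically verified VTA dopamine neurons, with the
opposite reading available as `duration_rule="lt"` for comparison.

## auROC selectivity

Binwise auROC is the normalized Mann–Whitney pair count with half credit
for ties, which equals threshold-sweep ROC integration exactly (tested to
1e-12 against both brute-force oracles).  Counts are used directly since
auROC is invariant under the strictly increasing counts→Hz rescaling.

The selectivity criterion compares the epoch-mean auROC with the mean and
across-bin SD of the unit's baseline-bin auROC values (pre-cue bins for the
tone epochs, [2, 3) s for Lever): selective iff |Δ|/σ_a > 2.  This mirrors
the z-score convention; the trial-shuffle null is reserved for the
*proportion* comparison, where the full pipeline is rerun on 10
label-permuted copies (class sizes preserved, independent permutation per
unit) and the observed proportion of selective units is compared with the
shuffle mean.

## Population decoding

Features: for each trial, bin b's feature is the across-unit mean of the
unit-normalized single-trial rate in bin b, using the simultaneously
recorded units of that trial's session; rows are pooled across animals of
one (area, group, session) cell.  Unit normalization is a baseline z with
μ, σ pooled over the unit's single-trial baseline-bin rates across all
trials — a per-unit constant, so no trial labels can leak through
normalization.  Flat-baseline units are dropped with a log note.  Raw
rates are available via `normalization="raw"`.

Decoding protocol per repeat: stratified 80/20 split (fraction
configurable); features standardized on the training split only; L1
logistic regression over a 30-point λ grid spanning three decades below
the data-driven λ_max = max_j |x_jᵀ(y − ȳ)|/n (the smallest fully-sparse
penalty); λ chosen by stratified 5-fold CV accuracy under the
**one-standard-error rule** (strongest penalty within one SE of the best);
refit on the full training split; held-out accuracy and nonzero-coefficient
features recorded.  100 repeats with split seeds drawn once from the master
seed make the whole procedure bit-reproducible.

Two numerical choices here deserve justification:

* **One-SE rule rather than CV argmax.** With 30 candidate penalties,
  argmax on CV accuracy overfits fold noise on label-free data, selecting
  weak penalties and spurious features; the 1-SE rule collapses to the
  empty (chance) model under the null while leaving strong-signal recovery
  unchanged.  It also subsumes tie-breaking toward sparsity.
* **Epoch accuracies from train-side selections.** The 10 most frequent
  features per epoch mask (Tone = bins 20–79, Lever = bins 80–99) across
  repeats are reported as the frequency summary, but refitting every
  repeat's restricted model on that cross-repeat set would leak held-out
  trials into feature selection (the tally sees all trials), inflating
  null accuracy far above chance.  Each repeat's epoch accuracy therefore
  refits on up to 10 of that repeat's own selected features inside the
  mask, ranked by coefficient magnitude.  A repeat whose penalty removed
  every epoch feature falls back to the majority-class rule.  The
  null-calibration tests and the acceptance script exercise this on
  gain-free simulations, and the planted-signal suite checks that a
  lever-only contrast still decodes with the planted bins as top features.

One caveat is irreducible: on a single finite dataset, realized noise can
make a feature genuinely (if spuriously) correlated with the labels across
*all* trials; cross-validation and the train/test split live inside that
same dataset, so no split-based procedure can unmask it, and the reported
held-out accuracy can sit a few points off 50 % in either direction for a
particular gain-free session.  The calibration statement is therefore
about expectation over datasets — repeated-split accuracies on one session
are mutually dependent, and their spread understates dataset-to-dataset
variation.

Group comparison: independent two-sample t on the two per-repeat accuracy
vectors (df = 2·n_repeats − 2) with pooled-SD Cohen's d.

## Group statistics

Pearson χ² is computed without Yates continuity correction throughout —
the convention the reproduced worked examples require.  Fisher's exact
test (two-sided: sum of hypergeometric probabilities ≤ the observed
table's) replaces χ² for 2×2 tables with any cell below 5.  Welch's t uses
Satterthwaite degrees of freedom.  Cohen's d uses the pooled SD for
independent/Welch comparisons and the SD of the differences for paired
ones.  The phi effect size is √(χ²/denominator); alongside the standard
total-N denominator the package exposes a responsive-denominator variant
that divides by the count of units outside the "none" column, which is the
convention needed to reproduce the published effect sizes this package's
worked examples check against.

## Simulator

Each unit is an inhomogeneous Poisson process with piecewise-constant
rate: baseline b drawn once per unit from a lognormal, multiplied by an
epoch gain inside the Tone^R/Tone^S/Lever windows of each trial.  DS−
trials receive the diluted gain 1 + (g − 1)·c with contrast c ∈ [0, 1].
Gains switch instantaneously at epoch edges and no refractory period is
modeled — the analysis operates on 50 ms counts, for which sub-bin
structure is irrelevant.  Units are independent; real inter-unit
correlations are an acknowledged simplification, so decoding accuracies on
synthetic cohorts should be read as upper bounds on what identical
rate-coded signal would support, not as predictions for real populations.

Condition presets fix the study's structure: 50 DS+ and 50 DS− trials in
pseudorandom order with at most 3 consecutive same-cue trials (built by a
constrained sequential draw), 3 s tone-to-lever delay, 30 s intertrial
interval, presses with ~0.9 s latency on 96 % of DS+ trials and ~3.8 s on
27 % of DS− trials.  The control preset plants per-epoch
activated/inhibited fractions matching the observed control proportions
(dmPFC ≈ 10/13/11 % activated for Tone^R/Tone^S/Lever; VTA ≈ 34/22/84 %)
over baselines of ≈ 6 Hz (dmPFC) and a VTA DA/non-DA mixture (≈ 3.8 Hz
wide-waveform DA, faster narrow-waveform non-DA).  The `isd_day1` preset
shifts fractions down in dmPFC and up in VTA with elevated non-DA
baselines; `isd_day15` keeps near-control fractions but attenuates epoch
gains in both areas and raises VTA baselines further — day-15 responsive
fractions are not published, so these reproduce the reported day-15
*pattern* (population activity down, unit proportions not significantly
changed) rather than printed values.  Waveform durations are drawn on the
correct side of the 1.2 ms typing threshold for the planted cell type, so
typing is exactly recoverable; rate draws for DA units are clipped below
12 Hz for the same reason.

The helper `gain_for_sd(b, k, n)` returns the gain whose rate increment
equals k sampling SDs of a trial-averaged 50 ms bin (√(b/(0.05·n))) — the
scale the z classifier operates on — used to plant effects of controlled
detectability.

## Problem sizes and determinism

Defaults mirror the study design (7 animals per group, ~35 dmPFC and ~9
VTA units per animal, 100 trials); the test and acceptance suites run
scaled-down versions chosen for tight Monte-Carlo turnaround (2–5 animals,
10–200 units, 10–100 decoding repeats), with recovery tolerances stated as
binomial CIs or 3-SE bands at those sizes.  All randomness flows from
explicit seeds; per-animal and per-stage streams are spawned via
`numpy.random.SeedSequence`, so sessions, cohorts, the shuffle null, the
decoder and the full pipeline are bit-reproducible for a fixed master
seed.

## Known limitations

* Independent-Poisson units: no noise correlations, no rate adaptation,
  no refractoriness.
* The responsiveness false-positive rate of the sliding-window criterion
  is not analytically controlled (multiple 200 ms windows per epoch); the
  simulator's null calibration bounds it empirically at ≈ 2–5 % per epoch
  and cue type.
* Cell typing from basal rate and waveform duration is a heuristic; the
  simulator makes it exactly recoverable, real data do not.
* Omission trials are included in neural averages by default (a config
  switch excludes them); no latency-to-press analysis is provided.
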