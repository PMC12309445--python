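# cuephys

Single-unit and population analysis of cue-evoked spike trains recorded
during a discriminative-stimulus (DS) reward-seeking task, in which one tone
(DS+) predicts a rewarded lever and another (DS−) an unrewarded one.  The
package targets simultaneous dorsal–medial prefrontal cortex (dmPFC) and
ventral tegmental area (VTA) recordings and the comparisons typical of
stress studies (control vs stressed groups, short- vs long-delay sessions),
and ships a calibrated spike-train simulator so every stage can be exercised
and validated without access to recordings.

## What it computes

**Peri-event alignment and z-scoring.** Spikes are aligned to cue onset and
counted in 100 half-open 50 ms bins on −1…+4 s.  The trial-averaged rate
trace r(b) is normalized as z(b) = (r(b) − μ_b)/σ_b with μ_b, σ_b taken over
a baseline window: the pre-cue second for the tone epochs, the late-tone
second [2, 3) s for the lever epoch.

**Responsiveness classification.** 200 ms windows advancing in 50 ms steps
cover each analysis epoch — Tone^R (0–0.4 s), Tone^S (0.5–3 s), Lever
(3–3.4 s).  A unit is *activated* (*inhibited*) in an epoch if at least m
windows have mean z > +2 (< −2); m = 1 for the transient epochs, m = 6 for
the sustained tone.

**Putative dopamine typing.** VTA units with basal rate < 12 Hz and wide
action potentials (≥ 1.2 ms, configurable) are labeled putative DA.

**auROC cue selectivity.** Per 50 ms bin, the area under the ROC curve
compares DS+ vs DS− single-trial rate distributions (Mann–Whitney pair
statistic with ½ tie credit; 0.5 = no discrimination).  A unit is selective
in an epoch when |epoch-mean auROC − μ_a| > 2σ_a, with μ_a, σ_a over the
baseline bins; the proportion of selective units is benchmarked against 10
trial-label shuffles.

**LASSO population decoding.** Each trial yields 100 features (per-bin
population-average baseline-z rates of its session's units); labels are 1
for DS+, 0 for DS−.  100 stratified 80/20 splits; per split the L1 strength
is tuned by 5-fold cross-validation (one-standard-error rule) and the
held-out accuracy and selected features recorded.  Per-feature selection
frequencies and the 10 most frequent features per epoch mask (Tone, Lever)
are reported; epoch accuracies come from restricted refits on each split's
own train-side selections, so label-free data decodes at chance.

**Group statistics.** Pearson χ² without continuity correction, Fisher's
exact test for small counts, Student/paired/Welch t with Cohen's d, and the
phi effect size in two conventions — the standard √(χ²/N) and a
responsive-denominator variant √(χ²/m) where m counts only units outside
the "none" category.

**Simulator.** Inhomogeneous-Poisson units with lognormal baseline rates,
multiplicative epoch gains, a DS+/DS− gain contrast, DA/non-DA structure in
the VTA and the full task timing (50+50 pseudorandom trials, 3 s tone → lever,
30 s ITI).  Presets `control`, `isd_day1`, `isd_day15` encode the observed
directions of episodic-social-defeat effects.

## Worked example

```python
from cuephys import chi_square, phi_effect

# activated / inhibited / none unit counts, control vs stressed group
res = chi_square([[13, 5, 112], [1, 1, 112]])
print(f"chi2({res.df}) = {res.chi2:.2f}, p = {res.p:.3f}")
print(f"phi (responsive denominator, m={res.n_responsive}) = {phi_effect(res):.2f}")
```

prints

```
chi2(2) = 11.95, p = 0.003
phi (responsive denominator, m=20) = 0.77
```

i.e. the stressed group's deficit of rapid-tone-activated units is highly
significant with a large effect size on the responsive subpopulation.  The
`examples/` directory contains one short narrative script per capability
(simulation + classification, auROC selectivity, decoding, statistics, the
end-to-end pipeline); each prints the numbers it computes and a line on
what they mean.  A thin CLI (`cuephys simulate|run|report`) wraps the
pipeline for shell use.

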