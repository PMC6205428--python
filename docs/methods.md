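# Methods

This note documents the models, defaults, and design choices behind
`revcorrfaces`, and what the synthetic-data results do and do not show.

## Stimulus model

A stimulus is a 2.25 s facial animation described numerically over a
catalog of 42 FACS action units. Per trial, the number of active AUs is
drawn from masses 0.10/0.30/0.40/0.20 over {1, 2, 3, 4}. The protocol
constrains only the minimum (1), maximum (4) and median (3); a uniform
law has median 2.5, so these masses are the simplest choice realizing
median 3 (CDF at 2 is 0.40 < 0.5, at 3 is 0.80 ≥ 0.5). AUs are drawn
uniformly without replacement; an optional exclusion list of mutually
incompatible AU pairs (default empty) implements biological-feasibility
constraints by rejection sampling.

Each active AU's activation over time follows a piecewise power law
realizing the seven named temporal parameters with testable semantics:
zero before `onset_latency`; rise to `peak_amplitude` at `peak_latency`
as `amp * ((t-onset)/(peak-onset))^acceleration`; a plateau of length
`sustainment`; decay to zero at `offset_latency` as
`amp * (1 - ((t-plateau_end)/(offset-plateau_end))^deceleration)`.
`offset_latency` is an absolute time (not a gap), stated explicitly
because either convention is defensible. The original graphics
generator's sampling law is not public; parameters are drawn uniformly
within invariant-respecting ranges (onset U(0, 0.5) s; rise time
U(0.15, 0.9) s; amplitude U(0.2, 1]; shape exponents U(0.5, 3);
sustainment and decay fill the remainder, leaving ≥ 0.05 s for the
decay). All ranges are configurable (`ProfileRanges`).

## Observer model

The simulated observer is this package's own construction — the
benchmark task records real humans, and no behavioral model of them is
available — so all recovery results are conditional on it. An observer
holds disjoint AU templates for pain and orgasm, drawn around
group-level sets: pain {4, 6, 9, 10, 20} in both cultures; orgasm
{1, 2, 5, 26, 27, 43} (Western) or {1, 2, 12, 43} (East Asian).
Individual variability drops each group AU with probability 0.05 and
adds each outside AU with probability 0.05 (additions are kept disjoint
across affects; at least one AU always survives).

Response rule: with the stimulus's active set A, the overlap for affect
T is o_T = |A ∩ T| / |T|. With probability `lapse_rate` (default 0.05)
the response is uniform over {pain, orgasm, other}; otherwise the
larger-overlap affect is reported iff its overlap is at least
`match_threshold` and strictly exceeds the other affect's — ties go to
"other", which is conservative for recovery. Intensity is
`clamp(round(1 + 4 * mean peak amplitude of the matched template AUs +
N(0, 0.5)), 1, 5)`; on lapse trials without matched AUs the mean runs
over all active AUs.

`match_threshold` defaults to 0.2. Under the 1-4-AU stimulus law, a
threshold of 0.5 would require three or more of a 5-6-AU template to be
simultaneously active, which happens on only ~1 trial in 500 — far too
few matches for any statistical model to recover, and fewer than the
lapse responses. At 0.3 the required overlap jumps from two to three
AUs as soon as individual variability grows a template past six AUs,
which collapses recovery for exactly those observers. At 0.2 one or two
active template AUs suffice across realistic template sizes (4-10),
giving 5-10% response rates per affect (a few hundred categorized trials
per session) and stable recovery. The threshold is per-observer
configurable.

Validation task: each displayed model is shown on 10 face identities
(simulated as i.i.d. repeats — no identity effect is modeled) once with
the matching word and once with the mismatching word; with 20 model
pairs this yields 400 distinct stimuli and 800 trials per observer,
exactly half matched. The yes/no answer applies the same overlap rule to
the model's AU set against the observer's own template for the cued
word.

## Fitting

Per observer, "other" trials are excluded and the response coded
pain = 0 / orgasm = 1 (how to treat "other" is unspecified in the
source procedure; exclusion is the reading consistent with a binary
coding). Each AU's presence is phi-correlated with the response; the
p-value uses the t transform with n-2 df, which at thousands of trials
is indistinguishable from exact methods. Significance is unadjusted
two-tailed p < .05 per AU — deliberately, as that is the procedure being
reproduced; the expected false-positive load is ~0.05 x 42 = 2.1 AUs per
observer. AUs with constant presence across retained trials are left
non-significant and flagged rather than erroring the whole fit.

Temporal coefficients regress the binary response on the seven
parameters over retained trials where the AU is active (whether the
original pooled all trials is ambiguous; the choice is recorded in the
model notes). Intensity gradients regress the 1-5 rating over
matching-affect trials. Both require ≥ 9 qualifying trials
(7 parameters + 2); scarcer cells yield `None` with a note instead of an
error, since significant AUs can legitimately have few active trials.
The "high-intensity" profile averages parameters over matching-affect
trials rated 4-5 (the cut is not defined upstream; 4-5 is the natural
upper band of a 5-point scale); element-wise means of valid profiles
provably satisfy the profile invariants.

## Distinctiveness

The classifier is Bernoulli naive Bayes over the 1x42 binary vectors —
the minimal faithful reading of "a Bayesian model" of the discrimination
task — with Laplace alpha = 1 and priors proportional to class size.
Split-half: each class is halved at random, training on one half and
evaluating mean posteriors on the other, repeated 1,000 times (the
repetition count is unstated upstream). The SD is reported both across
splits and across held-out models, since either convention occurs in
the literature.

d' applies the log-linear correction (add 0.5 to each cell, 1 to each
denominator) always rather than conditionally, avoiding
conditional-on-extremity bias; quadrants are assigned from the corrected
rates against 0.5, with exact ties going to the non-discriminated side.
The 2x2 chi-square is the plain Pearson statistic without Yates
correction, df = 1.

## Information analysis

MI is the plug-in estimator in bits without bias correction: it is used
as an effect-size screen under a permutation null, where estimator bias
cancels between observed and permuted values. The max-statistic test
shuffles labels 1,000 times, records the maximum MI across tested AUs
per iteration, includes the observed maximum in the null distribution,
and thresholds at the nearest-rank 95th percentile with a strict
inequality — a conservative variant that guarantees familywise validity.
The highly-frequent screen's null permutes each model's AU positions,
preserving per-model AU counts (the upstream Monte Carlo is not fully
specified; a pooled-frequency variant is available behind
`method="pooled"`). The specific/common partition reports AUs that fit
neither definition as "unclassified" instead of forcing them into a
category.

## Production comparison

Hamming distances are computed on the full 42-dimensional binary
vectors, so shared absences count toward similarity. Nearest-pattern
ties across affects resolve by majority affect among the tied patterns,
then by smaller mean distance to each affect's full pattern set, then to
pain (flagged) — the source procedure never mentions ties. Majority sets
use a strict > 50% rule. The packaged 11 pain + 3 orgasm patterns are
synthetic-consistent: real per-study AU tables are not redistributable,
so the fixture is constructed to reproduce the published set-level
relations (production-shared {4, 6, 10, 25, 26, 27, 43}; pain
production-only {7, 17, 45}; pain model/production convergence
{4, 6, 9, 10, 12, 20}; orgasm convergence {25, 26, 27, 43}) while
varying per-study composition. Conclusions about any individual study
cannot be drawn from it.

## Problem sizes and reproducibility

Default analysis sizes are the study conditions: 40 observers per
culture x 3,600 trials; 1,000 split-half repetitions; 1,000 permutation
iterations; 26 validation observers x 800 trials over 20 model pairs x
10 identities. The permutation-calibration checks use 500 replicate null
datasets, and the cross-cultural pattern check uses 20 replicate
permutation runs on one fitted cohort pair (re-simulating the full
cohorts per replicate adds nothing to a check of the permutation
machinery). A single root seed spawns per-stage child generators
(`numpy` `SeedSequence.spawn`), so any stage can be re-run in isolation
and full runs are byte-identical given (seed, config).

## What the synthetic results do and do not show

Passing recovery and distinctiveness checks show that the estimators
faithfully invert *this* generative observer: linear template matching,
independent trials, no learning, fatigue, sequential dependence,
reaction times, or face-identity effects, and noise exactly as
parameterized. They do not certify performance on human data, whose
response process is unknown and richer. Quantities printed by the
benchmark study (posteriors of 0.96-0.99, a specific chi-square value)
are functions of its unreleased human-derived models; the pipeline
reproduces their qualitative structure (near-ceiling posteriors,
overwhelmingly "discriminated" quadrant occupancy, cross-culturally
shared pain AUs with orgasm-specific accents 5/26/27 vs 12), not their
exact values.

Known limitations: the MI analysis covers AU presence only (no
temporal-parameter information measures); no ROC machinery beyond d';
no hierarchical signal-detection modeling; production comparison is
Western-only, as sufficient East Asian production data are not
available.
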