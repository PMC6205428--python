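# revcorrfaces

Reverse-correlation modeling and comparison of dynamic facial-expression
representations of physical pain and orgasm.

Observational studies report that people experiencing intense pain or
orgasm produce facial expressions that look remarkably similar, which
raises the question of whether these expressions can communicate at all.
One way to probe this is to model the *mental representations* observers
hold of each expression: present random dynamic facial animations — built
from FACS action units (AUs) with random temporal dynamics — ask the
observer whether each animation looks like pain, orgasm, or neither, and
recover the AUs statistically associated with each judgment.
`revcorrfaces` implements that pipeline end to end for researchers in
computational psychophysics: stimulus generation, per-observer model
fitting, distinctiveness analyses (Bayesian classification, signal
detection), mutual-information comparisons with permutation nulls, and a
comparison against the AU patterns reported by production studies.  A
synthetic-observer module provides ground-truth cohorts so every stage
can be exercised and its parameter recovery measured without human data.

## The method

- **Stimuli** (`stimgen`). Each trial activates 1-4 of 42 AUs (median 3);
  each active AU gets a seven-parameter temporal profile (onset latency,
  acceleration, peak amplitude, peak latency, sustainment, deceleration,
  offset latency) over a 2.25 s animation. Faces are never rendered; the
  stimulus is the numeric AU time course.
- **Observers** (`synthetic_observer`). A simulated observer holds an AU
  template per affect and responds by template overlap with a lapse rate
  and noisy 1-5 intensity ratings; cohorts default to 40 observers per
  culture (Western / East Asian), 3,600 trials each, plus an 800-trial
  yes/no validation task.
- **Fitting** (`revcorr_fit`). For each AU, the phi (Pearson) correlation
  between per-trial presence and the binary response (pain = 0,
  orgasm = 1; "other" trials excluded) selects the significant AUs
  (two-tailed p < .05); the sign routes each AU to the pain or orgasm
  model, so the two models of one observer are disjoint. OLS regressions
  relate the temporal parameters to the response and to intensity, and
  high-intensity trials (ratings 4-5) define the salient mean profile.
- **Distinctiveness** (`distinctiveness`). Split-half Bernoulli naive
  Bayes over the 1x42 binary model vectors (Laplace alpha = 1, 1,000
  splits); per-model d' = Phi^-1(H) - Phi^-1(F) with a log-linear
  correction, and quadrant assignment by hit/false-alarm rates vs 0.5.
- **Information analysis** (`infostats`). Plug-in mutual information
  (bits) between AU presence and a label, tested with a max-statistic
  permutation scheme (1,000 label shuffles, 95th percentile of the
  per-iteration maximum MI) restricted to Monte-Carlo-screened "highly
  frequent" AUs; run within culture (pain vs orgasm) and across cultures
  per affect.
- **Production comparison** (`production_compare`). Hamming
  nearest-neighbor classification of fitted models against per-study
  production AU patterns, a 2x2 chi-square on the confusion matrix,
  majority AU sets, and the four-set Venn partition of model/production
  pain/orgasm AUs. (The packaged patterns are a synthetic-consistent
  stand-in; supply your own JSON for real per-study tables.)

## Worked example

Simulate one Western observer, fit their models, and inspect the result:

```python
import numpy as np
from revcorrfaces import make_template, simulate_observer_log, fit_models

rng = np.random.default_rng(1)
template = make_template("western", rng=rng, add_prob=0.05, drop_prob=0.05,
                         observer_id="western_00")
log = simulate_observer_log(template, 3600, rng)
pain, orgasm = fit_models(log)
print(sorted(template.pain_aus), "->", sorted(pain.au_set))
print(sorted(template.orgasm_aus), "->", sorted(orgasm.au_set))
```

Output:

```
[4, 6, 9, 10, 14, 20] -> [4, 6, 9, 10, 14, 20]
[2, 5, 26, 27, 33, 43] -> [2, 5, 12, 26, 27, 33, 43]
```

This observer's template varied from the group template (AU14 added to
pain, AU33 to orgasm, AU1 dropped from orgasm). Of 3,600 trials, 220 were
categorized as pain and 185 as orgasm; the fit recovered every template
AU (e.g. AU4, brow lowerer: r = -0.23, p = 2.9e-06, negative sign =
pain) with one false positive (AU12 in the orgasm model), in line with
the two-tailed alpha = .05 screen.

The whole chain — simulate both cohorts, fit 160 models, classify, run
the validation task and the MI analyses, and compare against production
patterns — runs from one config:

```sh
revcorrfaces run-all --seed 0 --out runs/demo
revcorrfaces report runs/demo
```

Individual stages are available as subcommands (`simulate`, `fit`,
`frequent`, `bayes`, `dprime`, `mi`, `crossculture`,
`compare-production`).

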