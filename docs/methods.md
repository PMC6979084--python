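# Methods

## Model and assumptions

The package estimates the accuracy of two imperfect EIPH tests without a
gold standard by latent-class analysis. Each exercised exam event carries an
unobserved disease indicator `z ~ Bernoulli(prev)`. Conditional on `z`:

* the natural log of the lavage red-cell concentration (BALFRBC, cells/μL)
  is normal — `N(mu_pos, sigma_pos²)` when EIPH occurred, `N(mu_neg,
  sigma_neg²)` when it did not — i.e. the count itself is lognormal within
  each class;
* the binarized endoscopy outcome (TBE score ≥ 1) is Bernoulli with
  probability `se_tbe` given EIPH and `fpr_tbe` given no EIPH.

Sedentary (non-exercised) lavages are treated as true negatives by design:
their probability of EIPH is fixed at 0, they contribute only to the
negative biomarker component, and they carry no endoscopy outcome. The
exercised EIPH-negative events share the sedentary negative component; the
model therefore assumes that the biomarker distribution of a horse that
exercised but did not bleed equals that of a sedentary horse. Events are
treated as independent even when one horse contributes several; no
within-horse random effects are modeled.

The latent indicators are marginalized analytically, giving each exercised
record the two-component mixture likelihood

```
prev · N(y; mu_pos, sigma_pos) · se^t (1−se)^(1−t)
  + (1−prev) · N(y; mu_neg, sigma_neg) · fpr^t (1−fpr)^(1−t)
```

Marginalizing rather than sampling the indicators targets the same
posterior while making the density a pure function that can be unit-tested
against direct scipy evaluation.

## Priors

| parameter | prior | rationale |
|---|---|---|
| mu_pos, mu_neg | Normal(0, 100) (SD parameterization) | diffuse on the log scale |
| sigma_pos, sigma_neg | Uniform(0, 100) | diffuse; log-scale SDs are O(1) |
| se_tbe | Uniform(0, 1) | endoscopy sensitivity is the unknown of interest |
| fpr_tbe | Uniform(0, 0.01) | informative: visible airway blood after exercise essentially never occurs without hemorrhage |
| prev | Uniform(0, 1) | exercised prevalence unknown a priori |

The informative false-positive prior is what anchors the model; its upper
bound is therefore the subject of the built-in sensitivity analysis
(`prior_sensitivity`), which refits with the bound scaled ±10% (0.009 and
0.011) and reports the drift of every posterior mean.

## Sampler

Adaptive random-walk Metropolis-within-Gibbs on the marginalized log
joint: one Gaussian proposal per parameter per sweep, with per-parameter
proposal scales doubled/halved on a Robbins–Monro schedule (step
min(0.25, 1/√batch), batches of 50 sweeps, target acceptance 0.44) during
burn-in only, so the retained portion is a valid Markov chain. Defaults are
4 chains × 15,000 sweeps with the first 5,000 discarded, no thinning.
Starts are dispersed and data-informed (sedentary mean/SD for the negative
component, upper-quantile exercised logs for the positive one).

The mixture is made identifiable by rejecting proposals with
`mu_pos < mu_neg`, reflecting the biological direction (hemorrhage raises
counts); every retained draw satisfies the constraint. Proposals outside
the prior box are rejected via a −∞ prior; SDs are required strictly
positive even though the uniform prior's lower bound is 0.

Diagnostics: split R-hat by the classic potential-scale-reduction formula
(half-split chains, `sqrt(((n−1)/n·W + B/n)/W)`) and effective sample size
by Geyer initial-monotone truncated autocorrelation sums, both
cross-checked against arviz in the test suite. A fit reports
`converged=True` when all R-hat ≤ 1.05; any R-hat > 1.1 raises an explicit
warning flag in the result (never silent).

MAP: the retained draw with the highest joint posterior density (default),
with a per-parameter kernel-density marginal mode available behind a flag.
Credible intervals are equal-tailed 2.5/97.5 percentiles. Note that for a
parameter whose posterior is essentially its flat prior (fpr_tbe when the
data contain no false positives), the joint-MAP coordinate is arbitrary
within the prior range and should not be over-read; the posterior mean is
the stable summary there.

## ROC and threshold selection

Given component parameters, the rule "positive iff BALFRBC ≥ c" has
closed-form sensitivity `1 − Φ((ln c − mu_pos)/sigma_pos)` and specificity
`Φ((ln c − mu_neg)/sigma_neg)`. Precision uses Bayes' rule at an assumed
prevalence, fixed at 0.5 by default so the recommended cutoff is
discipline-agnostic (overridable). The F1 objective is the harmonic mean
of precision and recall — the standard definition; a geometric-mean
variant (Fowlkes–Mallows) is available behind a flag for comparison.

The optimum is located by a 4,001-point grid over
`[mu_neg − 5·sigma_neg, mu_pos + 5·sigma_pos]` on the log scale followed by
bounded scalar refinement between the argmax's grid neighbours
(tolerance 1e-10 on the log threshold). Grid-then-refine is used instead of
root-finding because F1 over thresholds can be flat or boundary-maximized:
for indistinguishable components the F1 supremum (2/3 at balanced
prevalence) is approached in the classify-all-positive limit, and the
result is returned flagged `boundary=True` rather than chased to −∞.
Thresholds are reported to full precision internally and rounded to whole
cells/μL only in reports. The optimizer agrees with a 10⁶-point brute-force
grid to within 0.5% of the natural-scale threshold across an 81-setting
component grid in the test suite.

## Descriptive layer

* Spearman correlation: average ranks for ties, two-sided p from the
  t-approximation on n−2 df (backed by `scipy.stats.spearmanr`; validated
  exhaustively against a sort-based rank-Pearson oracle on small inputs,
  where an exact permutation p would also be feasible).
* Repeat-lavage comparison: one-way repeated-measures ANOVA (backed by
  `statsmodels` AnovaRM); with two occasions F equals the squared paired-t
  statistic identically, which the suite asserts to 1e-10. The degenerate
  zero-within-change case returns F=0, p=1 explicitly.
* Pooled summaries reconstruct the total sum of squares (within + between,
  N−1 denominator), so pooling the two printed sedentary occasion summaries
  (9, 286, 160) and (9, 322, 194) gives mean 304 exactly and SD 173.5 —
  within ±1 of the 173 computed from the raw data, the discrepancy being
  input rounding.
* Cross-tabulation calls a count equal to the threshold positive (≥, per
  the threshold's definition); a strict-inequality flag exists because
  usage in prose is sometimes loose. Percentages are always carried with
  numerator and denominator.
* The all-score overlap interval is the intersection of per-score observed
  ranges: max of minima to min of maxima, empty when crossed.

## Synthetic cohorts

`generate_cohort` draws exactly the model's generative process: Bernoulli
latent status, status-conditional lognormal counts, status-conditional
Bernoulli endoscopy positivity. Default design mirrors the study: 102
exercised events plus 9 sedentary horses lavaged twice. Default parameters
(`default_study_params`) are the study's point estimates where printed —
endoscopy sensitivity 0.59, false-positive probability 0.005 (the
informative prior's midpoint), prevalence 0.96 (the lavage-based
Thoroughbred estimate) — and documented moment-matched choices elsewhere:
the negative component matches the pooled sedentary 304 ± 173 cells/μL
(mu_neg ≈ 5.577, sigma_neg ≈ 0.530), and the positive component
(mu_pos = 9.0, sigma_pos = 1.5) puts its median near 8,100 cells/μL,
between the observed medians of moderate endoscopy grades, with enough
spread to reproduce the heavy upper tail. Severity grades 1–4 decorate
synthetic endoscopy positives with probabilities proportional to the
observed grade frequencies (59:54:18:4); the latent-class model itself is
binary in TBE, so grades affect descriptive outputs only.

What the generator does **not** emulate: within-horse correlation across
repeated exams, time-from-exercise effects on either test, any departure of
real biomarker tails from lognormality, and ordinal (per-grade) endoscopy
information. Passing tests therefore demonstrate internal consistency of
the estimation machinery under the model's own assumptions, not robustness
to these real-data features.

All randomness flows from one master seed per cohort/fit
(`numpy.random.default_rng` with spawned per-chain sequences); identical
seeds give byte-identical cohorts, draws, and pipeline reports.

## Problem sizes and numerical choices

The default sampler configuration (4 × 15,000) is used for the
prior-dominated specificity check. The repeated parameter-recovery study in
the test suite runs 20 cohorts of 500 exercised events with shortened
chains (4 × 2,500, 750 burn-in), which the diagnostics show mix fully for
this 7-parameter posterior; coverage of the 95% intervals is asserted at
the binomial-tolerance level ≥ 18/20. Degenerate inputs are handled
explicitly: empty cohorts, missing endoscopy on exercised records, constant
correlation inputs, unbalanced repeated-measures layouts and non-positive
counts all raise errors naming the offending input; mixture weights of
exactly 0 or 1 are valid and reduce to the single-component likelihood.

## Known limitations

* Single-threshold accuracy: credible intervals for the thresholded
  biomarker's sensitivity/specificity are not propagated from the posterior
  (the threshold is derived from the MAP fit only).
* The exercised-negative and sedentary biomarker distributions are
  assumed identical; with only 18 sedentary lavages this assumption is
  barely testable from data of the study's size.
* Adaptation freezes at the end of burn-in; pathological posteriors (e.g.
  near-empty mixture components at tiny n) may need longer burn-in or
  manual proposal scales via `McmcConfig.proposal_scales`.
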