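# Methods

This note records the statistical conventions, algorithmic choices and
modeling assumptions behind `lncpairsig`, at the level of detail needed
to reproduce or audit a run.

## Input formats

All inputs are tab-separated text (`.csv` is also accepted for the
expression matrix). Expression is genes × samples on the raw FPKM scale;
negative values are rejected, duplicate gene rows are collapsed by mean.
The clinical table needs columns `sample`, `futime` (days), `fustat`
(1 = death); `stage`, `T`, `M`, `N`, `age` are used when present.
Records with follow-up < 31 days are removed before any modeling, and
duplicate samples keep the first occurrence.

## Pair indicator

For an unordered gene pair stored canonically as (A, B) with A < B
lexicographically, the covariate in sample *s* is
`C(s) = 1 if FPKM_A(s) >= FPKM_B(s) else 0`. Ties therefore score 1 in
the canonical orientation; flipping the orientation complements the
indicator on tie-free data. The indicator is invariant to any strictly
positive per-sample rescaling, the property that motivates the design.
Pairs whose prevalence (fraction of fitting samples with C = 1) is not
strictly inside (0.2, 0.8) are dropped as uninformative; prevalence is
computed on the samples actually used for model fitting (tumor samples
with valid clinical records).

## Screens

*Immune co-expression.* Pearson correlation between each lncRNA and each
immune gene on log2(FPKM + 1) over tumor samples; two-sided p from the
t distribution with n − 2 degrees of freedom. A lncRNA passes when some
immune gene gives r > 0.4 **and** p < 0.001 (signed threshold, as in the
original protocol; no multiplicity correction at this stage).
Zero-variance genes are skipped.

*Differential expression.* The original protocol used a moderated
linear-model test; with only expression values and no replicate-level
modeling required here, we use the two-sample Wilcoxon rank-sum test on
log2(FPKM + 1) per gene, tumor vs normal, with the asymptotic
tie-corrected normal approximation. Fold change is the difference of
group means on the log2(FPKM + 1) scale. A gene passes when
|log2FC| > 1 and Benjamini–Hochberg FDR < 0.05. The BH adjustment is the
standard step-up procedure, implemented and unit-tested against the
brute-force definition.

## Cox partial-likelihood engine

Single implementation used for the univariate screen, the stepwise
refinement, the final multivariate model and the independence analyses:

- Efron approximation for tied event times.
- Newton–Raphson with step-halving enforced on the partial
  log-likelihood (up to 30 halvings per iteration), ridge-regularized
  solve as fallback for singular Hessians.
- Convergence when the gradient max-norm or step max-norm falls below
  1e-9 (50 iterations max).
- Monotone-likelihood (separation) detection: any |beta| exceeding 20
  during or after iteration flags the model as non-converged with a
  warning; such covariates are excluded from the univariate screen's
  retained set.
- Wald standard errors from the inverse Hessian; AIC = 2k − 2·loglik.

The engine is validated three ways in the test suite: against
brute-force grid maximization of the explicitly coded partial
likelihood on small tie-free instances (≤ 1e-4), against an independent
reference implementation on tied data, and by checking the null
distribution of Wald p-values for uniformity.

## LASSO-Cox selection

The L1-penalized Cox path is fit with `scikit-survival`'s Coxnet
(30 penalties, `alpha_min_ratio` 0.05). Cross-validation error is the
Verweij–van Houwelingen partial-likelihood deviance
−2·(ll_all(β) − ll_train(β)), evaluated with the in-repo Efron
log-likelihood so the CV criterion is independent of the path solver.
K-fold CV (default 10 folds) is repeated with reshuffled folds and the
deviance averaged over all folds and repeats; the original protocol ran
1000 such cycles, the default here is 10 (3 in the acceptance runs) as a
pure runtime knob — the selection rule is unchanged and configurable via
`lasso_repeats`. If the deviance-minimizing penalty keeps no covariate,
the largest penalty with at least one nonzero coefficient is used.

## Stepwise refinement

Among the LASSO-selected pairs, the AIC-minimal Cox model is found by
exhaustive best-subset search when ≤ 12 pairs remain (guaranteeing the
global AIC optimum over subsets) and by backward elimination otherwise.
The final multivariate coefficients are the signature weights W_i.

## Time-dependent ROC and cut-off

At horizon *t*, cases are subjects with an event by *t* (cumulative) and
controls subjects still event-free at *t* (dynamic). Following the
Kaplan–Meier estimator of Heagerty, Lumley and Pepe (as in
`survivalROC`):

```
sens(c) = [1 − Ŝ(t | X > c)] · P(X > c) / [1 − Ŝ(t)]
spec(c) =      Ŝ(t | X ≤ c)  · P(X ≤ c) /      Ŝ(t)
```

with Ŝ the product-limit estimator. Thresholds are the midpoints
between consecutive unique scores plus ±∞ sentinels; raw sensitivities
and specificities are clipped to [0, 1] and monotonized by running
maxima from the appropriate end. AUC is the trapezoid integral of the
curve traversed in order of decreasing threshold. On fully uncensored
data this reproduces the Mann–Whitney AUC to machine precision (an
acceptance criterion). The cut-off maximizes sens + spec (Youden-type);
exact ties go to the smaller threshold. The high-risk group is
RiskScore > cut-off (strict). A horizon at which Ŝ(t) is 0 or 1 (no
controls or no cases) makes the ROC undefined and raises an error rather
than returning a degenerate value.

## Evaluation statistics

- Log-rank test: standard two-group 1-df test (via `lifelines`).
- Kaplan–Meier: in-repo product-limit estimator; at tied times events
  precede censorings.
- Chi-square: Pearson statistic without continuity correction; a
  warning is emitted when any expected count is < 5.
- Rank-sum comparisons (risk score across clinical strata, immune
  fractions and IC50 across risk groups): two-sample Wilcoxon rank-sum
  (Mann–Whitney) with the asymptotic tie-corrected p. These groups are
  independent samples, so the rank-sum test, not the paired signed-rank
  test, is the appropriate form.
- Independence Cox: univariate and multivariate models over ordinally
  coded stage/T/M/N, age and the risk score; exactly collinear
  covariates are dropped (later-listed first) with a warning.
- Immune correlation: Spearman rho per cell type with the t-based
  two-sided p.

## Synthetic cohort generator

The generator plants a known ground truth so recovery can be scored:

- **Expression.** Gene-level log2 means: lncRNAs U(2, 7), immune genes
  U(3, 8). A single latent immune factor per sample drives both all
  immune genes and the designated co-expressed lncRNAs (loading 0.8,
  residual sd 0.6, giving pairwise correlations ≈ 0.64 on the log
  scale); remaining genes get independent noise. FPKM = 2^x.
- **Differential expression.** DE genes are shifted ±1.5 log2 units in
  tumor samples (80% up), drawn from the co-expressed set first so the
  screening funnel has survivors.
- **Prognostic pairs.** True pairs use disjoint DE genes with matched
  shift direction and close means (Δμ ~ U(−0.5, 0.5)), keeping indicator
  prevalence inside the filter window. Each pair gets β ∈
  [0.8, 1.2] (sign-symmetric option via `beta_range`); the true linear
  predictor η is computed from the *exact* realized indicators.
- **Survival.** Event times are exponential with rate
  `baseline_hazard · exp(η)`; censoring is exponential with its rate
  calibrated by bisection (including the administrative truncation at
  3650 days) to a target censoring fraction of 0.6, a typical value for
  cohorts of this kind. `baseline_hazard = 1e-4`/day puts the median
  survival of a typical η ≈ 2 sample near 2.5 years, so that few
  subjects fall under the 31-day follow-up filter while the 1/3/5-year
  horizons remain informative.
- **Clinical covariates.** Stage/T/M/N are drawn from cumulative-logit
  models monotone in η, and age from a normal distribution, so the
  planted signal propagates into the clinicopathological tables.
- **Immune fractions and IC50.** Inverse-logit and linear functions of η
  respectively, with per-cell-type / per-drug slopes recorded in the
  ground truth.
- **Reproducibility.** The cohort *structure* (gene means, pair choices,
  slopes) and the *sample draw* use separately spawned seed streams, so
  an independent validation cohort can be drawn from the same structure
  with a different `sample_seed`. A single pipeline seed fans out to
  per-stage seeds by stable hashing of the stage name.

## Limitations

- The 5-year ROC is undefined when a cohort's follow-up ends before the
  horizon with the last observation an event (Ŝ(t) = 0); heavily
  censored simulated cohorts occasionally hit this, and the code raises
  instead of extrapolating.
- Wald p-values from the univariate screen are asymptotic; with few
  events per pair they are approximate, as in the original protocol.
- Pair indicators built from overlapping genes are correlated, so the
  univariate screen's retention rate under the null is only
  approximately the nominal level (verified within Monte-Carlo error in
  the acceptance tests).
- Exhaustive best-subset search is exponential and therefore capped at
  12 candidates; beyond that, backward elimination may return a local
  AIC optimum.
- IC50 comparisons use simulated sensitivities; no pharmacogenomic
  model fitting is implemented.
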