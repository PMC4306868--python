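# Methods

## The DeFries–Fulker regression

DF analysis estimates behavior-genetic variance components by ordinary
regression on kinship pairs that differ in genetic similarity. In the
mean-centered form used here as the default,

    K1 = b0 + b1 (K2 − Km) + b2 [R × (K2 − Km)] + e,

the expected within-pair regression slope at relatedness R is
b1 + b2·R. With MZ pairs (R = 1) and DZ pairs (R = 0.5) this pins down
b1 = c² (shared environment) and b2 = h² (heritability), since under
the ACE model the double-entered slope equals the twin correlation,
rMZ = h² + c² and rDZ = 0.5·h² + c². The residual share 1 − b1 − b2 is
nonshared environment confounded with measurement error. The classical
uncentered equation (`eq1`, with a main-effect R term whose coefficient
is not interpreted) is implemented for completeness; the centered form
(`eq2`) and its extension with difference scores (`eq3`) are the
defaults because they are the forms used for substantive estimates.

Specific nonshared environments enter `eq3` as ENVDIF difference
scores, focal twin minus co-twin. These are ordinary regression
coefficients in outcome units per covariate unit, judged by t tests,
not latent variance shares.

### Double entry and inference

Every usable pair contributes two rows with the focal/co-twin roles
swapped, which uses all the information in a pair but duplicates each
observation. Naive OLS standard errors would therefore be too small.
We use the cluster-robust sandwich estimator with twin pair as the
cluster,

    (X'X)^-1 [ Σ_g X_g' u_g u_g' X_g ] (X'X)^-1,

scaled by the CR1 small-sample factor G/(G−1) · (N−1)/(N−k), with test
statistics referred to Student's t on G − 1 degrees of freedom
(G pairs, N rows, k coefficients). This is the convention of classical
survey-regression software; CR0 (no factor) is available via
`fit(cov="cr0")`. The choice of variant is a documented package
decision — at several hundred clusters the difference is negligible,
and the Monte-Carlo calibration test confirms the null rejection rate
of an ENVDIF t test sits at the nominal 5% level and that 95%
intervals for b1/b2 cover at the nominal rate.

### Numerical choices

- OLS is solved by QR (`numpy.linalg.lstsq`); residual orthogonality is
  asserted in tests at 1e-8.
- Rank deficiency is detected before fitting via pivoted QR with
  tolerance `max(diag R) · max(n, k) · eps`, and reported with the
  names of the collinear columns. The canonical degenerate input is
  single-zygosity data, where R is constant and the interaction column
  duplicates the co-twin column; the model constructor additionally
  refuses single-zygosity samples outright since b1 and b2 are then not
  separately identified.
- Km is the mean of K2 over the rows actually entering a model, i.e.
  it is recomputed after listwise deletion for each model, so every
  fitted model is self-contained. (Whether to center before or after
  deletion is genuinely open; per-model centering keeps each reported
  model internally consistent.)
- The deletion unit is the pair: if either twin lacks any variable a
  model uses, both rows drop, because K2 and ENVDIF are undefined
  otherwise. Reported N counts twins (rows), which is twice the number
  of pair clusters.
- Variance shares are reported unconstrained. Estimates outside [0, 1]
  raise a warning but are never truncated — the DF estimator is a plain
  regression, and truncation would hide misfit.
- Covariates are never standardized; ENVDIF coefficients stay on the
  raw scale (e.g. percentile points per weekly fast-food day), and for
  binary covariates the difference scores take values in {−1, 0, 1}.

## Survey measures

Seven diet/activity risk measures are constructed from raw adolescent
survey items, all oriented so that higher = more at-risk:

- **fast_food**: weekly fast-food days, 0–7, validated pass-through;
- **low_veg**: 1 iff none of twelve ate-yesterday vegetable flags is
  set. If every observed flag is 0 but one is missing, the result is
  missing — consumption cannot be ruled out. (The alternative —
  treating a partially missing battery as 0 — is defensible; the
  stricter rule was chosen and is flagged here.)
- **meal_dep**: proportion of the 21 weekly main meals skipped,
  ((7−b)+(7−l)+(7−d))/21;
- **low_sport / low_cycle / low_exercise**: activity frequency
  categories (0 = not at all, 1 = 1–2, 2 = 3–4, 3 = 5+ times per week)
  reverse-coded as 3 − category;
- **insuff_ex**: 1 iff the week's total activity bouts across the
  three items fall below the five-session guideline. The categorical
  items report ranges, not counts, so a bouts-per-category mapping is
  required; we use interval midpoints 0, 1.5, 3.5 and the guideline
  value 5 for the open-ended top category. Any single item at "5 or
  more times" therefore suffices on its own. The mapping is a package
  decision and is configurable via the `bout_map` argument.

Missingness propagates through every constructor; models apply
pairwise listwise deletion, never imputation, so sample sizes vary
across models exactly as they do in survey practice.

## The synthetic twin generator

The simulator emulates the structure of a same-sex twin subsample of a
national adolescent health survey. The latent outcome is

    Y* = √h²·A + √c²·C + √e²·E + Σ_j β_j X_j,

with A, C, E standard normal; C shared within pair; E independent per
twin; and A identical within MZ pairs and correlated 0.5 within DZ
pairs (√0.5·A_shared + √0.5·A_unique per member). The DZ genetic
correlation is fixed at 0.5 with no assortative-mating or dominance
options, mirroring the model class the DF estimator assumes. Without
covariates Y* has unit variance and the classical twin correlations
hold exactly in expectation.

Covariates come in the four types found in the survey's descriptives —
bounded counts (binomial), binaries, discretized proportions
(binomial/denominator) and 0–3 ordinals — drawn per member through a
Gaussian copula whose within-pair correlation is a parameter
(default 0, i.e. covariates are purely nonshared; the joint
distribution of real co-twins' covariates is unknown, so it is exposed
rather than asserted). Causal effects β_j act on the latent scale
*before* percentile scoring.

The percentile transform replaces each score by 100 × (share of the
sample scoring strictly lower), giving a near-uniform marginal on
[0, 100) with SD ≈ 28.9. It is monotone, so it preserves ranks but
compresses the tails; covariate effects measured after the transform
are attenuated relative to their latent β. Recovery experiments
therefore run on the raw latent scale by default, and percentile-scale
ENVDIF coefficients from study-scale runs should be read as
transform-attenuated — a caveat that applies equally to real
percentile-scored outcomes.

The study-scale default configuration (`study_default_config`) uses
490 pairs with 53% MZ, ACE shares (h², c², e²) = (0.27, 0.44, 0.29) —
the decomposition a baseline DF fit typically reports for verbal
ability in such samples — and seven covariates whose marginals match
the survey's published means/SDs (e.g. weekly fast-food days
binomial(7, 0.324) for a mean of 2.27; a 25% no-vegetable rate; a 38%
insufficient-exercise rate). Default causal effects place the
published percentile-point coefficients on the latent scale by
dividing by 28.9 (the percentile-scale SD), with the three
single-activity items given zero effect, matching their null results.
Binomial marginals understate the overdispersion of real count items;
this affects realism of covariate spread, not the estimator
properties under test.

What passing tests show — and do not show. The generator draws from
exactly the ACE-plus-linear-covariates model the estimator assumes, so
recovery tests demonstrate correctness of the implementation, not
robustness to assortative mating, dominance, rater effects, age/sex
structure, or informative missingness, none of which are simulated
(missingness is only available as uniform pair dropout).

## The model suite

`run_model_suite` mirrors the reporting layout of a twin study
screening diet and exercise measures: for the nutrition table a
baseline and the three measures jointly and one at a time; for the
exercise table a baseline and the four measures jointly and one at a
time; and one full sensitivity model with all seven measures — twelve
blocks in total. The two per-table baselines are the same model and
must produce identical estimates (tested). Each block applies its own
pairwise listwise deletion and reports its own N and R².

## Monte-Carlo problem sizes

The validation experiments use 200 replicates at 1000 pairs per
zygosity for ACE-share recovery (Monte-Carlo SE of the mean ≈ 0.004),
single samples of 5000 pairs per zygosity for agreement with the
Falconer estimator 2(rMZ − rDZ), 2000 pairs per zygosity for recovery
of an injected ENVDIF effect of −1.0, and 1000 replicates at 500 pairs
per zygosity for the null-covariate type-I error (95% binomial band
0.05 ± 0.0135). These sizes make the Monte-Carlo error small relative
to the effects being checked while keeping the whole suite fast.

## Known limitations

- No maximum-likelihood ACE structural-equation fitting, bootstrap
  inference, survey weights, multiple imputation or multiple-testing
  adjustment; half-sibling/cousin relatedness codes are unsupported.
- The variance decomposition inherits all DF-regression caveats:
  estimates are unconstrained, c² and h² are strongly negatively
  correlated, and percentile scoring attenuates covariate effects.
- The simulator's covariates are cross-sectionally independent of the
  latent A/C/E factors; gene–environment correlation and interaction
  are out of scope.
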