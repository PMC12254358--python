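# Methods

## The twin model

The engine fits multivariate-normal models to twin-pair observation
vectors. For a trait pair the observation is
(trait1_twin1, trait2_twin1, trait1_twin2, trait2_twin2); the
univariate model is the one-trait special case. Identification rests on
the classical twin-design assumptions: additive-genetic factors
correlate 1.0 between MZ and 0.5 between DZ co-twins, the shared
environment correlates 1.0 in both groups, the non-shared environment
is uncorrelated between co-twins, and means/variances do not depend on
twin order or zygosity (the latter is testable, see below). Same-sex
and opposite-sex DZ pairs are pooled into one DZ group: phenotypes are
residualized on sex before modelling, and no sex-limitation model is
fitted. Each component covariance block (A, C, E) is parameterized by a
lower-triangular Cholesky factor, which enforces positive
semi-definiteness; standardized components and the factor correlations
rA/rC/rE are derived quantities, never free parameters. The
mathematically equivalent correlated-factors parameterization
(per-trait standard deviations plus a tanh-mapped correlation) is
available and used in tests to confirm both yield identical likelihoods.
A single grand mean per trait is kept as a free parameter so the engine
also works on non-residualized input.

## Likelihood and missing data

Estimation is casewise full-information maximum likelihood: each pair
contributes the log density of its observed subvector, with the mean
and covariance subset to the observed indices. Internally observations
are grouped by missingness pattern and reduced to per-pattern counts,
means and scatter matrices; the likelihood is then evaluated from these
sufficient statistics, which is algebraically exact and makes one
evaluation independent of sample size. `PairData.from_moments` feeds
exact population moments through the same code path, which is how the
closed-form oracle checks (Falconer estimators, CTCT identities) are
run without sampling noise.

## Saturated models and assumption tests

Three constraint levels: (0) free means and free 4x4 covariance per
zygosity group; (1) per group, means and variances equated across twin
order and the two cross-twin cross-trait covariances equated (the
cross-twin block becomes symmetric); (2) means and variances
additionally equated across zygosity, while within-twin cross-trait and
cross-twin covariances stay free per group — these are exactly the
quantities the twin and CTCT correlations are read from. Likelihood-
ratio tests between successive levels are the assumption tests. The
model chain saturated(0) > ACE > {AE, CE} > E is nested throughout, and
the ACE fit is also compared against the fully saturated model.

## Model selection and decomposition

Nested AE/CE/E fits are compared to ACE with central chi-square
likelihood-ratio tests (degrees of freedom = difference in free
parameter counts). Variance components on the boundary make the central
chi-square conservative for dropping C; this standard convention is
kept deliberately. Among non-rejected nested models the one with the
fewest free parameters is selected (ties broken by AIC;
AIC = -2LL + 2k is reported for every fit). The phenotypic correlation
of the selected model decomposes exactly as
rPh = h1 h2 rA + c1 c2 rC + e1 e2 rE; shares are each term over rPh and
are undefined (an error) when |rPh| < 1e-6.

## Optimization and profile confidence intervals

Fits start from moment estimates (Falconer-style closed forms applied
to the empirical cross-twin blocks, PSD-projected) and are minimized
with L-BFGS-B on the unconstrained parameterization (ftol 1e-13, gtol
1e-8), followed by a Nelder-Mead polish (fatol 1e-10) because
numeric-gradient quasi-Newton steps can stall a few 1e-5 above the
optimum when a component sits on its zero boundary. Non-convergence
triggers up to four jittered restarts (seeded, jitter SD 0.1) and is
reported, never silently swallowed. Trial points whose observed
covariance sub-blocks are not positive definite receive a large finite
objective value; with moment starts the optimizer stays inside the PD
region.

All confidence intervals are profile-likelihood intervals: a bound is
the value of the target quantity at which the profiled -2LL exceeds the
minimum by the chi-square(1) quantile (3.841 at 95%). The profile is
computed by SLSQP with an equality constraint on the derived target,
warm-started from the nearest previously profiled solution; the bound
is bracketed by geometric expansion and refined by Brent root-finding
(xtol 1e-4). Profiled values are memoized so bracket endpoints are
evaluated consistently. Searches respect the target's natural range
(components in [0, 1], correlations in [-1, 1]); if the likelihood
stays under the threshold all the way to a boundary, the bound is
reported at the boundary.

## Preprocessing conventions

* Synaesthesia screen: item weights 1.0 / 0.5 / 0 for yes / to some
  extent / no; one missing or "don't know" item is tolerated and
  contributes 0; more than one excludes the respondent, and an excluded
  twin removes the whole pair.
* Symptom scales: respondents answering strictly less than 80% of a
  scale's items are missing on that scale (exactly 80% is included).
  Near-complete responses are prorated (n_items x mean of answered
  items) to avoid downward bias; this choice is recorded in the run
  provenance. Missing scores are never imputed and propagate to
  pairwise-available analyses.
* Exclusion order: screen missingness, then incomplete pair (co-twin
  absent or excluded), then undetermined zygosity; the tally plus the
  survivors partitions the participating individuals.
* Skewness uses the adjusted Fisher-Pearson G1 estimator; scores with
  skew > 1 (and non-negative support) are transformed by log(1+x). The
  decision is made once on raw scores — standardized residuals contain
  negatives, so the transform can never be re-applied downstream.
* Cronbach's alpha is computed on complete cases; its 95% CI uses
  Feldt's F interval with (n-1) and (n-1)(k-1) degrees of freedom.
* Residualization regresses each (possibly transformed) score on a
  sex indicator and birth year jointly across all included individuals
  by OLS; residuals are divided by their ddof-1 standard deviation.
* One-per-pair selection is a seeded Bernoulli(0.5) per pair;
  correlations use pairwise-complete cases with Fisher-z CIs; the
  Pearson-Filon comparison takes the smallest of the three pairwise
  ns (conservative) and the Bonferroni flag divides alpha by the
  primary-correlation family size (default 8).

## The synthetic cohort

The generator emulates an 18-year-old population twin cohort: 814 MZ,
923 same-sex DZ and 835 opposite-sex DZ pairs by default, birth years
1999-2004, a small fraction (0.008) of same-sex pairs relabelled as
undetermined zygosity, an 8-item synaesthesia screen (3 response
levels) and eight symptom scales with realistic item counts (12, 38,
11, 6, 18, 12, 23, 13) and response formats. Items are
graded-threshold discretizations of the latent trait plus independent
Gaussian item noise; the noise SD is calibrated from the target alpha
by inverting the Spearman-Brown relation with an exact correction for
ordinal attenuation at the trait's thresholds. Threshold placement for
the four skewed traits uses a geometric exceedance with per-trait
bases calibrated so the scale-score skews reproduce the graded pattern
typical of such data (about 2.4 for the screen, 2.8 for psychotic-like
experiences, 1.2-1.4 for the obsessive-compulsive and autism scales);
unskewed traits use equiprobable categories. Missing and "don't know"
codes are inserted per item slot at per-trait rates chosen to give
scale coverages between about 94% and 100% and roughly 10% screen-rule
exclusions.

Cross-trait factor correlations can be a scalar (direct for two
traits, exchangeable for more) or a vector of anchor correlations
completed to a PSD matrix by a single-factor construction — needed
because the nine-trait default grades the genetic links (strongest,
0.33, for the obsessive-compulsive analogue; weakest, 0.07, for the
eating-disorder analogue).

An important design point: published twin estimates for questionnaire
phenotypes live on the observed score scale, where E absorbs
measurement error. Using such values directly as latent truths under
an item layer would double-count measurement error and attenuate every
observed association. The default configuration therefore states its
targets on the observed scale and attenuation-corrects the latent
parameters: latent a2 = observed a2 / effective reliability, and
latent rE is inflated by the corresponding E-standardization factor
(genetic correlations are invariant to uncorrelated measurement
error). Effective reliability is the squared correlation between the
(log-transformed where skewed) scale score and the latent trait under
the fixed measurement design — close to alpha for unskewed scales,
noticeably below it (0.57-0.72) for the heavily floored ones. After
this correction, score-scale analyses of the generated cohort recover
approximately the stated observed-scale structure.

What the generator does not emulate: non-participating co-twins
(singleton rows are supported in the data layout and exercised by
tests, but not generated), dominance, sex-limitation of the genetic
architecture, assortative mating, item-level local dependence, and any
longitudinal structure. Passing tests on this cohort therefore show
that the pipeline recovers a known ACE truth under realistic
measurement conditions — not that real data satisfy the twin-design
assumptions.

## Problem sizes and tolerances used in validation

Oracle equivalences are exact-moment computations (tolerance 1e-4
against closed forms; 1e-8 against reference multivariate-normal
densities). Parameter recovery uses 20 replicate cohorts of 4000 MZ +
4000 DZ pairs; profile-CI coverage uses 500 replicates at 1000 + 1000
pairs; Pearson-Filon calibration uses 5000 null replicates at n = 1000
plus a 10^4-replicate parametric bootstrap; the structural-pattern
check uses the study-scale cohort (2572 pairs) plus 20 replicate
cohorts for the model-selection rate. These sizes keep each validation
block in the minutes range on one CPU while leaving Monte-Carlo error
well inside the asserted tolerances.

## Known limitations

* With a true shared-environment component of zero, the non-negative
  parameterization truncates C at the boundary: across replicates c2
  picks up a small positive bias (~0.01-0.02 at 4000+4000 pairs) with
  a compensating negative bias in a2, and rA (a ratio of estimated
  quantities) a similar positive bias. This is a property of
  boundary-constrained variance components, not of the optimizer.
* Central chi-square p-values for boundary tests (dropping C) are
  conservative; mixture (chi-bar-square) reference distributions are
  not implemented.
* Profile bounds that run into a parameter boundary are reported at
  the boundary rather than flagged as one-sided.
* No dominance (ADE), sex-limitation, definition variables, or >2-trait
  models; the eating-disorder analogue uses 23 items as configured in
  the default cohort.
* Cronbach's alpha on complete cases can differ from pairwise-deletion
  alpha when item missingness is informative; the generator inserts
  missingness completely at random, where the two agree.
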