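# twinlink

Classical twin-design analysis of the association between self-reported
synaesthesia and neurodevelopmental/psychiatric features — from raw
questionnaire items to the bivariate genetic/environmental decomposition
of each association — together with a synthetic twin-cohort generator
that makes every stage testable without access to registry data.

## Who this is for

Twin-study and behaviour-genetics researchers who want a reproducible,
tested pipeline for the standard bivariate ACE workflow on questionnaire
phenotypes: scale scoring with inclusion rules, descriptives
(skew, Cronbach's alpha), skew-gated transformation and residualization,
one-twin-per-pair correlation analysis with dependent-correlation
comparisons, and full-information maximum-likelihood twin modelling.

## The model

For each trait the phenotypic variance is decomposed into additive
genetic (A), shared-environment (C) and non-shared-environment (E)
components using the MZ/DZ contrast: additive-genetic factors correlate
1.0 between monozygotic co-twins and 0.5 between dizygotic co-twins,
C correlates 1.0 in both, E is uncorrelated. For a trait pair, each
component is a 2x2 covariance block parameterized through its Cholesky
factor (equivalently, the correlated-factors solution with per-trait
variances a_i^2, c_i^2, e_i^2 and factor correlations rA, rC, rE). The
expected covariance of the pair observation vector
(y11, y21, y12, y22) is

    within-twin block:   A + C + E
    cross-twin block:    A + C   (MZ)      0.5 A + C   (DZ)

and parameters are estimated by casewise full-information maximum
likelihood (FIML), so missing entries need no imputation. The
model-implied phenotypic correlation decomposes as

    rPh = h1 h2 rA + c1 c2 rC + e1 e2 rE ,    h_i = sqrt(a_i^2), ...

and each term divided by rPh is that component's share of the
association. Nested AE/CE/E models are compared to ACE by likelihood-
ratio tests (parsimony rule), assumptions are checked with step-wise
constrained saturated models, twin and cross-twin cross-trait (CTCT)
correlations are extracted from the constrained saturated fit, and all
confidence intervals are profile-likelihood intervals.

The correlation stage uses one randomly selected twin per pair (twin
observations are not independent), Fisher-z confidence intervals, and
the Pearson–Filon (1898) z test for comparing two dependent overlapping
correlations.

## Worked example

```python
from twinlink.syntwin import default_config, generate_twin_dataset
from twinlink.scales import (pairs_to_individuals, score_dataset,
                             apply_inclusion_filters, prepare_phenotype)
from twinlink.assoc import select_one_per_pair, pearson_with_ci
from twinlink.twinmodel import (PairData, fit_bivariate_ace,
                                lrt_compare, decompose_rph)

cfg = default_config(seed=1)        # 814 MZ + 923 same-sex DZ + 835 opposite-sex DZ pairs
pairs = generate_twin_dataset(cfg)
individuals = pairs_to_individuals(pairs, cfg.traits)
included, tally = apply_inclusion_filters(score_dataset(individuals, cfg.traits))
print("exclusion tally:", tally)

phen = included[["pair_id", "twin", "zygosity", "sex", "birth_year"]].copy()
for spec in cfg.traits:
    prep = prepare_phenotype(included[f"{spec.name}_score"],
                             included["sex"].to_numpy(),
                             included["birth_year"].to_numpy())
    phen[spec.name] = prep.values.to_numpy()

one = select_one_per_pair(phen, seed=2)
r = pearson_with_ci(one["synaesthesia"], one["oc"])
print(f"synaesthesia x OC: r = {r.r:.3f} (95% CI {r.ci_low:.3f}-{r.ci_high:.3f}), n = {r.n}")

data = PairData.from_scores(phen, "synaesthesia", "oc")
ace = fit_bivariate_ace(data, "ACE")
ae  = fit_bivariate_ace(data, "AE")
print("AE vs ACE:", lrt_compare(ace, ae))
dec = decompose_rph(ae)
print(f"rPh = {dec.rph_model:.3f}, A share = {dec.share_A:.2f}, E share = {dec.share_E:.2f}")
```

Output:

```
exclusion tally: {'screen_missingness': 542, 'incomplete_pair': 492, 'undetermined_zygosity': 20, 'included': 4090}
synaesthesia x OC: r = 0.264 (95% CI 0.223-0.304), n = 2031
AE vs ACE: LRTResult(delta_neg2ll=0.005746706545323832, delta_df=3, p_value=0.9998843358603904, preferred='AE')
rPh = 0.259, A share = 0.76, E share = 0.24
```

Reading the numbers: 542 individuals are dropped by the synaesthesia-
screen missingness rule, 492 because their co-twin is missing or
excluded, and 20 for undetermined zygosity, leaving 2045 complete pairs.
On one randomly chosen twin per pair, the synaesthesia screen correlates
r = 0.26 with the obsessive-compulsive analogue scale. Dropping the
shared-environment component costs essentially no model fit (p ≈ 1.0),
so the parsimonious AE model is selected; it attributes 76% of the
phenotypic correlation to additive-genetic factors and 24% to the
non-shared environment.

The same analysis runs end to end from the command line:

```bash
twinlink simulate --out cohort.csv --seed 1
twinlink run --outdir results_run            # full pipeline on the default cohort
twinlink report --in results_run             # text summary of the fitted models
```

`twinlink run` writes `table2.csv` (descriptives), `fig1.csv`
(forest-plot-ready correlations), `comparisons.csv` (dependent-
correlation tests), `table3.csv` (rPh/rA/rE and CTCT correlations with
CIs), `table4.csv` (A/E shares of each association), `exclusions.csv`,
`model_fits.json` and `run.json` (provenance).

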