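# Methods

## The penetrance model

Families are ascertained through a single carrier proband; traits are
normed clinical scores (standard scores, mean 100/SD 15; scaled scores,
10/3; T-scores, 50/10). For one trait, each family contributes the proband
value P and the family score F, the unweighted arithmetic mean over all
available non-proband relatives (mother, father, siblings) with a
non-missing value. Relatives are weighted equally regardless of degree of
relatedness — the simplest defensible aggregation when availability varies
across families. Missingness is handled per trait: a family enters a
trait's analysis iff both P and F exist for that trait.

The centred regression

    P − mean(F) = offset + β₁ (F − mean(F)) + e

is ordinary least squares. Centring the predictor at its own mean makes
the fitted intercept identically `mean(P) − mean(F)` (the OLS line passes
through the mean point), so the intercept *is* the average carrier shift —
the penetrance estimate — and is unbiased for the generative offset even
when the slope is attenuated (see below). Inference:

* all tests two-sided on n−2 degrees of freedom with the classical OLS
  standard errors;
* slope vs 0 is algebraically identical to the Pearson correlation test
  (`t = r√(n−2)/√(1−r²)`); the package computes both routes independently
  and the test suite checks they agree to 1e-9;
* slope vs 1 uses `t = (β₁ − 1)/SE(β₁)`; rejection means the carrier
  shift varies across the family-score range;
* Cohen's d = offset / **normative** SD of the instrument (15/3/10), not
  a pooled sample SD — the definition consistent with every published
  per-trait row, and the one that keeps d comparable across score scales;
* adjusted R² uses the one-predictor formula `1 − (1−R²)(n−1)/(n−2)` and
  is reported as-is when negative;
* Bonferroni correction is applied per test family (offset, slope-vs-0,
  slope-vs-1, and the Model-1 family-FSIQ term), each across the m=12
  traits, flagging `p·m < 0.05`.

Degenerate inputs raise `DegenerateDataError` rather than returning
NaNs: fewer than 4 pairs, zero family-score or proband variance. A
perfect fit (zero residual variance) yields p=1 for a slope test whose
null value equals the estimate and p=0 otherwise, keeping the identity
configuration (P ≡ F) well-defined.

## Multivariate extensions

Model 1 adds the family FSIQ score to the trait's own family score; Model
2 further adds family SES, MacArthur ladder rung, proband birth weight,
gestation length and maternal age. Fits are complete-case OLS
(statsmodels). The two are compared by the nested partial-F

    F = ((SS₁ − SS₂)/Δdf) / (SS₂/df₂)

which is only valid on an identical row set, so `anova_gate` always
refits Model 1 on exactly Model 2's complete cases before comparing.
Individual Model 2 coefficients are serialized with a `gated` flag and
should only be interpreted when the ANOVA gate passes. Designs with
condition number above 1e8 (or rank-deficient, e.g. a constant covariate,
or family FSIQ requested for the FSIQ outcome itself) are flagged
`collinear` and warned about, but the pinv-based fit is still returned.
Complete-case univariate refits (`complete_case_univariate`) restrict the
centred regression to Model 2's rows so explained variance can be
compared like for like. Predictors are not standardized: coefficients are
reported in measurement units.

## Trait-by-relative clustering

Per family and trait, three columns are formed: proband value, sibling
value (within-family mean if several siblings), and the parent score
(mother/father mean, or the single participating parent). Each of the 36
columns is z-scored with the sample mean/SD over non-missing values
*within that column* — scaling within role, so level differences between
roles (the offsets themselves) cannot dominate the correlations — and
cognitive columns are negated so higher always indexes impairment.
Correlations are pairwise-complete Pearson (sibling columns exist for only
a subset of families); entries with fewer than `min_overlap=3` overlapping
families are recorded and set to 0, and zero-variance columns are dropped
with a warning, shrinking the matrix.

Rows of the correlation matrix are treated as 36-dimensional feature
vectors and clustered agglomeratively (Euclidean distance, Ward linkage —
the combination whose objective is the within-cluster sum of squares that
the elbow criterion inspects; `1−r` distance and other linkages are
available through the estimator's parameters). The number of clusters is
the k in 2…k_max (default k_max=10) maximizing the second difference of
the WSS curve, ties broken toward smaller k. When the strongest curvature
explains less than 10% of the total WSS drop (or the curve is flat), the
selection is flagged low-confidence and defaults to k=2 — a deliberate
operationalisation of what is usually a visual judgement, chosen so the
rule is deterministic and testable. The role-pair quadrant summary reports
the mean off-diagonal correlation within each of the 3×3 role blocks,
turning "parent traits track sibling traits more closely than proband
traits" into a number.

## The synthetic generator

`generate_cohort` draws, per family f and trait t,

    L_ft ~ N(family_mean_t, between_family_sd_t²)
    relative value = L_ft + N(0, within_family_sd_t²)
    proband value  = family_mean_t + offset_t + slope_t(L_ft − family_mean_t)
                     + Σ_p β[p→t](L_fp − family_mean_p) + Σ_c γ[c,t] z_fc
                     + N(0, proband_noise_sd_t²)

with mother/father/sibling rows present independently with probabilities
57/58, 34/58 and 24/58 by default, covariates drawn from configurable
means/SDs (effects γ default to zero), and at most one sibling per family
(the design recruited single male siblings). All draws come from one
`numpy` generator stream in a fixed order, so a seed pins the cohort
bit-for-bit.

Two deliberate properties:

* **Attenuation is real and quantified.** The pipeline sees the noisy
  relative average, not L. The estimable slope is the generative slope
  times the reliability of the family score,
  `between² / (between² + within²/m)`, and the proband–family correlation
  has the closed form `slope·between² / √((between²+within²/m)(slope²·between²+noise²))`
  (m = number of relatives). Recovery tests compare against these
  oracles, not the latent parameters. The penetrance *offset*, by
  contrast, is unbiased regardless of attenuation.
* **The XYY-like preset is derived, not hand-tuned.** At call time it
  centres each trait's latent family mean on the mean of the three
  published relative-role means, splits the mean per-role variance into
  between/within components by an intraclass correlation of 0.5
  (cognitive) or 0.3 (behavioural) — placeholder values, as the study
  reports no such split — takes the published offsets and slopes, sets
  the proband noise SD to match the published proband marginal SD (floored
  at a quarter of the normative SD), and adds three modest negative
  family-FSIQ → proband-SRS couplings (−0.25 score/score) mirroring the
  reported protective cross-trait effect.

What the generator does **not** emulate: age structure and age-varying
coupling, rater effects, per-trait missingness beyond role availability
(e.g. probands untested on one instrument), role-specific trait means
(mothers and fathers share one latent family mean), assortative mating and
any explicit genetic transmission model. Passing tests therefore show the
*estimators* behave correctly under the assumed structure, not that real
family data satisfy that structure.

## Problem sizes and numerical choices

Test and acceptance runs use sizes chosen to make Monte-Carlo error small
relative to the asserted tolerances while keeping the suite quick:
10,000 replicates at n=58 for the slope-vs-1 type-I rate (binomial SE
≈ 0.002 against a ±0.01 band), 1,000 generator replicates for offset
unbiasedness (3-SE band), 400 replicates for the nested-F null rejection
rate, 6,000 families for the closed-form correlation check, and 4,000–8,000
families for slope-attenuation recovery. Exact identities (centring,
test equivalence, partial-F vs independent residual-sum and statsmodels
oracles) are asserted at 1e-9–1e-12. CSV outputs of the CLI are written
with 6 significant digits so reruns are diffable; cohort files round-trip
at full precision.

## Known limitations

* Nuclear families only, one proband per family; no kinship weighting or
  mixed-effects modeling of the varying relative composition across
  families.
* Classical OLS standard errors throughout; no robust or
  heteroskedasticity-consistent alternatives.
* No imputation: all multivariate analyses are complete-case.
* The elbow rule and the Ward/Euclidean choice are sensible defaults, not
  claims about how any particular published dendrogram was produced;
  cluster stability (bootstrapping) is out of scope.
* Confidence intervals for Cohen's d are not provided.
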