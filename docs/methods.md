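# Methods

`eelvkit` implements the statistical machinery for validating a bedside
end-expiratory lung volume (EELV) technique — nitrogen washin-washout
(WI-WO), read off an ICU ventilator — against quantitative CT as the
reference, across a grid of ventilator settings (PEEP, tidal volume) in a
lavage-ARDS animal model. This note documents the models, the numerical
choices, and what the synthetic cohort generator does and does not
emulate.

## Data model

One *measurement record* is an animal x condition row: PEEP (cm H2O),
tidal volume V_T (mL), respiratory rate, and EELV by both methods (mL).
Either EELV value may be missing (technical WI-WO failures, pneumothorax
at high V_T); a record enters the paired analyses only when both are
present. Each animal's timeline is ARDS onset (PEEP 0) -> decremental
PEEP trial (20 -> 2 cm H2O, 2 cm H2O steps) -> an 8-level V_T ladder
(4-20 mL/kg) at a per-animal "optimal" PEEP. The per-animal baseline
covariate `EELV_Base` is the CT volume at ARDS onset; validation rejects
animals without exactly one onset record. Units are fixed: mL, cm H2O,
kg.

Per paired row the Bland-Altman coordinates are the mean
`m = (CT + WIWO)/2` and the bias `d = WIWO - CT` (both mL).

## Agreement

**Calibration regression.** OLS of WI-WO on CT with two-sided Wald
p-values. Its inverse (`convert_wiwo_to_ct`) maps a bedside reading to a
CT-equivalent volume; the propagated SE uses the calibration residual SD
divided by |slope| (first-order).

**Non-constant bias with repeated measures.** The bias depends on the
measured volume and each animal contributes ~16 linked pairs, so
classical Bland-Altman limits are wrong on two counts. The model is

    d_ij = b0 + b1 * m_ij + u_i + e_ij,
    u_i ~ N(0, tau^2) per animal,  e_ij ~ N(0, sigma^2),

estimated by *alternating regression*: (i) GLS for (b0, b1) under the
block compound-symmetric covariance (each animal block solved by the
Sherman-Morrison identity), alternating with (ii) an exact ML update of
the variance components — sigma^2 is profiled out in closed form and the
remaining 1-D negative profile log-likelihood in the variance ratio
lambda = tau^2/sigma^2 is minimized by bounded Brent search (lambda = 0,
no clustering, is an admissible boundary solution). A single EM step per
pass was tried first and abandoned: EM approaches the tau^2 = 0 boundary
only geometrically and stalls the outer loop. Iteration stops when
(b0, b1) move < 1e-6 mL and the variance SDs move < 1e-3 mL (the second
guard prevents false convergence on the cold start, where tau^2 = 0 makes
the first GLS pass a no-op); the default cap is 500 passes, and
exceeding it raises an error carrying the full iteration trace.

Limits of agreement are `b0 + b1*m +/- 1.96 * sqrt(sigma^2 + tau^2)` —
the marginal 95% band for a new pair from a new animal. The classical
mean bias and `+/-1.96 SD(d)` are reported alongside, since published
analyses do not always say which of the two conventions produced their
interval. With one animal and the slope constrained to zero, the
estimator degrades exactly to classical Bland-Altman.

**Percentage error** is `100 * 1.96 * SD(d) / mean(m)`; the 1.96
multiplier is a parameter because the convention's constant is sometimes
printed ambiguously.

## Bias model

The bias is regressed on PEEP, V_T and EELV_Base with a per-animal random
intercept (`statsmodels` MixedLM), fitted by **maximum likelihood** so
that AIC is comparable across fixed-effect structures; a REML refit of
the final model is available. Two numerical points matter:

* covariates are standardized inside the fit — the raw three-way product
  (PEEP ~10 x V_T ~10^2 x EELV_Base ~10^2) reaches ~10^6 and makes the
  Hessian numerically singular; likelihood, AIC and Wald p-values are
  invariant to this reparametrization;
* the optimizer order is Powell -> BFGS -> Nelder-Mead with a
  finite-log-likelihood check: gradient-based L-BFGS can park the
  random-effect variance on the zero boundary (reported log-likelihood
  +inf) or stop ~2 log-units short of the optimum, which silently
  corrupts AIC comparisons. The profiled objective has one free
  parameter, so derivative-free Powell is both reliable and fast here.

**Backward stepwise AIC** respects marginality (a main effect is never
dropped while one of its interactions remains) and records the full
selection path; accepted-path AICs are non-increasing by construction.
Two calibration facts worth knowing when interpreting selections:

* under a pure-noise response, each term survives AIC deletion with
  probability P(chi2_1 > 2) ~ 0.157, so full collapse to the
  intercept-only model happens with probability ~0.843^k for k candidate
  terms — ~60% from a 3-term main-effects model but only ~30% from the
  full 7-term factorial. AIC-based selection *keeps* pure-noise terms at
  a calibrated ~16% rate; that is a property of AIC, not a defect;
* cluster-level covariates (EELV_Base is constant within animal) have
  anti-conservative likelihood-ratio behavior when the number of animals
  is small; with 14 animals their spurious-retention rate is visibly
  above the nominal rate.

**Dunnett many-to-one contrasts** of mean bias at each PEEP level versus
PEEP 0 use `scipy.stats.dunnett` (multivariate-t with equicorrelation);
measurements within a PEEP level are pooled across animals, so the
contrasts treat them as exchangeable — an approximation consistent with
the equicorrelation framework. The QMC evaluation of the null
distribution is given a fixed internal generator so repeated analyses
are byte-identical; the simultaneous-CI root finding can be skipped
(`with_ci=False`) in simulation loops that only need adjusted p-values.

**Zero-bias test**: Wilcoxon signed-rank (exact for n <= 25 without
zeros/ties), two-sided. A compatibility mode runs Mann-Whitney of the
sample against a zero vector, matching the letter of some published
method sections; the signed-rank form is the coherent one-sample
analogue and is the default. An all-zero sample returns p = 1 by
convention.

**Median-split summary**: each of V_T, PEEP, EELV_Base is classified
high (> cutoff) / low; cutoffs default to cohort medians, with fixed
overrides available (e.g. the published 170 mL / 10 cm H2O / 157 mL).

## Trending

Consecutive-change pairs (Delta CT, Delta WI-WO) are formed within each
animal along its single experimental timeline; deltas never span
animals. The four-quadrant **concordance rate** is the percentage of
retained pairs with same-sign changes; a pair with a zero component has
no defined direction and counts as discordant (conservative). The
**exclusion zone** removes pairs with |mean change| below a threshold
(an alternative max(|dCT|, |dWIWO|) rule is available): small changes
reflect measurement noise, not trending.

The **polar transform** rotates the four-quadrant plane 45 degrees
clockwise so the identity line is horizontal: theta = atan2(dWIWO, dCT)
- 45, wrapped to (-180, 180]; the radius is the mean change, and pairs
in which both methods decrease sit on the left half, measured from the
180-degree axis. **Angular bias** is the arithmetic mean (with sample
SD, ddof = 1) of signed deviations from the agreement axis — deviations
live well inside +/-90 degrees, so circular corrections are unnecessary.
**Radial limits of agreement** are the 95th percentile (linear
interpolation) of absolute deviations — the symmetric sector holding 95%
of pairs; the parametric 1.96 x SD variant is reported alongside because
published tables rarely disclose which estimator they used.

## Change detection

For each true-change threshold t, labels are |Delta CT| > t (strict) and
scores are |Delta WI-WO|. The ROC is empirical (midrank tie handling);
AUC equals the Mann-Whitney concordant-pair probability and its 95% CI
uses the DeLong structural-component variance estimator (implemented
here; checked in tests against brute-force pair counting). The
Youden-optimal cutoff maximizes Se + Sp - 1 over observed scores, ties
broken toward the larger cutoff (higher specificity); all
confusion-table metrics are reported, with zero-denominator ratios as
missing rather than infinite. A signed-direction variant (sign
disagreement zeroes the score) is available since published tables do
not state how sign-discordant changes were scored.

## CT gas volume

Gas fraction per voxel is -HU/1000 clamped to [0, 1] (air -1000, water
0); EELV_CT is gas fraction x voxel volume summed over the lung mask, in
mL. Voxels below -1000 HU clamp to 1 rather than being excluded (the
alternative is not documented in the source analyses). Arrays are
(z, y, x); masks are voxel-aligned with no partial-volume weighting.
Segmentation is an input, not computed. A deterministic block phantom
with an analytic gas volume supports exact testing.

## Synthetic cohort generator

The generator reproduces the *statistical structure* the analysis
assumes, not the physiology:

* **Recruitment**: per-animal logistic curve in PEEP, renormalized to
  pass exactly through a baseline draw at PEEP 0 (Gamma with mean 236,
  SD 143 mL — strictly positive, mean preserved exactly) and a recruited
  volume at PEEP 20 (Normal 1206 +/- 185 mL, floored 50 mL above
  baseline); midpoint 10 +/- 2 cm H2O, scale 3 +/- 0.5. A small tidal
  recruitment term (4 mL per mL/kg of V_T above 6) applies within the
  ladder stage only, so the two PEEP anchors stay exactly on target.
* **Bias**: expected bias b0 + b1*m + gain * max(0, PEEP - 10) * amp,
  with amp = (1 + 0.5*[V_T < 170 mL]) * (1 + 0.5*[EELV_Base < 157 mL])
  — a median-split indicator interaction rather than a smooth surface,
  mirroring how such interactions are typically reported. The bias is
  defined on the pairwise mean m, which depends on the result; the
  noise-free fixed point is solved in closed form before noise. Defaults
  (b0 = 85.8 mL, b1 = -0.4503, gain = -6 mL/cm H2O) were calibrated once
  so that a large simulated cohort reproduces the published calibration
  regression (slope 0.58, intercept 96 mL) and total bias SD ~203 mL
  (limits of agreement ~+/-398 mL).
* **Noise**: CT 30 mL, WI-WO 130 mL (white, additive, floor at 0 mL),
  plus a 25 mL per-animal bias offset. The published record does not
  identify the split between proportional and random error; this split
  is a tunable, not a fact.
* **Missingness**: each non-baseline row loses one method (WI-WO with
  probability 0.75 — technical failures dominate) with probability
  48/252, leaving 218 fully paired rows in expectation out of 266;
  baseline rows are exempt so EELV_Base always exists.
* **Optimal PEEP**: a per-animal draw from {8,...,16} cm H2O by default;
  rule-based proxies (best-volume retention, compliance-peak proxy,
  fixed table value) are available but only proxy the physiology.

What the generator does *not* emulate: gas-exchange dynamics, time
trends within a condition, autocorrelated measurement drift,
heteroscedastic noise, or the WI-WO breath-by-breath computation. Tests
that pass on this generator therefore demonstrate correctness of the
*statistics* under the assumed error structure, not validity of the
bedside technique on real animals. One deliberate consequence of the
white-noise model: consecutive-change noise is ~sqrt(2) larger than
per-measurement noise, so the default cohort's concordance rate (~65%)
sits below the published ~79%, while the agreement-level quantities
match closely.

Determinism: all draws flow from one root generator seeded by
`config.seed`; the same seed yields byte-identical CSV output.

## Problem sizes in the test and acceptance runs

Chosen to keep the default suite inside a few minutes on one CPU:
bias-line CI coverage uses 500 default cohorts against a 400-animal
Monte-Carlo estimate of the population bias line (the estimand of a
d-on-m regression under measurement error, including attenuation and
noise-correlation effects); three-way retention 60 replicates of
28-animal complete cohorts with an injected continuous three-way signal
(40 mL per unit triple z-score over 160 mL noise); pure-noise collapse
120 replicates; mixed-model type-I error 400 and Dunnett family-wise
error 300 null-generator replicates, asserted within three binomial
standard errors of the nominal 5% (plus small-sample Wald slack). The
null generators raise baseline volumes to 800 +/- 150 mL and reduce
WI-WO noise to 80 mL: at the default low volumes the 0-mL floor clips a
few percent of readings and induces genuine (if small) covariate
structure, which is a property of the generator, not of the estimators
under test.

## Known limitations

* The alternating regression fits a random intercept only (no random
  slope in m), matching the repeated-measures structure the analysis
  assumes; strongly animal-specific proportional bias would be absorbed
  into sigma^2 and widen the limits.
* Dunnett contrasts ignore within-animal correlation across PEEP levels;
  with 10 levels x 14 animals the approximation is anti-conservative in
  principle, though the measured family-wise error under the null
  generator stays at ~5%.
* Wald p-values from the mixed model use the normal reference; with 14
  animals, tests of between-animal covariates are slightly liberal.
* DeLong intervals are asymptotic; with < ~10 cases per class they
  should not be trusted.
* The 0 mL floor makes the generator's noise slightly non-Gaussian at
  very low volumes (onset conditions).
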