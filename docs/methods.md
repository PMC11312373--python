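# Methods

## The estimand and the analysis chain

`inflascore` implements a cohort analysis of chronic low-grade systemic
inflammation and ageing outcomes. The exposure is the **INFLA-Score**, an
equally weighted composite of four blood markers — C-reactive protein
(CRP, mg/L), white blood cell count (WBC), platelet count (Plt) and the
neutrophil-to-lymphocyte ratio (NLR = neutrophil / lymphocyte count).
Each marker is ranked into empirical population deciles; deciles 1–5
contribute −4, −3, −2, −1, 0 points and deciles 6–10 contribute
0, +1, +2, +3, +4, so the total lies in [−16, +16], higher = more
pro-inflammatory. Two decile→points conventions circulate in the
literature (1–5 / 6–10 split versus 1–4 / 5–6 / 7–10); written out both
are the vector `[-4, -3, -2, -1, 0, 0, +1, +2, +3, +4]`, so the package
implements one mapping and accepts either variant name.

Outcomes are (i) **premature death**, death before age 75, with deaths at
75+ treated as censoring (at the death date by default, optionally at the
75th birthday), and (ii) **age-related hospitalization**, the first
admission whose ICD-10 code falls in a user-supplied list of age-related
diseases. Follow-up runs from the baseline visit to the earliest of
death, loss to follow-up and a fixed administrative date (2022-02-01).

Associations are estimated with Cox proportional-hazards models for
exposure quartiles (Q1 reference; Wald 95% CIs `exp(β ± 1.96·SE)`), an
ordinal 1..k Wald trend test, restricted-cubic-spline dose-response
curves, subgroup refits, three sensitivity re-analyses, a 12-cell
diet × inflammation joint model and diet-tertile-stratified modification
fits. Life expectancy lost per quartile is obtained by life-table
attribution (below).

## Cox models

Partial-likelihood maximisation is delegated to `statsmodels` `PHReg`.
Ties are handled with the **Efron** correction by default — follow-up
measured in days produces heavy ties — with Breslow available via
`ModelSpec(ties="breslow")`. Trend is coded 1..k on the quartile index, a
common convention. CIs are Wald on the log scale throughout.

High-level fitters (`quartile_fit`, `rcs_curve`, `joint_fit`,
`modification_fit`) first drop adjustment covariates the data cannot
identify: binary flags that are constant or have zero events on one
level. Such covariates put the partial-likelihood maximum at infinity
(quasi-separation) — routine in small strata, e.g. zero premature deaths
among participants with prevalent cancer in a few-thousand-person
subgroup. `cox_fit` itself never prunes and raises `FitError` instead, so
the behaviour is explicit at the low level and forgiving at the pipeline
level.

## Restricted cubic splines

The spline basis is the natural-cubic parameterisation that is linear
beyond the boundary knots, with k−1 free coefficients for k knots;
default 4 knots at the 5th/35th/65th/95th exposure percentiles (standard
practice; knot placement is configurable). Nonlinearity is tested by a
likelihood-ratio test of the k−2 nonlinear terms against the linear-only
model (χ², k−2 df). The curve is anchored at the exposure median
(HR = 1); pointwise CIs come from the delta method on the basis-row
contrast. Tie method, trend coding and knot scheme are stated here
because they are analysis choices the results depend on; all three are
surfaced in `ModelSpec` rather than hidden.

## Life-table attribution

Given a sex-specific reference schedule of central death rates m(a) for
single ages 40–100, exposure-group prevalences p_g (default 0.25 per
quartile, by construction of quartiles; overridable with empirical
sex-specific values) and premature-death hazard ratios h_g versus Q1,
group rates are calibrated so the population mixture reproduces the
reference exactly:

    m_Q1(a) = m_ref(a) / Σ_g p_g h_g ,    m_g(a) = h_g · m_Q1(a)

(the mixture identity Σ p_g m_g = m_ref holds to 1e−12 by construction).
HRs are treated as age-constant over 40–100. Life tables use 1-year
intervals with mid-interval deaths, q = m/(1 + m/2), l(40) = 1,
L = l − d/2, terminal closure L(100) = l(100)/m(100), e = T/l. The gap
Δe_g(a) = e_Q1(a) − e_g(a) is the average survival time lost by group g.
CI bounds substitute the group's HR CI limits one group at a time (other
groups at point estimates); a log-normal parametric bootstrap
(`expectancy_gap_bootstrap`) is provided as an alternative since the
published CI method for such gaps is rarely stated.

`synthetic_uk_reference(sex)` supplies a stand-in reference schedule: a
Gompertz law m(x) = a·e^{b(x−40)} with (a, b) solved so that remaining
life expectancy at ages 40 and 60 matches published ONS 2018–2020
national values (men 40.2/22.3 y, women 43.4/25.0 y). It is a smooth
synthetic approximation, not the ONS table; users reproducing published
attributions exactly should load the real table via `read_life_table`.

## Diet scores

The 0–6 **healthy-diet covariate** awards one point each for red meat
≤ 3 times/week, vegetables ≥ 4 tbsp/day, fruit ≥ 3 servings/day, fish
≥ 4 times/week, grains ≥ 5 servings/week and urinary sodium
≤ 70.6 mmol/L; ≥ 3 points flags a healthy diet. **HEI-2020** (0–100) sums
13 components linearly interpolated between the published USDA min/max
standards (densities per 1,000 kcal, % energy, or the
(MUFA+PUFA)/SFA ratio); standards ship as an editable CSV
(`inflascore/data/hei2020_standards.csv`) so alternative cut-offs can be
swapped in. **MED** (0–9) is the Trichopoulou-style count against
sex-specific cohort medians, with the moderate-alcohol window
(10–50 g/day men, 5–25 women) rather than a median cut, as in the
original index. **DASH** (8–40) is the Fung-style sum of cohort quintile
ranks over 8 components, reversed for sodium, red/processed meat and
sweets. MED and DASH are therefore *relative* scores, defined with
respect to the analysis population passed in. Repeated 24-h recalls are
averaged before scoring (`average_recalls`). Missing components yield
NaN — the signal that drops a participant from diet analyses while
keeping them in the main analyses.

## Quantile binning and tie handling

All quantile binning (deciles, quartiles, quintiles, tertiles, DASH
ranks) uses empirical quantiles with linear interpolation; a value
exactly at a cut-point goes to the **lower** bin. Integer scores produce
tie blocks that never straddle a bin boundary; duplicate cut-points are
collapsed (as `pandas.qcut(duplicates="drop")` would). Constant input is
a `BinningError`; decile maps fitted on a constant marker are flagged
degenerate rather than rejected, since the score is still well defined
(all zeros). The decile map is fitted on the full analysis population,
not sex-stratified.

## The synthetic cohort

The generator produces the statistical structure the analysis assumes —
it is the package's test bed, standing in for application-gated cohort
data, and is itself first-class, tested code.

* **Margins.** Ages are integer years ~ N(57, 8²) truncated to 40–70;
  54% men; CRP is log-normal with mean 2.59 and SD 4.34 mg/L (the SD
  exceeding the mean implies right skew, hence log-normal); cell counts
  are gamma with the cohort means/SDs (WBC 6.88 ± 2.03, Plt 253 ± 60,
  neutrophils 4.22 ± 1.41, lymphocytes 1.96 ± 1.13), truncated at
  clinically plausible caps. Covariate prevalences follow the baseline
  table (10% current smokers, 27% hypertension, ...).
* **Dependence.** A Gaussian factor copula: each marker's normal
  coordinate loads on a shared factor λ·L + γ·F (L = latent unhealthy
  lifestyle, shared with diet intakes; F = common marker factor;
  defaults λ = 0.25, γ = 0.40). Lymphocytes load negatively so latent
  inflammation raises NLR. Diet intakes are log-normal with signed
  loadings on L, which induces the diet–inflammation correlation the
  joint analysis needs. WBC is *not* constrained to equal the sum of its
  differential counts.
* **Events.** Death and hospitalization times are Weibull increments
  from baseline, `t = scale·(E/e^lp)^{1/shape}` (default shape 1 =
  exponential, giving closed-form rate ratios for validation), with lp
  the participant's eventual INFLA-quartile log-HR (defaults: death
  ln 1.12/ln 1.25/ln 1.58 for Q2–Q4; hospitalization
  ln 1.04/ln 1.09/ln 1.19) plus optional covariate effects (age, sex by
  default). Scoring happens *inside* the generator so the hazard can
  depend on the realised quartile. Deaths receive an ICD-10 cause from a
  configurable categorical; age at death is baseline age plus the
  increment, so premature death (< 75) is well defined.
* **Censoring.** Loss to follow-up is exponential and independent
  (0.004/year); administrative censoring at 2022-02-01; recruitment
  uniform over 2007-09-01..2010-10-01. Together these put the median
  follow-up at ≈ 12.7 years and premature-death prevalence at ≈ 5.6%.
  Event times are capped at 200 years before calendar conversion; capped
  times are always censored.

What the generator does **not** emulate: item-level food questionnaires
(food groups are simulated directly), measurement error and within-person
biomarker drift, competing-risk structure between hospitalization and
death (the two processes are conditionally independent given the
quartile), non-proportional hazards, and cohort-entry health-volunteer
bias. Passing tests therefore demonstrate that the *estimators* recover
known generating values under the model's assumptions — not that those
assumptions hold in any real cohort.

## Numerical and degenerate-input choices

* Follow-up in years = days/365.25; baseline age in whole years, so age
  at death carries < 1 y discretisation from the integer baseline age.
* ICD-10 matching at the 3-character category (sub-codes ignored);
  ranges must stay within one letter block; "I69" is enumerated with
  stroke explicitly.
* Cox convergence is `PHReg`'s default Newton criterion; fits with
  non-finite or absurd (> 50) standard errors are reported as
  non-converged/separated rather than returned.
* Cohort CSVs are written with `%.17g` floats and read with the
  round-trip parser, so re-running a stage from cached files reproduces
  downstream tables exactly.
* `GroupSpec` requires Σp_g = 1 (1e−9), h_ref = 1 exactly, h_g > 0;
  `build_life_table` guards m ≥ 0 and closes the terminal interval with
  max(m(100), 1e−12).

## Problem sizes used in validation

The test-suite and acceptance-script simulations use: parameter recovery
at n = 50,000 (5 seeds); null CI coverage over 200 cohorts of n = 2,500;
spline calibration over 100 linear-truth replicates (n = 1,500) and 50
J-shaped replicates (n = 8,000); modification detection over 40
replicates (n = 12,000); life-table oracle simulation with 4–6 × 10⁵
lives. These sizes give Monte-Carlo error comfortably inside each check's
tolerance while keeping a full run on one CPU in a few minutes.

## Known limitations

* Premature-death HRs are applied to all-age mortality 40–100 in the
  life-table attribution, as the source analyses describe; output tables
  carry that assumption rather than hiding it.
* The modification analysis is stratified refitting; the product-term
  Wald test (`interaction_wald`) is an extension, and no additive
  interaction (RERI) measure is provided.
* No competing-risks (Fine–Gray) modelling; cause-specific Cox only.
* No imputation of missing biomarkers — participants without complete
  inflammation panels are excluded, mirroring the source design.
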