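# Methods

This note documents the models, the synthetic data process, the
numerical choices, and the limits of what the test suite demonstrates.

## The estimands

The package targets within-hospital disparities in skilled nursing
facility (SNF) placement by opioid use disorder (OUD) status, via two
complementary model families.

**Fixed-effects linear probability models.** For binary placement
outcomes (entered a preferred SNF; entered a 4–5-star SNF; entered a
4–5-star SNF among preferred-SNF discharges), OLS with hospital
intercepts absorbed estimates the within-hospital OUD gap in
percentage points, adjusted for age, sex, race/ethnicity, dual
eligibility, Medicare Advantage, ESRD entitlement, urbanicity (RUCA),
and a comorbidity index. The within transformation (group demeaning)
is numerically identical to hospital dummies; hospitals contributing a
single row are dropped and counted, degrees of freedom subtract the
absorbed effects, and standard errors are HC1 — a linear probability
model's residuals are heteroskedastic by construction, so
homoskedastic errors would be indefensible.

**Conditional logit.** Placement is modelled as a McFadden choice over
the discharge's choice set with utility
`v_ij = x_ij'β + d_i·(x_ij'δ)`, `d_i` the OUD flag. Because the
exposure is constant within a choice set, it is identified only
through the interactions δ; the model therefore conditions out all
patient-level main effects, and patient-level confounding is handled
by design instead: 1:k matching on hospital and date (±2 days), then
inverse-probability weighting and quintile subclassification on a
logistic propensity score. Interactions with preferred status and
star rating are the coefficients of interest.

**Margins.** Conditional-logit marginal effects are alternative- and
set-specific, so effects are anchored at the SNF closest to each
patient's home: its preferred flag is counterfactually switched off/on
(or its rating raised one star) with everything else fixed, the
softmax is re-evaluated, and the probability change is averaged by
exposure group in percentage points. The computation is deterministic
given the fit (no Monte Carlo) and equals the one-line closed form
`p' = p·e^Δv / (1 − p + p·e^Δv)` exactly; the test suite asserts that
identity to 1e−12. Group differences are tested through δ (Wald,
cluster-robust), never through the margins themselves.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| choice-set radius | 22 | km | documented catchment radius for hospital-SNF transfers |
| nearest-facility rule | 15 | SNFs | keeps rural choice sets non-degenerate |
| preferred threshold | 0.50 | cumulative volume share | standard definition; sensitivity grid 0.10–0.80 |
| match ratio / window | 1 / ±2 | controls / days | primary matched design; ratios 2–3 supported |
| age-spline knot | 65 | years | Medicare eligibility boundary |
| propensity trimming | [0.01, 0.99] | score | removes boundary scores before weighting |
| high quality | {4, 5} | stars | the conventional dichotomy of the 5-star overall rating |
| convergence | 1e−8 | max-norm of gradient | reproducibility of reported optima |

Threshold crossing for preferred status is **inclusive**: facilities
are accumulated in descending volume order (ties broken by ascending
facility id) and the facility whose addition first attains the
threshold share is preferred. Hospitals with no prior-year volume get
an empty preferred set and stay in the analysis. Prior-year volumes
count all SNF-bound discharges before cohort exclusions, on the view
that referral relationships reflect total flow.

IPW weights are ATE-style (1/e and 1/(1−e)) normalized to mean one per
exposure group — ATE rather than ATT because the weighted estimand
should blend both groups toward the pooled covariate distribution.
Quintiles are cut on the pooled trimmed score distribution.

## The synthetic generator

`generate_population` emulates the structure of a national discharge
dataset with a known truth:

* **Geography.** States are rectangular tiles (~250 km); hospitals
  scatter uniformly within a tile; SNFs cluster around hospitals with
  a long-tailed exponential radial mixture (scale 12 km, 20% at
  4× that), so the 22 km radius binds in dense markets and the
  15-nearest rule in thin ones. Patient homes scatter ~8 km around
  the discharging hospital; home coordinates stand in for zip-centroid
  geocoding.
* **Patients.** Age is a mixture of under-65 (disability-entitled,
  7.5%) and 65+ (normal around 79); sex, race/ethnicity, urbanicity,
  Medicare Advantage, ESRD, and a truncated-Poisson comorbidity index
  are drawn marginally; dual eligibility is far more common under 65.
  OUD follows a logistic model whose slopes fix the confounding
  directions (younger age, dual eligibility) and whose intercept is
  solved at generation time so realized prevalence matches the target
  (default 1.2%).
* **Placement.** Each discharge's SNF is a draw from the conditional
  logit itself (Gumbel-max) over the hospital's choice set, defined as
  (within radius) ∪ (k nearest) same-state SNFs. Because chosen
  alternatives come from that set, the pipeline's three-category union
  reconstructs exactly the same sets, so the downstream model is
  correctly specified by construction.
* **Preferred dynamics.** The first calendar year of the window is a
  burn-in with empty preferred networks; each later year classifies
  preferred SNFs from realized prior-year volumes with the same
  cumulative rule the pipeline applies, so generator truth and
  pipeline classification agree exactly (asserted in tests).
* **Default effects.** β makes preferred status and home proximity the
  dominant drivers with a modest quality effect; δ injects negative
  OUD×preferred and OUD×quality interactions — the access gap under
  study — plus small positive for-profit and %Medicaid interactions.

What the generator does **not** emulate: real geography or zip
geometry, ICD-coded exposure (OUD arrives as a flag), enrollment-file
semantics, facility openings/closures, capacity constraints, or
referral-and-rejection dynamics. Passing tests therefore demonstrate
the *machinery* — filters, classification, matching, weighting,
likelihoods, margins — and estimator calibration under correct
specification; they cannot certify behaviour under the selection
processes real claims data embed.

A separate binary-panel simulator (`simulate_lpm_outcome`) injects an
exact within-hospital OUD gap for linear-probability recovery tests,
and `simulate_choice_data` draws long-format choice data directly from
supplied (β, δ) for estimator-level studies, bypassing geography.

## Numerical choices

* **Distances** are haversine on the IUGG mean sphere (6371.0088 km).
  At sub-25 km scales the gap to an ellipsoidal geodesic (<0.3%)
  cannot flip the documented thresholds; test fixtures keep points
  away from the 22 km boundary.
* **Optimization** is Newton–Raphson with backtracking line search on
  the analytic gradient and Hessian, log-sum-exp stabilized, falling
  back to BFGS if the Hessian is not positive definite; convergence is
  gradient max-norm < 1e−8. Columns are scaled by their standard
  deviation for conditioning (softmax is location-invariant within a
  set, so no centering is needed) and estimates are reported back on
  the natural scale exactly.
* **Cluster-robust covariance** is the sandwich with score
  contributions summed within state clusters and a G/(G−1) factor;
  with one cluster per choice set it reduces to the plain robust
  estimator (asserted). P-values use a t reference with G−1 degrees
  of freedom — the standard small-G correction; with 20 clusters the
  normal reference over-rejects noticeably (≈7.5% at nominal 5% in
  simulation) while the t reference sits near 6%.
* **Star ratings** enter the choice model linearly (per-star), matching
  the "+1 star" margin framing; missing ratings are imputed at the
  neutral value 3 inside the choice model (the generating process must
  rank unrated facilities too) but propagate as missing in the quality
  outcomes, where those rows are excluded with a logged count. In the
  +1-star margin, closest SNFs already at 5 stars cannot be
  manipulated under linear entry and are excluded and counted rather
  than diluting the estimand with zeros.
* **Matching** is greedy without replacement within exact hospital
  strata: seeded random case order, controls ranked by date distance
  with seeded random tie-breaks. Optimal matching would add cost
  without changing the estimand materially in exact strata.
* **Degenerate inputs** fail loudly: choice sets without exactly one
  chosen row, attributes with no within-set variation (unidentified in
  conditional logit), fewer than five distinct propensity scores, a
  completely separated propensity model. Quasi-separation of rare
  covariate categories is tolerated — boundary scores fall to the
  trimming step — and constant design columns are dropped with a
  warning.

## Simulation study sizes

The bundled studies use sizes chosen to give the relevant checks
adequate precision while keeping a full run in minutes on one CPU:
recovery at 5,000 choice sets × 10 alternatives (the 3-SE single-draw
check allows one documented re-draw, since a correct estimator misses
a 3-SE band on some draw of six coefficients ~5% of the time);
coverage over 100–200 replicates at 1,000 sets; test size over 400
null replicates at 400 sets; power at δ_preferred = −0.8 over 100
replicates at 300 and 1,000 sets (approximate power >0.99 at the
larger size); IIA thinning at 2,000 sets × 8 alternatives; the
end-to-end pipeline at 60,000 discharges. The pipeline's matched
subsample at that scale (~1,300 choice sets) yields serviceable but
wide interaction confidence intervals; estimator-level claims rest on
the direct simulators.

## Known limitations

* Margins carry no delta-method standard errors; inference on group
  differences runs through the interaction coefficients only.
* Star ratings are treated linearly in the choice model; a categorical
  entry would change the margin definition.
* The IIA check is a stability comparison, not a formal
  Hausman–McFadden test.
* With few clusters (the synthetic default is 3–4 states in small
  runs) cluster-robust intervals are wide and approximate; the
  simulation studies use 20 clusters.
* Nested/mixed logit, caliper matching, doubly-robust weighting, and
  multiple imputation for missing ratings are out of scope.
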