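# snfchoice

Do hospitalized patients with opioid use disorder (OUD) reach their
hospitals' *preferred* and *high-quality* skilled nursing facilities
(SNFs) at the same rate as comparable patients without OUD?
`snfchoice` implements the full analysis chain for that question as a
tested, reusable Python package, exercised end to end on a synthetic
discharge generator with known ground truth (the real analysis runs on
restricted Medicare claims that have no public release).

It is aimed at health-services and pharmacoepidemiology researchers
who study post-acute care transitions, referral networks, and access
disparities with discrete-choice methods.

## What it computes

**Choice sets and preferred networks.** Each discharge's choice set is
the union of (a) all same-state SNFs that received a discharge from the
hospital that year, (b) all SNFs within 22 km of the hospital, and
(c) the 15 nearest SNFs. A hospital-year's *preferred* network is the
smallest set of highest-volume SNFs covering a cumulative 50% (a
configurable threshold with a 10%–80% sensitivity grid) of the
hospital's prior-year SNF discharges.

**Placement models.**

1. *Linear probability models with hospital fixed effects*
   (`FixedEffectsLPM`): within-hospital OUD gaps in the probability of
   entering a preferred SNF, a high-quality (4–5 star) SNF, and a
   high-quality SNF among preferred-SNF discharges, adjusted for
   patient covariates, with heteroskedasticity-robust errors.
2. *McFadden conditional logit* (`ConditionalLogit`), written from the
   likelihood up: the probability that discharge *i* enters
   alternative *j* is

   ```
   P(choice_i = j) = exp(v_ij) / Σ_k exp(v_ik),
   v_ij = x_ij' β + d_i · (x_ij' δ)
   ```

   where `x_ij` collects SNF attributes (preferred status, star
   rating, home and hospital distances, ownership, chain status,
   hospital affiliation, beds, occupancy, % Medicaid) and `d_i` flags
   OUD. Patient-level covariates are absorbed by the choice set, so
   the exposure enters only through the interactions `δ` — the
   coefficients of interest. Standard errors are cluster-robust by
   state with a t(G−1) reference.

**Confounding control.** OUD discharges are matched 1:k (k ≤ 3) to
non-OUD discharges on hospital and date (±2 days); a logistic
propensity model (age as a two-piece spline, demographics, dual
eligibility, Medicare Advantage, ESRD, urbanicity, comorbidity index)
yields inverse-probability-of-treatment weights (trimmed, ATE-style)
and propensity-quintile subclassification, with conditional-logit fits
weighted and re-estimated per quintile.

**Counterfactual margins.** For each patient's *closest* SNF, the model
is re-evaluated with that facility's preferred flag switched on versus
off, or its star rating raised by one, holding everything else fixed;
the average change in entry probability is reported per exposure group
in percentage points, and group differences are tested through the
`δ` interactions. A choice-set *thinning* check (randomly removing
5–20% of non-chosen alternatives and refitting) probes the
independence-of-irrelevant-alternatives assumption.

**Synthetic generator.** `generate_population` draws hospitals and
SNFs on a tiled geography, patients with realistic covariates, OUD
from a calibrated logistic model (default prevalence 1.2%, OUD
patients younger and more often dual-eligible), and each SNF placement
from the conditional-logit process above — returning the true (β, δ),
propensities, choice sets, and dynamic preferred networks for use as
test oracles.

## Worked example

Simulate 2,000 choice sets of 10 SNFs from known coefficients, fit the
interacted conditional logit, and compute closest-SNF margins:

```python
from snfchoice import ConditionalLogit, simulate_choice_data, closest_snf_margin

beta  = {"preferred": 1.0,  "star_rating": 0.20,  "dist_home_km": -0.10}
delta = {"preferred": -0.40, "star_rating": -0.25, "dist_home_km": 0.02}
table = simulate_choice_data(2000, 10, beta, delta, n_clusters=20, seed=7)
fit = ConditionalLogit.from_choice_table(table).fit()
print(fit.summary().round(4))
for attr in ("preferred", "star_rating"):
    e = closest_snf_margin(fit, table, attr)
    print(f"{attr}: non-OUD {e.margin_non_oud_pp:+.2f} pp | OUD {e.margin_oud_pp:+.2f} pp "
          f"| diff {e.difference_pp:+.2f} pp (p={e.p_value:.4f})")
```

```
                      coef  cluster_se        z       p
preferred           1.0279      0.0630  16.3170  0.0000
star_rating         0.2018      0.0206   9.7949  0.0000
dist_home_km       -0.0948      0.0061 -15.6038  0.0000
oud_x_preferred    -0.4304      0.0961  -4.4784  0.0003
oud_x_star_rating  -0.2228      0.0281  -7.9196  0.0000
oud_x_dist_home_km  0.0152      0.0073   2.0778  0.0515

preferred: non-OUD +14.84 pp | OUD +8.37 pp | diff -6.47 pp (p=0.0003)
star_rating: non-OUD +2.59 pp | OUD -0.27 pp | diff -2.86 pp (p=0.0000)
```

Every main effect and interaction lands within sampling error of its
generating value. The margins read as: making the closest SNF
preferred raises a non-OUD patient's probability of entering it by
14.8 percentage points but an OUD patient's by only 8.4 (the injected
negative `δ_preferred`); an extra star helps patients without OUD and
does nothing (here slightly negative) for patients with OUD, the
pattern the interaction test flags.

The full pipeline — generation, cohort filters, choice sets, matching,
weighting, both model families, margins, and the IIA check — runs from
one configuration:

```python
from snfchoice import PipelineConfig, run_pipeline
results = run_pipeline(PipelineConfig(seed=1, out_dir="runs/demo"))
```

or from the shell via `snfchoice run-all --seed 1 --out runs/demo`
(stage-by-stage commands `simulate`, `build`, `match`, `weight`,
`fit-lpm`, `fit-clogit`, `margins`, `iia-check`, and `report` are also
available; each run writes CSV tables with JSON schema sidecars and
its resolved configuration).

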