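"""Matched-cohort machinery: 1:k matching, propensity scores, IPW.

Conditional logit absorbs everything constant within a choice set, so
patient-level confounding between the exposure groups is handled
before estimation: each discharge with opioid use disorder (OUD) is
matched to up to k non-OUD discharges from the same hospital within a
+/-2 day window, then inverse-probability-of-treatment weights and
propensity-score quintiles are built on the matched sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


@dataclass
class MatchedCohort:
    """Result of greedy without-replacement matching."""

    pairs: List[Tuple[str, List[str]]]  # (oud discharge_id, control ids)
    ratio: int
    unmatched_oud: int
    date_window_days: int

    @property
    def matched_ids(self) -> List[str]:
        out = []
        for case, controls in self.pairs:
            out.append(case)
            out.extend(controls)
        return out


@dataclass
class PropensityFit:
    """Logistic propensity model for OUD on the matched sample."""

    params: pd.Series
    bse: pd.Series
    scores: pd.Series  # indexed by discharge_id, in (0, 1)
    dropped_columns: List[str]
    knot_age: float
    model_result: object = None


def match(
    discharges: pd.DataFrame,
    ratio: int = 1,
    window_days: int = 2,
    seed: int = 0,
) -> MatchedCohort:
    """Greedy 1:k matching on hospital and discharge date (+/- window).

    OUD cases are processed in seeded random order; eligible controls
    (same hospital, within the window, not yet used) are ranked by
    absolute date difference with seeded random tie-breaks.  Cases with
    no eligible control are dropped and counted.
    """
    if ratio not in (1, 2, 3):
        raise ValueError("ratio must be 1, 2, or 3")
    rng = np.random.default_rng(seed)
    d = discharges.copy()
    d["_date"] = pd.to_datetime(d["discharge_date"])

    pairs: List[Tuple[str, List[str]]] = []
    unmatched = 0
    for _, hosp_grp in d.groupby("hospital_id", sort=True):
        cases = hosp_grp[hosp_grp["oud"].astype(bool)]
        controls = hosp_grp[~hosp_grp["oud"].astype(bool)]
        if cases.empty:
            continue
        ctrl_dates = controls["_date"].to_numpy()
        ctrl_ids = controls["discharge_id"].to_numpy()
        used = np.zeros(len(controls), dtype=bool)

        case_order = rng.permutation(len(cases))
        for ci in case_order:
            case = cases.iloc[ci]
            gap = np.abs((ctrl_dates - case["_date"].to_numpy()) / np.timedelta64(1, "D"))
            eligible = np.flatnonzero((gap <= window_days) & ~used)
            if eligible.size == 0:
                unmatched += 1
                continue
            tie = rng.random(eligible.size)
            order = eligible[np.lexsort((tie, gap[eligible]))]
            take = order[:ratio]
            used[take] = True
            pairs.append((case["discharge_id"], list(ctrl_ids[take])))

    logger.info(
        "matching: %d cases matched (ratio up to %d), %d unmatched", len(pairs), ratio, unmatched
    )
    return MatchedCohort(
        pairs=pairs, ratio=ratio, unmatched_oud=unmatched, date_window_days=window_days
    )


def propensity_design(
    discharges: pd.DataFrame, knot_age: float = 65.0
) -> pd.DataFrame:
    """Covariate design for the propensity model.

    Age enters as a two-piece linear spline with a knot at ``knot_age``
    (Medicare eligibility boundary by default); categorical covariates
    are dummy-coded against their first level.
    """
    age = discharges["age"].astype(float)
    X = pd.DataFrame(index=discharges.index)
    X["age_below_knot"] = np.minimum(age, knot_age)
    X["age_above_knot"] = np.maximum(age - knot_age, 0.0)
    X["female"] = (discharges["sex"] == "female").astype(float)
    for col in ("race_ethnicity", "ruca"):
        dummies = pd.get_dummies(discharges[col], prefix=col, drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    for col in ("dual_eligible", "medicare_advantage", "esrd_eligibility"):
        X[col] = discharges[col].astype(float)
    X["elixhauser"] = discharges["elixhauser"].astype(float)
    return X


def fit_propensity(
    matched_discharges: pd.DataFrame, knot_age: float = 65.0
) -> PropensityFit:
    """Maximum-likelihood logit of OUD on the matched-sample design.

    Constant covariate columns are dropped with a warning.  Perfect
    separation fails with a diagnostic naming the separating covariate.
    """
    y = matched_discharges["oud"].astype(int).to_numpy()
    X = propensity_design(matched_discharges, knot_age=knot_age)

    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    if dropped:
        logger.warning("propensity design: dropping constant columns %s", dropped)
        X = X.drop(columns=dropped)

    design = sm.add_constant(X, has_constant="add")
    import warnings as _warnings

    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # quasi-separation noise; checked below
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError
        sep = _separating_covariate(X, y)
        raise RuntimeError(
            f"propensity fit failed (covariate most implicated: {sep}): {exc}"
        ) from exc
    fitted = np.asarray(res.predict(design))
    eps = 1e-8
    # complete separation: the model classifies the exposure perfectly.
    # quasi-separation of a rare category is tolerated — boundary scores
    # fall to the IPW trimming step.
    if np.all(fitted[y == 1] >= 1 - eps) and np.all(fitted[y == 0] <= eps):
        sep = _separating_covariate(X, y)
        raise RuntimeError(
            f"propensity model completely separated (covariate most implicated: {sep})"
        )
    scores = pd.Series(fitted, index=matched_discharges["discharge_id"].to_numpy())
    return PropensityFit(
        params=res.params,
        bse=res.bse,
        scores=scores,
        dropped_columns=dropped,
        knot_age=knot_age,
        model_result=res,
    )


def _separating_covariate(X: pd.DataFrame, y: np.ndarray) -> str:
    """Heuristic: covariate whose ranges in the two groups overlap least."""
    best, best_overlap = "unknown", np.inf
    for c in X.columns:
        v = X[c].to_numpy(dtype=float)
        a, b = v[y == 1], v[y == 0]
        if a.size == 0 or b.size == 0:
            continue
        overlap = min(a.max(), b.max()) - max(a.min(), b.min())
        if overlap < best_overlap:
            best, best_overlap = c, overlap
    return best


def compute_ipw(
    fit: PropensityFit,
    oud: pd.Series,
    trim_bounds: Tuple[float, float] = (0.01, 0.99),
) -> pd.DataFrame:
    """ATE-style inverse-probability-of-treatment weights after trimming.

    Weights are 1/e for OUD and 1/(1-e) otherwise, computed on records
    whose score lies inside ``trim_bounds``, then normalized to mean 1
    within each exposure group.  Returns a frame indexed by
    discharge_id with columns score, weight, oud.
    """
    lo, hi = trim_bounds
    scores = fit.scores
    oud = oud.reindex(scores.index).astype(bool)
    inside = (scores >= lo) & (scores <= hi)
    n_trimmed = int((~inside).sum())
    if inside.sum() == 0:
        raise RuntimeError("all records trimmed; no weights computable")
    if n_trimmed:
        logger.info("IPW trimming removed %d records outside [%g, %g]", n_trimmed, lo, hi)
    e = scores[inside]
    t = oud[inside]
    w = np.where(t, 1.0 / e, 1.0 / (1.0 - e))
    out = pd.DataFrame({"score": e, "weight": w, "oud": t.astype(int)})
    for g in (0, 1):
        mask = out["oud"] == g
        if mask.any():
            out.loc[mask, "weight"] /= out.loc[mask, "weight"].mean()
    return out


def assign_quintiles(weights: pd.DataFrame) -> pd.Series:
    """Quintile labels 1-5 from the pooled trimmed score distribution.

    Cut-points are pooled quantiles; counts per quintile are equal up
    to ties.  Fewer than five distinct scores is an error.
    """
    scores = weights["score"]
    if scores.nunique() < 5:
        raise ValueError(
            f"cannot form quintiles: only {scores.nunique()} distinct scores"
        )
    labels = pd.qcut(scores, q=5, labels=False, duplicates="drop")
    if labels.nunique() < 5:
        raise ValueError("cannot form 5 quintiles: score distribution too discrete")
    return (labels + 1).rename("quintile")


def standardized_mean_differences(
    discharges: pd.DataFrame,
    covariate_design: Optional[pd.DataFrame] = None,
    weights: Optional[pd.Series] = None,
) -> pd.Series:
    """Weighted standardized mean differences (OUD minus non-OUD).

    Denominator is the pooled *unweighted* standard deviation so that
    weighting schemes are compared on a fixed scale.
    """
    X = covariate_design if covariate_design is not None else propensity_design(discharges)
    oud = discharges["oud"].astype(bool).to_numpy()
    w = np.ones(len(X)) if weights is None else np.asarray(weights, dtype=float)
    out = {}
    for c in X.columns:
        v = X[c].to_numpy(dtype=float)
        sd = np.sqrt(0.5 * (v[oud].var(ddof=1) + v[~oud].var(ddof=1)))
        if sd == 0:
            out[c] = 0.0
            continue
        m1 = np.average(v[oud], weights=w[oud])
        m0 = np.average(v[~oud], weights=w[~oud])
        out[c] = (m1 - m0) / sd
    return pd.Series(out, name="smd")
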