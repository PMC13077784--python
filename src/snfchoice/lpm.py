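"""Linear probability models with absorbed hospital fixed effects.

The three binary placement outcomes (entered a preferred SNF; entered
a high-quality 4-5 star SNF; entered a high-quality SNF among those
discharged to preferred SNFs) are modelled by OLS on within-hospital
demeaned data, which is numerically identical to including one dummy
per hospital.  Hospitals contributing a single observation are dropped
(their fixed effect absorbs the row entirely) and counted.  Standard
errors are heteroskedasticity-robust (HC1) with degrees of freedom
corrected for the absorbed effects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Patient-level adjustment covariates for the placement models.
LPM_COVARIATES = (
    "oud",
    "age",
    "female",
    "race_ethnicity",
    "dual_eligible",
    "medicare_advantage",
    "esrd_eligibility",
    "ruca",
    "elixhauser",
)


@dataclass
class LPMResults:
    """Estimates from a fixed-effects linear probability model."""

    outcome: str
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame  # columns: lower, upper
    n_used: int
    n_singletons_dropped: int
    n_hospitals: int
    df_resid: int

    @property
    def tvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        t = self.tvalues.to_numpy(dtype=float)
        p = 2.0 * stats.t.sf(np.abs(t), df=max(self.df_resid, 1))
        return pd.Series(p, index=self.params.index)

    def summary(self) -> pd.DataFrame:
        tab = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "ci_low": self.conf_int["lower"],
                "ci_high": self.conf_int["upper"],
                "p": self.pvalues,
            }
        )
        tab.attrs["outcome"] = self.outcome
        tab.attrs["n_used"] = self.n_used
        tab.attrs["n_singletons_dropped"] = self.n_singletons_dropped
        tab.attrs["n_hospitals"] = self.n_hospitals
        return tab


class FixedEffectsLPM:
    """OLS on a binary outcome with group (hospital) effects absorbed.

    Parameters
    ----------
    y : array of 0/1 outcomes
    X : DataFrame of regressors (no constant; it is absorbed)
    groups : array of hospital labels, one per row
    outcome : display name for the outcome
    """

    def __init__(self, y, X: pd.DataFrame, groups, outcome: str = "outcome"):
        self.y = np.asarray(y, dtype=float)
        self.X = X.astype(float)
        self.groups = np.asarray(groups)
        self.outcome = outcome
        if self.y.ndim != 1 or len(self.y) != len(self.X) or len(self.y) != len(self.groups):
            raise ValueError("y, X, and groups must have matching lengths")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str,
        covariates: Sequence[str] = LPM_COVARIATES,
        group_col: str = "hospital_id",
    ) -> "FixedEffectsLPM":
        """Build the design from a per-discharge frame.

        Rows with a missing outcome are excluded with a logged count
        (missing star ratings propagate into the quality outcomes).
        Categorical covariates are dummy-coded against the first level;
        ``female`` is derived from ``sex`` when absent.
        """
        d = df.copy()
        n_missing = int(d[outcome].isna().sum())
        if n_missing:
            logger.info("%s: excluding %d rows with missing outcome", outcome, n_missing)
            d = d[d[outcome].notna()]
        if "female" not in d.columns and "sex" in d.columns:
            d["female"] = (d["sex"] == "female").astype(float)
        X = pd.DataFrame(index=d.index)
        for c in covariates:
            if c not in d.columns:
                continue
            if d[c].dtype == object or isinstance(d[c].dtype, pd.CategoricalDtype):
                X = pd.concat(
                    [X, pd.get_dummies(d[c], prefix=c, drop_first=True, dtype=float)], axis=1
                )
            else:
                X[c] = d[c].astype(float)
        return cls(d[outcome].to_numpy(dtype=float), X, d[group_col].to_numpy(), outcome)

    def fit(self) -> LPMResults:
        codes, counts = np.unique(self.groups, return_counts=True)
        singleton_groups = set(codes[counts == 1])
        keep = ~np.isin(self.groups, list(singleton_groups))
        n_singletons = int((~keep).sum())
        if n_singletons:
            logger.info("dropping %d singleton observations", n_singletons)
        y = self.y[keep]
        X = self.X.loc[self.X.index[keep]]
        g = self.groups[keep]

        if len(y) == 0:
            raise ValueError("no observations left after dropping singletons")

        gcodes = pd.factorize(g)[0]
        n_groups = gcodes.max() + 1
        Xv = X.to_numpy(dtype=float)

        ybar = np.bincount(gcodes, weights=y) / np.bincount(gcodes)
        yd = y - ybar[gcodes]
        Xd = np.empty_like(Xv)
        for j in range(Xv.shape[1]):
            xbar = np.bincount(gcodes, weights=Xv[:, j]) / np.bincount(gcodes)
            Xd[:, j] = Xv[:, j] - xbar[gcodes]

        names = list(X.columns)
        k = Xd.shape[1]
        df_resid = len(y) - k - n_groups

        if np.allclose(yd, 0.0):
            warnings.warn(
                f"{self.outcome}: outcome constant within every hospital; coefficients set to 0"
            )
            zero = pd.Series(0.0, index=names)
            ci = pd.DataFrame({"lower": zero, "upper": zero})
            return LPMResults(
                self.outcome, zero, zero, ci, len(y), n_singletons, int(n_groups), max(df_resid, 1)
            )

        XtX = Xd.T @ Xd
        beta, *_ = np.linalg.lstsq(Xd, yd, rcond=None)
        resid = yd - Xd @ beta

        XtX_inv = np.linalg.pinv(XtX)
        meat = (Xd * (resid**2)[:, None]).T @ Xd
        scale = len(y) / max(df_resid, 1)  # HC1 with absorbed-FE dof
        cov = scale * XtX_inv @ meat @ XtX_inv
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))

        crit = stats.t.ppf(0.975, df=max(df_resid, 1))
        params = pd.Series(beta, index=names)
        bse_s = pd.Series(bse, index=names)
        ci = pd.DataFrame(
            {"lower": params - crit * bse_s, "upper": params + crit * bse_s}
        )
        return LPMResults(
            outcome=self.outcome,
            params=params,
            bse=bse_s,
            conf_int=ci,
            n_used=len(y),
            n_singletons_dropped=n_singletons,
            n_hospitals=int(n_groups),
            df_resid=max(df_resid, 1),
        )


def make_outcomes(
    kept_discharges: pd.DataFrame,
    facilities: pd.DataFrame,
    networks,
    high_quality_stars: Sequence[int] = (4, 5),
) -> pd.DataFrame:
    """Per-discharge binary placement outcomes.

    ``preferred_entry``: chosen SNF in the hospital-year's preferred
    set.  ``high_quality_entry``: chosen SNF rated 4-5 stars (missing
    rating propagates as missing and those rows are later excluded from
    quality models).  ``hq_given_preferred``: high-quality entry
    restricted to preferred-entry rows, else missing.
    """
    d = kept_discharges.copy()
    years = pd.to_datetime(d["discharge_date"]).dt.year
    star = d["chosen_facility_id"].map(facilities.set_index("facility_id")["star_rating"])

    pref = [
        1.0
        if row_choice in networks[(h, y)].preferred_set
        else 0.0
        for row_choice, h, y in zip(d["chosen_facility_id"], d["hospital_id"], years)
    ]
    d["preferred_entry"] = pref
    hq = star.isin(high_quality_stars).astype(float)
    hq[star.isna()] = np.nan
    d["high_quality_entry"] = hq
    d["hq_given_preferred"] = np.where(d["preferred_entry"] == 1.0, hq, np.nan)
    n_missing = int(star.isna().sum())
    if n_missing:
        logger.info("%d discharges have chosen SNFs with missing star ratings", n_missing)
    return d
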