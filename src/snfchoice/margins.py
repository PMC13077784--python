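"""Counterfactual closest-SNF marginal effects and IIA sensitivity.

Marginal effects in conditional logit differ per alternative and per
choice set, so effects are evaluated at a policy-relevant anchor: the
SNF closest to each patient's home.  For each discharge the closest
alternative's attribute is manipulated (preferred off -> on, or star
rating +1), the softmax is re-evaluated with all other attributes and
alternatives held fixed, and the change in that alternative's
predicted entry probability is averaged within exposure groups, in
percentage points.  Group differences are tested through the
corresponding OUD x attribute interaction coefficient (cluster-robust
Wald), not through the margins themselves.

The conditional logit's independence-of-irrelevant-alternatives (IIA)
assumption is probed by randomly thinning non-chosen alternatives from
every choice set and comparing refitted coefficients to the full-model
estimates on the scale of the full-model standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .clogit import ConditionalLogit, ConditionalLogitResults

logger = logging.getLogger(__name__)

MANIPULATIONS = ("preferred", "star_rating")


@dataclass
class MarginalEffect:
    """Closest-SNF margin for one manipulated attribute and stratum."""

    attribute: str
    stratum: str
    margin_non_oud_pp: float
    margin_oud_pp: float
    difference_pp: float
    p_value: float
    n_non_oud: int
    n_oud: int
    n_excluded: int  # sets skipped (capped or missing attribute)

    def as_dict(self) -> dict:
        return {
            "attribute": self.attribute,
            "stratum": self.stratum,
            "non_oud_pp": self.margin_non_oud_pp,
            "oud_pp": self.margin_oud_pp,
            "difference_pp": self.difference_pp,
            "p_value": self.p_value,
            "n_excluded": self.n_excluded,
        }


def _counterfactual_probs(
    fit: ConditionalLogitResults,
    table: pd.DataFrame,
    attribute: str,
    closest_mask: np.ndarray,
    values: np.ndarray,
) -> np.ndarray:
    """Closest-row probabilities with ``attribute`` set to ``values``.

    ``values`` has one entry per closest row (table order).  Rebuilds
    the design exactly as the fitted model did and evaluates the
    softmax at the fitted coefficients.
    """
    cf = table.copy()
    col = cf[attribute].to_numpy(dtype=float).copy()
    col[closest_mask] = values
    cf[attribute] = col
    attrs = [n for n in fit.params.index if not n.startswith("oud_x_")]
    model = ConditionalLogit.from_choice_table(
        cf,
        attributes=attrs,
        interactions="oud" in cf.columns,
        cluster_col=None,
        check_identification=False,
    )
    p = model._probabilities(
        fit.params.reindex(model.names).to_numpy(), model.X
    )
    # model sorts rows by discharge_id; map closest probabilities back
    order = np.argsort(table["discharge_id"].to_numpy(), kind="stable")
    p_table_order = np.empty_like(p)
    p_table_order[order] = p
    return p_table_order[closest_mask]


def closest_snf_margin(
    fit: ConditionalLogitResults,
    choice_table: pd.DataFrame,
    manipulation: str,
    stratum: str = "overall",
    use_weights: Optional[bool] = None,
) -> MarginalEffect:
    """Average closest-SNF probability change under a manipulation.

    ``manipulation`` is ``"preferred"`` (entry probability when the
    closest SNF is preferred versus non-preferred) or ``"star_rating"``
    (+1 star; closest SNFs already at 5 stars or with missing ratings
    cannot be manipulated under the linear-entry convention and are
    excluded with a count).  Deterministic given the fit — no
    Monte-Carlo.  Averages use the fit's weights when it was weighted.
    """
    if manipulation not in MANIPULATIONS:
        raise ValueError(f"manipulation must be one of {MANIPULATIONS}")
    t = choice_table.reset_index(drop=True)
    closest = t["closest"].to_numpy() == 1
    base_vals = t.loc[closest, manipulation].to_numpy(dtype=float)

    if manipulation == "preferred":
        keep_sets = np.ones(closest.sum(), dtype=bool)
        lo_vals = np.zeros(closest.sum())
        hi_vals = np.ones(closest.sum())
    else:
        keep_sets = np.isfinite(base_vals) & (base_vals < 5.0)
        lo_vals = base_vals
        hi_vals = base_vals + 1.0
    n_excluded = int((~keep_sets).sum())
    if n_excluded:
        logger.info(
            "%s margin: %d closest SNFs not manipulable (capped/missing)",
            manipulation,
            n_excluded,
        )

    p_lo = _counterfactual_probs(fit, t, manipulation, closest, np.where(keep_sets, lo_vals, base_vals))
    p_hi = _counterfactual_probs(fit, t, manipulation, closest, np.where(keep_sets, hi_vals, base_vals))
    delta_pp = (p_hi - p_lo) * 100.0

    set_oud = t.loc[closest, "oud"].to_numpy(dtype=int)
    weighted = fit.weighted if use_weights is None else use_weights
    if weighted and "weight" in t.columns:
        w = t.loc[closest, "weight"].to_numpy(dtype=float)
    else:
        w = np.ones(closest.sum())

    def _avg(group: int) -> Tuple[float, int]:
        m = keep_sets & (set_oud == group)
        if not m.any():
            return float("nan"), 0
        return float(np.average(delta_pp[m], weights=w[m])), int(m.sum())

    m0, n0 = _avg(0)
    m1, n1 = _avg(1)
    _, p_val = margin_difference_test(fit, manipulation)
    return MarginalEffect(
        attribute=manipulation,
        stratum=stratum,
        margin_non_oud_pp=m0,
        margin_oud_pp=m1,
        difference_pp=m1 - m0,
        p_value=p_val,
        n_non_oud=n0,
        n_oud=n1,
        n_excluded=n_excluded,
    )


def margin_difference_test(
    fit: ConditionalLogitResults, attribute: str
) -> Tuple[float, float]:
    """Cluster-robust Wald z and two-sided p for the OUD interaction."""
    term = f"oud_x_{attribute}"
    if term not in fit.params.index:
        raise KeyError(
            f"interaction {term!r} absent from the fit; cannot test the margin difference"
        )
    return fit.wald_test(term)


def thin_choice_table(
    choice_table: pd.DataFrame, drop_fraction: float, seed: int = 0
) -> pd.DataFrame:
    """Remove a seeded random share of non-chosen alternatives per set.

    The chosen alternative is never removable and at least one
    non-chosen alternative is always retained; sets with fewer than
    two alternatives are left untouched.
    """
    if not 0.0 <= drop_fraction <= 0.20:
        raise ValueError("drop_fraction must lie in [0, 0.20]")
    if drop_fraction == 0.0:
        return choice_table.copy()
    rng = np.random.default_rng(seed)
    keep_idx = []
    for _, grp in choice_table.groupby("discharge_id", sort=True):
        non_chosen = grp.index[grp["choice"] == 0]
        n_drop = int(np.floor(drop_fraction * len(non_chosen)))
        n_drop = min(n_drop, len(non_chosen) - 1)
        if n_drop <= 0 or len(grp) < 2:
            keep_idx.append(grp.index.to_numpy())
            continue
        drop = rng.choice(non_chosen.to_numpy(), size=n_drop, replace=False)
        keep_idx.append(np.setdiff1d(grp.index.to_numpy(), drop))
    kept = choice_table.loc[np.concatenate(keep_idx)]
    return kept.reset_index(drop=True)


def iia_thinning_check(
    choice_table: pd.DataFrame,
    drop_fraction: float,
    seed: int = 0,
    full_fit: Optional[ConditionalLogitResults] = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Refit after thinning and compare coefficients to the full model.

    Returns one row per coefficient: full and thinned estimates, their
    difference, the full-model cluster SE, and the shift expressed in
    SE units.  Under IIA (which holds by construction for data
    generated from the model) shifts stay within sampling error.
    """
    if full_fit is None:
        full_fit = ConditionalLogit.from_choice_table(choice_table, **fit_kwargs).fit()
    thinned = thin_choice_table(choice_table, drop_fraction, seed=seed)
    thin_fit = ConditionalLogit.from_choice_table(thinned, **fit_kwargs).fit()
    out = pd.DataFrame(
        {
            "full": full_fit.params,
            "thinned": thin_fit.params.reindex(full_fit.params.index),
        }
    )
    out["diff"] = out["thinned"] - out["full"]
    out["full_se"] = full_fit.bse
    out["shift_in_se"] = out["diff"] / out["full_se"]
    out.attrs["drop_fraction"] = drop_fraction
    out.attrs["n_sets"] = full_fit.n_choice_sets
    return out
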