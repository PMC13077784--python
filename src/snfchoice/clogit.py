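"""McFadden conditional logit with exposure interactions, from scratch.

The probability that discharge ``i`` enters alternative ``j`` of its
choice set is the softmax of a linear index over SNF attributes::

    P(choice_i = j) = exp(v_ij) / sum_k exp(v_ik),
    v_ij = x_ij' beta + d_i * (x_ij' delta)

where ``d_i`` flags opioid use disorder.  Patient-level covariates are
constant within a choice set and therefore unidentified as main
effects; the exposure enters only through the interactions ``delta``.

Estimation is Newton-Raphson on the analytic gradient and Hessian
(log-sum-exp stabilized), with a BFGS fallback on a non-positive-
definite Hessian, and a cluster-robust (state-clustered) sandwich
covariance.  Continuous attributes are standardized internally for
optimizer conditioning and estimates are reported on the original
scale.  Observation weights (one per choice set, e.g. inverse
propensity weights) multiply each set's log-likelihood contribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .config import ATTRIBUTES
from .synthetic import NEUTRAL_STAR

logger = logging.getLogger(__name__)


def _group_structure(group_ids: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Contiguous group codes, start offsets, and per-row group index.

    Rows must already be sorted so that each group is contiguous.
    """
    codes, first = np.unique(group_ids, return_index=True)
    order = np.argsort(first)
    codes = codes[order]
    starts = np.sort(first)
    idx = np.searchsorted(starts, np.arange(len(group_ids)), side="right") - 1
    return codes, starts, idx


class ConditionalLogit:
    """Conditional (McFadden) logit model over grouped alternatives.

    Parameters
    ----------
    choice : 0/1 array, exactly one 1 per group
    X : (n_rows, p) design of alternative-varying regressors
    group_ids : choice-set label per row (rows of a set need not be
        contiguous; the constructor sorts)
    names : column names for reporting
    weights : optional per-row weights, constant within a group
    cluster : optional cluster label per row (constant within group)
        for the sandwich covariance; defaults to one cluster per set
    """

    def __init__(
        self,
        choice,
        X,
        group_ids,
        names: Sequence[str],
        weights=None,
        cluster=None,
        check_identification: bool = True,
    ):
        choice = np.asarray(choice, dtype=float)
        X = np.asarray(X, dtype=float)
        group_ids = np.asarray(group_ids)
        if not np.all(np.isfinite(X)):
            raise ValueError("design contains non-finite attribute values")
        order = np.argsort(group_ids, kind="stable")
        self.choice = choice[order]
        self.X = X[order]
        self.group_ids = group_ids[order]
        self.names = list(names)
        if len(self.names) != self.X.shape[1]:
            raise ValueError("names length must match design width")

        w = np.ones(len(choice)) if weights is None else np.asarray(weights, dtype=float)[order]
        cl = self.group_ids if cluster is None else np.asarray(cluster)[order]

        self.group_codes, self._starts, self._gidx = _group_structure(self.group_ids)
        self.n_sets = len(self.group_codes)
        sizes = np.diff(np.append(self._starts, len(self.choice)))
        self._sizes = sizes

        chosen_per_set = np.add.reduceat(self.choice, self._starts)
        bad = np.flatnonzero(chosen_per_set != 1)
        if bad.size:
            raise ValueError(
                f"choice set {self.group_codes[bad[0]]!r} has "
                f"{int(chosen_per_set[bad[0]])} chosen rows (need exactly 1)"
            )
        self._chosen_rows = np.flatnonzero(self.choice == 1.0)

        # per-set weight and cluster (taken from the first row of each set)
        self.set_weights = w[self._starts]
        if not np.allclose(w, self.set_weights[self._gidx]):
            raise ValueError("weights must be constant within each choice set")
        self.set_cluster = cl[self._starts]

        if check_identification:
            self._check_identification()
        # scale-only standardization: softmax is location-invariant per
        # set, so only the column scale matters for conditioning
        sd = self.X.std(axis=0)
        self._scale = np.where(sd > 0, sd, 1.0)
        self._Xs = self.X / self._scale

    # -- construction from the long choice table ---------------------------

    @classmethod
    def from_choice_table(
        cls,
        df: pd.DataFrame,
        attributes: Optional[Sequence[str]] = None,
        interactions: bool = True,
        oud_col: str = "oud",
        weight_col: Optional[str] = None,
        cluster_col: Optional[str] = "state_id",
        group_col: str = "discharge_id",
        check_identification: bool = True,
    ) -> "ConditionalLogit":
        """Build the model from one-row-per-alternative data.

        Missing star ratings are imputed at the neutral value used by
        the generator's utility (3.0) with a logged count; interaction
        columns ``oud_x_<attr>`` are appended when ``interactions``.
        """
        attrs = [a for a in (attributes or ATTRIBUTES) if a in df.columns]
        if not attrs:
            raise ValueError("no model attributes found in the choice table")
        Xm = df[attrs].to_numpy(dtype=float).copy()
        if "star_rating" in attrs:
            j = attrs.index("star_rating")
            n_missing = int(np.isnan(Xm[:, j]).sum())
            if n_missing:
                logger.info(
                    "imputing %d missing star ratings at %.1f for the choice model",
                    n_missing,
                    NEUTRAL_STAR,
                )
                Xm[np.isnan(Xm[:, j]), j] = NEUTRAL_STAR
        names = list(attrs)
        blocks = [Xm]
        if interactions:
            d = df[oud_col].to_numpy(dtype=float)[:, None]
            blocks.append(Xm * d)
            names += [f"oud_x_{a}" for a in attrs]
        X = np.hstack(blocks)
        return cls(
            choice=df["choice"].to_numpy(),
            X=X,
            group_ids=df[group_col].to_numpy(),
            names=names,
            weights=df[weight_col].to_numpy() if weight_col else None,
            cluster=df[cluster_col].to_numpy() if cluster_col and cluster_col in df.columns else None,
            check_identification=check_identification,
        )

    # -- likelihood ---------------------------------------------------------

    def _check_identification(self) -> None:
        hi = np.maximum.reduceat(self.X, self._starts, axis=0)
        lo = np.minimum.reduceat(self.X, self._starts, axis=0)
        spread = (hi - lo).max(axis=0)
        dead = np.flatnonzero(spread <= 1e-12)
        if dead.size:
            bad = [self.names[j] for j in dead]
            raise ValueError(
                f"attributes {bad} never vary within any choice set; such "
                "terms are unidentified in conditional logit (alternative-"
                "invariant covariates must enter via interactions)"
            )

    def _probabilities(self, params: np.ndarray, X: np.ndarray) -> np.ndarray:
        v = X @ params
        vmax = np.maximum.reduceat(v, self._starts)
        ev = np.exp(v - vmax[self._gidx])
        denom = np.add.reduceat(ev, self._starts)
        return ev / denom[self._gidx]

    def loglik(self, params) -> float:
        """Weighted log-likelihood at ``params`` (original scale)."""
        return self._ll_core(np.asarray(params, dtype=float), self.X)[0]

    def score(self, params) -> np.ndarray:
        """Analytic gradient at ``params`` (original scale)."""
        return self._ll_core(np.asarray(params, dtype=float), self.X)[1]

    def loglik_and_gradient(self, params) -> Tuple[float, np.ndarray]:
        ll, g, _ = self._ll_core(np.asarray(params, dtype=float), self.X, hessian=False)
        return ll, g

    def _ll_core(
        self, params: np.ndarray, X: np.ndarray, hessian: bool = True
    ) -> Tuple[float, np.ndarray, Optional[np.ndarray]]:
        v = X @ params
        vmax = np.maximum.reduceat(v, self._starts)
        vc = v - vmax[self._gidx]
        ev = np.exp(vc)
        denom = np.add.reduceat(ev, self._starts)
        p = ev / denom[self._gidx]

        w = self.set_weights
        ll = float(np.sum(w * (vc[self._chosen_rows] - np.log(denom))))

        wp = w[self._gidx] * p
        xbar = np.add.reduceat(p[:, None] * X, self._starts, axis=0)
        g = X[self._chosen_rows].T @ w - xbar.T @ w

        H = None
        if hessian:
            H = -(X.T @ (wp[:, None] * X) - xbar.T @ (w[:, None] * xbar))
        return ll, g, H

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        tol: float = 1e-8,
        maxiter: int = 200,
    ) -> "ConditionalLogitResults":
        """Maximize the likelihood; Newton with BFGS fallback.

        Convergence is gradient max-norm below ``tol`` in the
        standardized parameterization.
        """
        Xs = self._Xs
        p = np.zeros(Xs.shape[1])
        used_fallback = False
        n_iter = 0
        for n_iter in range(1, maxiter + 1):
            ll, g, H = self._ll_core(p, Xs)
            if np.max(np.abs(g)) < tol:
                break
            try:
                c, low = linalg.cho_factor(-H)
                step = linalg.cho_solve((c, low), g)
            except linalg.LinAlgError:
                used_fallback = True
                res = optimize.minimize(
                    lambda b: -self._ll_core(b, Xs, hessian=False)[0],
                    p,
                    jac=lambda b: -self._ll_core(b, Xs, hessian=False)[1],
                    method="BFGS",
                    options={"gtol": tol / 10.0, "maxiter": 500},
                )
                p = res.x
                continue
            # backtracking line search on the likelihood
            scale = 1.0
            for _ in range(40):
                ll_new = self._ll_core(p + scale * step, Xs, hessian=False)[0]
                if ll_new > ll - 1e-12:
                    break
                scale *= 0.5
            p = p + scale * step

        ll, g, H = self._ll_core(p, Xs)
        grad_norm = float(np.max(np.abs(g)))
        converged = grad_norm < tol
        if not converged:
            warnings.warn(
                f"conditional logit did not reach gradient tolerance "
                f"(|g|_max = {grad_norm:.2e})"
            )

        cov_s = self._cluster_covariance(p, H)
        D = np.diag(1.0 / self._scale)
        params = p / self._scale
        cov = D @ cov_s @ D
        cov = 0.5 * (cov + cov.T)

        return ConditionalLogitResults(
            model=self,
            params=pd.Series(params, index=self.names),
            cov=pd.DataFrame(cov, index=self.names, columns=self.names),
            loglik=ll,
            grad_norm=grad_norm,
            converged=converged,
            n_iter=n_iter,
            used_bfgs_fallback=used_fallback,
            n_choice_sets=self.n_sets,
            n_alternatives=len(self.choice),
            n_clusters=len(np.unique(self.set_cluster)),
            weighted=not np.allclose(self.set_weights, 1.0),
            _params_std=p,
        )

    def _cluster_covariance(self, params_std: np.ndarray, H: np.ndarray) -> np.ndarray:
        """Sandwich: bread = inv(-H); meat = cluster-summed score outers.

        With one cluster per choice set this reduces to the plain
        heteroskedasticity-robust estimator.  Small-sample factor
        G/(G-1).
        """
        Xs = self._Xs
        p = self._probabilities(params_std, Xs)
        xbar = np.add.reduceat(p[:, None] * Xs, self._starts, axis=0)
        s = self.set_weights[:, None] * (Xs[self._chosen_rows] - xbar)  # per-set scores

        cl_codes, cl_idx = np.unique(self.set_cluster, return_inverse=True)
        G = len(cl_codes)
        S = np.zeros((G, Xs.shape[1]))
        np.add.at(S, cl_idx, s)
        meat = S.T @ S
        if G > 1:
            meat *= G / (G - 1)
        bread = np.linalg.pinv(-H)
        return bread @ meat @ bread


@dataclass
class ConditionalLogitResults:
    """Fitted conditional logit: estimates, sandwich covariance, record."""

    model: ConditionalLogit
    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    grad_norm: float
    converged: bool
    n_iter: int
    used_bfgs_fallback: bool
    n_choice_sets: int
    n_alternatives: int
    n_clusters: int
    weighted: bool
    _params_std: np.ndarray = field(repr=False, default=None)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    @property
    def zvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        """Two-sided p-values on a t reference with G-1 degrees of
        freedom (G = number of clusters), the standard small-G
        correction for cluster-robust Wald statistics."""
        z = self.zvalues.to_numpy(dtype=float)
        df = max(self.n_clusters - 1, 1)
        return pd.Series(2.0 * stats.t.sf(np.abs(z), df=df), index=self.params.index)

    def predict_proba(self, params: Optional[np.ndarray] = None) -> np.ndarray:
        """Per-row choice probabilities (model row order)."""
        b = self.params.to_numpy() if params is None else np.asarray(params, dtype=float)
        return self.model._probabilities(b, self.model.X)

    def wald_test(self, term: str) -> Tuple[float, float]:
        """Cluster-robust Wald statistic and two-sided p (t, G-1 df)."""
        if term not in self.params.index:
            raise KeyError(f"term {term!r} not in the fitted model")
        with np.errstate(divide="ignore", invalid="ignore"):
            z = float(self.params[term] / self.bse[term])
        df = max(self.n_clusters - 1, 1)
        p = float(2.0 * stats.t.sf(abs(z), df=df)) if np.isfinite(z) else float("nan")
        return z, p

    def summary(self) -> pd.DataFrame:
        tab = pd.DataFrame(
            {
                "coef": self.params,
                "cluster_se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )
        tab.attrs.update(
            loglik=self.loglik,
            n_choice_sets=self.n_choice_sets,
            n_alternatives=self.n_alternatives,
            n_clusters=self.n_clusters,
            converged=self.converged,
            weighted=self.weighted,
        )
        return tab


def fit_by_quintile(
    choice_table: pd.DataFrame,
    quintiles: pd.Series,
    min_choice_sets: int = 50,
    **from_table_kwargs,
) -> Dict[int, ConditionalLogitResults]:
    """Independent conditional-logit fits within propensity quintiles.

    ``quintiles`` maps discharge_id to a label 1-5.  Quintiles with
    fewer than ``min_choice_sets`` sets are skipped with a warning.
    """
    labels = choice_table["discharge_id"].map(quintiles)
    present = sorted(pd.unique(labels.dropna()))
    if len(present) < 2:
        raise ValueError(f"expected multiple quintile strata, found {present}")
    out: Dict[int, ConditionalLogitResults] = {}
    for q in present:
        sub = choice_table[labels == q]
        n_sets = sub["discharge_id"].nunique()
        if n_sets < min_choice_sets:
            warnings.warn(f"quintile {q}: only {n_sets} choice sets; fit skipped")
            continue
        out[int(q)] = ConditionalLogit.from_choice_table(sub, **from_table_kwargs).fit()
    return out
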