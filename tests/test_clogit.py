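"""Conditional logit: brute-force likelihood/gradient oracles,
invariances, identification failures, and sandwich covariance."""

import numpy as np
import pandas as pd
import pytest

from snfchoice.clogit import ConditionalLogit, fit_by_quintile
from snfchoice.synthetic import simulate_choice_data
from tests.conftest import make_choice_table


def brute_loglik(df, params, names, weights=None):
    """Direct softmax enumeration with explicit exponentials."""
    ll = 0.0
    for g, grp in df.groupby("discharge_id", sort=True):
        v = np.zeros(len(grp))
        for name, b in zip(names, params):
            if name.startswith("oud_x_"):
                v += b * grp[name[6:]].to_numpy() * grp["oud"].to_numpy()
            else:
                v += b * grp[name].to_numpy()
        p = np.exp(v) / np.exp(v).sum()
        w = 1.0 if weights is None else grp[weights].iloc[0]
        ll += w * np.log(p[grp["choice"].to_numpy() == 1][0])
    return ll


@pytest.fixture()
def hand_fixture():
    """3 sets x 3 alternatives, two attributes, mixed exposure."""
    sets = [
        ([[1.0, 0.2], [0.0, 1.5], [0.0, -0.3]], 0),
        ([[0.0, 2.0], [1.0, -1.0], [1.0, 0.5]], 2),
        ([[1.0, 0.0], [0.0, 0.0], [1.0, 1.0]], 1),
    ]
    return make_choice_table(sets, oud=[0, 1, 1], state=["s0", "s1", "s0"])


class TestLikelihood:
    def test_single_alternative_set_contributes_zero(self):
        df = make_choice_table([([[1.0]], 0), ([[0.5], [1.5], [0.2]], 1)])
        m = ConditionalLogit.from_choice_table(
            df, attributes=["x0"], interactions=False, cluster_col=None
        )
        b = np.array([0.7])
        only_big = df[df["discharge_id"] == "d1"]
        m2 = ConditionalLogit.from_choice_table(
            only_big, attributes=["x0"], interactions=False, cluster_col=None
        )
        assert m.loglik(b) == pytest.approx(m2.loglik(b), abs=1e-12)

    def test_zero_params_give_uniform_loglik(self):
        df = make_choice_table([(np.random.default_rng(0).normal(size=(4, 2)), 2)])
        m = ConditionalLogit.from_choice_table(
            df, attributes=["x0", "x1"], interactions=False, cluster_col=None
        )
        assert m.loglik(np.zeros(2)) == pytest.approx(np.log(0.25), abs=1e-12)

    def test_loglik_matches_brute_force_enumeration(self, hand_fixture):
        m = ConditionalLogit.from_choice_table(hand_fixture, attributes=["x0", "x1"])
        params = np.array([0.8, -0.4, 0.3, 0.9])
        want = brute_loglik(hand_fixture, params, m.names)
        assert m.loglik(params) == pytest.approx(want, abs=1e-10)

    def test_gradient_matches_central_finite_differences(self, hand_fixture):
        m = ConditionalLogit.from_choice_table(hand_fixture, attributes=["x0", "x1"])
        params = np.array([0.8, -0.4, 0.3, 0.9])
        g = m.score(params)
        h = 1e-6
        for j in range(len(params)):
            e = np.zeros_like(params)
            e[j] = h
            fd = (m.loglik(params + e) - m.loglik(params - e)) / (2 * h)
            assert g[j] == pytest.approx(fd, abs=1e-6)

    def test_probabilities_sum_to_one_within_sets(self, hand_fixture):
        m = ConditionalLogit.from_choice_table(hand_fixture, attributes=["x0", "x1"])
        res = m.fit()
        p = res.predict_proba()
        sums = np.add.reduceat(p, m._starts)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_location_invariance_within_sets(self, hand_fixture):
        """Adding a per-set constant to an attribute shifts every
        alternative's utility equally and leaves the likelihood fixed."""
        m = ConditionalLogit.from_choice_table(hand_fixture, attributes=["x0", "x1"])
        shifted = hand_fixture.copy()
        shift = shifted["discharge_id"].map({"d0": 3.0, "d1": -1.5, "d2": 0.7})
        shifted["x1"] = shifted["x1"] + shift
        m2 = ConditionalLogit.from_choice_table(shifted, attributes=["x0", "x1"])
        params = np.array([0.8, -0.4, 0.3, 0.9])
        assert m.loglik(params) == pytest.approx(m2.loglik(params), abs=1e-10)

    def test_bad_choice_counts_raise(self):
        df = make_choice_table([([[1.0], [0.0]], 0)])
        two = df.copy()
        two["choice"] = 1
        with pytest.raises(ValueError, match="chosen rows"):
            ConditionalLogit.from_choice_table(two, attributes=["x0"], interactions=False)


class TestFit:
    def test_row_order_invariance(self):
        df = simulate_choice_data(300, 4, {"preferred": 0.9, "dist_home_km": -0.1}, seed=1)
        a = ConditionalLogit.from_choice_table(df).fit()
        b = ConditionalLogit.from_choice_table(
            df.sample(frac=1, random_state=7).reset_index(drop=True)
        ).fit()
        assert np.allclose(a.params, b.params, atol=1e-8)
        assert np.allclose(a.bse, b.bse, atol=1e-8)

    def test_duplication_with_halved_weights_is_invariant(self):
        df = simulate_choice_data(200, 4, {"preferred": 0.9, "dist_home_km": -0.1}, seed=2)
        a = ConditionalLogit.from_choice_table(df).fit()
        dup = df.copy()
        dup["discharge_id"] = dup["discharge_id"] + 10_000
        both = pd.concat([df, dup], ignore_index=True)
        both["weight"] = 0.5
        b = ConditionalLogit.from_choice_table(both, weight_col="weight").fit()
        assert np.allclose(a.params, b.params, atol=1e-7)
        assert b.loglik == pytest.approx(a.loglik, abs=1e-6)

    def test_alternative_invariant_attribute_unidentified(self):
        df = make_choice_table(
            [([[1.0, 0.3], [1.0, 0.9]], 0), ([[0.0, 0.1], [0.0, 0.8]], 1)]
        )
        with pytest.raises(ValueError, match="never vary within any choice set"):
            ConditionalLogit.from_choice_table(df, attributes=["x0", "x1"], interactions=False)

    def test_matches_statsmodels_conditional_logit(self):
        """Independent cross-check against the established implementation."""
        from statsmodels.discrete.conditional_models import ConditionalLogit as SMCL

        df = simulate_choice_data(400, 4, {"preferred": 0.8, "dist_home_km": -0.1}, seed=3)
        mine = ConditionalLogit.from_choice_table(
            df, attributes=["preferred", "dist_home_km"], interactions=False
        ).fit()
        sm_fit = SMCL(
            df["choice"].to_numpy(),
            df[["preferred", "dist_home_km"]].to_numpy(),
            groups=df["discharge_id"].to_numpy(),
        ).fit(disp=0)
        assert np.allclose(mine.params.to_numpy(), np.asarray(sm_fit.params), atol=1e-4)

    def test_convergence_record(self):
        df = simulate_choice_data(200, 5, {"preferred": 1.0, "star_rating": 0.2}, seed=4)
        res = ConditionalLogit.from_choice_table(df).fit()
        assert res.converged
        assert res.grad_norm < 1e-8
        assert res.n_choice_sets == 200
        assert res.n_alternatives == 1000
        cov = res.cov.to_numpy()
        assert np.allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) > -1e-10)


class TestClusterCovariance:
    def test_singleton_clusters_equal_heteroskedastic_sandwich(self):
        """With one cluster per choice set the cluster estimator reduces
        to the plain robust sandwich; verified against a test-side
        enumeration of per-set scores."""
        df = simulate_choice_data(150, 3, {"preferred": 0.7, "dist_home_km": -0.08}, seed=5)
        df["state_id"] = df["discharge_id"]  # one cluster per set
        res = ConditionalLogit.from_choice_table(df).fit()

        m = res.model
        b_std = res._params_std
        Xs = m._Xs
        p = m._probabilities(b_std, Xs)
        scores = []
        for g in range(m.n_sets):
            lo = m._starts[g]
            hi = m._starts[g + 1] if g + 1 < m.n_sets else len(p)
            xb = (p[lo:hi, None] * Xs[lo:hi]).sum(axis=0)
            chosen = lo + np.argmax(m.choice[lo:hi])
            scores.append(Xs[chosen] - xb)
        S = np.asarray(scores)
        G = m.n_sets
        meat = (S.T @ S) * G / (G - 1)
        _, _, H = m._ll_core(b_std, Xs)
        bread = np.linalg.inv(-H)
        want = bread @ meat @ bread
        D = np.diag(1.0 / m._scale)
        want = D @ want @ D
        assert np.allclose(res.cov.to_numpy(), want, atol=1e-10)

    def test_cluster_se_differ_from_unclustered_with_real_clusters(self):
        df = simulate_choice_data(
            400, 4, {"preferred": 0.8}, {"preferred": -0.3}, n_clusters=8, seed=6
        )
        clustered = ConditionalLogit.from_choice_table(df).fit()
        df2 = df.copy()
        df2["state_id"] = df2["discharge_id"]
        unclustered = ConditionalLogit.from_choice_table(df2).fit()
        assert clustered.n_clusters == 8
        assert not np.allclose(clustered.bse, unclustered.bse)


class TestQuintileFits:
    def test_identical_labels_rejected(self):
        df = simulate_choice_data(100, 3, {"preferred": 0.5}, seed=7)
        labels = pd.Series(1, index=pd.unique(df["discharge_id"]))
        with pytest.raises(ValueError, match="multiple quintile strata"):
            fit_by_quintile(df, labels)

    def test_small_stratum_skipped_with_warning(self):
        df = simulate_choice_data(120, 3, {"preferred": 0.5}, seed=8)
        ids = pd.unique(df["discharge_id"])
        labels = pd.Series(np.where(np.arange(len(ids)) < 110, 1, 2), index=ids)
        with pytest.warns(UserWarning, match="fit skipped"):
            fits = fit_by_quintile(df, labels, min_choice_sets=50)
        assert list(fits) == [1]

    def test_disjoint_strata_fit_independently(self):
        df = simulate_choice_data(300, 3, {"preferred": 0.8, "star_rating": 0.1}, seed=9)
        ids = pd.unique(df["discharge_id"])
        labels = pd.Series(np.repeat([1, 2, 3], 100), index=ids)
        fits = fit_by_quintile(df, labels, min_choice_sets=50)
        assert set(fits) == {1, 2, 3}
        solo = ConditionalLogit.from_choice_table(
            df[df["discharge_id"].map(labels) == 2]
        ).fit()
        assert np.allclose(fits[2].params, solo.params, atol=1e-10)
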