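"""GLMM tree: instability tests, split search, mixed fit, prediction."""

import itertools
import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logit

from periotree.mixedlm import fit_random_intercept, marginal_leaf_probability
from periotree.selection import DEFAULT_VARIABLE_LEVELS
from periotree.simulate import SimConfig, generate
from periotree.tree import (
    GLMMTreeClassifier,
    _binomial_deviance,
    choose_split,
    model_from_json,
    model_to_json,
    node_intercept,
)
from periotree.tree import test_instability as instability_p

VARS = list(DEFAULT_VARIABLE_LEVELS)


def _merged(cohort):
    return cohort.merged()


class TestInstability:
    def test_two_level_statistic_equals_squared_standardised_difference(self):
        # 10-row fixture: chi-squared(1) statistic must equal the square of
        # the standardised two-sample residual-sum difference
        y = np.array([1, 0, 0, 1, 0, 0, 0, 1, 0, 0], dtype=float)
        x = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        beta = node_intercept(y, np.zeros(10))
        p_hat = np.full(10, expit(beta))
        p_pkg = instability_p(y, p_hat, x, "nominal", levels=["a", "b"])
        r = y - p_hat
        w = p_hat * (1 - p_hat)
        s1 = r[x == 0].sum()
        w1, w2 = w[x == 0].sum(), w[x == 1].sum()
        z2 = s1**2 * (w1 + w2) / (w1 * w2)
        assert p_pkg == pytest.approx(stats.chi2.sf(z2, 1), rel=1e-10)

    def test_null_p_values_approximately_uniform(self):
        """Independent 3-level covariate: p-values are ~Uniform(0,1)."""
        rng = np.random.default_rng(77)
        pvals = []
        for _ in range(400):
            n = 600
            y = (rng.random(n) < 0.15).astype(float)
            if y.sum() in (0, n):
                continue
            x = rng.integers(0, 3, size=n)
            beta = node_intercept(y, np.zeros(n))
            p_hat = np.full(n, expit(beta))
            pvals.append(instability_p(y, p_hat, x, "nominal", levels=list("abc")))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_perfect_separation_tiny_p(self):
        y = np.array([1.0] * 40 + [0.0] * 40)
        x = np.array([0] * 40 + [1] * 40)
        p_hat = np.full(80, 0.5)
        assert instability_p(y, p_hat, x, "nominal", levels=["a", "b"]) < 1e-6

    def test_single_level_returns_one(self):
        y = np.array([0.0, 1.0, 0.0, 1.0])
        p_hat = np.full(4, 0.5)
        assert instability_p(y, p_hat, np.zeros(4, dtype=int), "nominal", levels=["a"]) == 1.0
        assert instability_p(y, p_hat, np.full(4, 2.0), "numeric") == 1.0

    def test_ordinal_cusum_detects_monotone_shift(self):
        rng = np.random.default_rng(5)
        n = 800
        x = rng.integers(0, 4, size=n)
        y = (rng.random(n) < np.array([0.05, 0.05, 0.05, 0.4])[x]).astype(float)
        beta = node_intercept(y, np.zeros(n))
        p_hat = np.full(n, expit(beta))
        assert instability_p(y, p_hat, x, "ordinal") < 1e-8


class TestChooseSplit:
    def test_table_collapsed_counts_pick_gt60_boundary(self):
        """Exhaustive-deviance oracle on the exact collapsed bone-loss counts:
        the optimal ordinal threshold separates >60% from the rest."""
        levels = ["<=20", "21-40", "41-60", ">60"]
        counts, lost = [700, 1078, 531, 219], [21, 44, 47, 49]
        x = np.repeat(np.arange(4), counts)
        y = np.concatenate([
            np.r_[np.ones(l), np.zeros(n - l)] for n, l in zip(counts, lost)
        ])
        off = np.zeros_like(y)
        rule, mask = choose_split(y, off, x, "ordinal", min_node_size=50, levels=levels)
        assert rule.left_levels == ("<=20", "21-40", "41-60")
        # independent oracle: enumerate all three admissible thresholds
        devs = []
        for t in range(3):
            m = x <= t
            devs.append(
                _binomial_deviance(y[m], off[m], node_intercept(y[m], off[m]))
                + _binomial_deviance(y[~m], off[~m], node_intercept(y[~m], off[~m]))
            )
        assert int(np.argmin(devs)) == 2

    def test_two_level_variable_only_one_split(self):
        y = np.r_[np.ones(30), np.zeros(170)]
        x = np.r_[np.zeros(100, dtype=int), np.ones(100, dtype=int)]
        rule, mask = choose_split(y, np.zeros(200), x, "nominal", min_node_size=50, levels=["a", "b"])
        assert set(rule.left_levels) in ({"a"}, {"b"})
        assert mask.sum() == 100

    def test_min_node_size_boundary_returns_none(self):
        y = np.r_[np.ones(5), np.zeros(55)]
        x = np.r_[np.zeros(10, dtype=int), np.ones(50, dtype=int)]
        assert choose_split(y, np.zeros(60), x, "nominal", min_node_size=20, levels=["a", "b"]) is None

    def test_numeric_threshold_is_midpoint(self):
        rng = np.random.default_rng(3)
        x = np.r_[rng.uniform(0, 1, 100), rng.uniform(2, 3, 100)]
        y = np.r_[(rng.random(100) < 0.05), (rng.random(100) < 0.5)].astype(float)
        rule, _ = choose_split(y, np.zeros(200), x, "numeric", min_node_size=30)
        assert 1.0 < rule.threshold < 2.0


class TestMixedFit:
    def test_sigma_zero_closed_form_leaf_logits(self):
        rng = np.random.default_rng(8)
        leaf = rng.integers(0, 3, size=600)
        y = (rng.random(600) < np.array([0.1, 0.3, 0.6])[leaf]).astype(float)
        pat = np.arange(600) // 10
        fit = fit_random_intercept(y, leaf, pat, sigma_fixed=0.0)
        for l in range(3):
            assert fit.betas[l] == pytest.approx(logit(y[leaf == l].mean()), abs=1e-10)
        assert fit.sigma_b == 0.0
        assert np.all(fit.blups == 0.0)

    def test_quadrature_refinement_self_consistency(self):
        rng = np.random.default_rng(42)
        P, T = 300, 20
        b = rng.normal(0, 1.0, P)
        pat = np.repeat(np.arange(P), T)
        y = (rng.random(P * T) < expit(logit(0.15) + b[pat])).astype(float)
        leaf = np.zeros(P * T, dtype=int)
        f15 = fit_random_intercept(y, leaf, pat, quadrature_points=15)
        f31 = fit_random_intercept(y, leaf, pat, quadrature_points=31)
        assert abs(f15.loglik - f31.loglik) < 1e-3
        assert f15.sigma_b == pytest.approx(f31.sigma_b, abs=1e-3)

    def test_empty_leaf_rejected(self):
        y = np.array([0.0, 1.0, 0.0, 1.0])
        with pytest.raises(ValueError, match="leaf"):
            fit_random_intercept(y, np.zeros(4, dtype=int), np.arange(4), n_leaves=2)

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        pat = np.repeat(np.arange(50), 8)
        y = (rng.random(400) < 0.2).astype(float)
        leaf = (np.arange(400) % 2).astype(int)
        a = fit_random_intercept(y, leaf, pat)
        b = fit_random_intercept(y, leaf, pat)
        assert np.array_equal(a.betas, b.betas) and a.sigma_b == b.sigma_b


class TestPrediction:
    def test_marginal_equals_conditional_at_sigma_zero(self):
        assert marginal_leaf_probability(-2.0, 0.0) == pytest.approx(expit(-2.0), abs=1e-12)

    def test_symmetry_beta_zero(self):
        assert marginal_leaf_probability(0.0, 2.0) == pytest.approx(0.5, abs=1e-10)

    def test_monte_carlo_integration_oracle(self):
        rng = np.random.default_rng(9)
        b = rng.normal(0, 0.8, size=1_000_000)
        mc = expit(-1.3 + b).mean()
        assert marginal_leaf_probability(-1.3, 0.8) == pytest.approx(mc, abs=1e-3)

    def test_monotone_in_beta(self):
        betas = np.linspace(-4, 4, 30)
        p = marginal_leaf_probability(betas, 1.2)
        assert np.all(np.diff(p) > 0)


class TestEstimator:
    def test_recovers_single_binary_effect(self):
        """Rates 0.05 vs 0.30 on one covariate, no clustering, 1000 patients:
        exactly one split, on that covariate, with leaf rates near truth."""
        cfg = SimConfig(
            n_patients=1000, seed=70, null_rate=0.05, sigma_b=0.0,
            p_bone_loss_missing=0.0,
            extra_effects={"jaw": {"mandible": float(logit(0.30) - logit(0.05))}},
        )
        m = _merged(generate(cfg))
        est = GLMMTreeClassifier(sigma_fixed=0.0)
        est.fit(m[VARS], m["lost_by_T2"].to_numpy(), groups=m["patient_id"].to_numpy())
        assert est.partitioning_variables_ == ["jaw"]
        assert est.n_leaves_ == 2
        rates = sorted(lf.n_lost / lf.n_teeth for lf in est.root_.leaves())
        n = m.shape[0]
        assert rates[0] == pytest.approx(0.05, abs=2 * np.sqrt(0.05 * 0.95 / (n / 2)))
        assert rates[1] == pytest.approx(0.30, abs=2 * np.sqrt(0.30 * 0.70 / (n / 2)))

    def test_one_split_equals_two_group_logistic_closed_form(self):
        """Oracle equivalence: sigma fixed at 0, the fitted leaf betas are
        the closed-form logits of the two group rates."""
        cfg = SimConfig(
            n_patients=300, seed=71, null_rate=0.05, sigma_b=0.0, p_bone_loss_missing=0.0,
            extra_effects={"jaw": {"mandible": 2.0}},
        )
        m = _merged(generate(cfg))
        est = GLMMTreeClassifier(sigma_fixed=0.0)
        est.fit(m[VARS], m["lost_by_T2"].to_numpy(), groups=m["patient_id"].to_numpy())
        for leaf in est.root_.leaves():
            assert leaf.beta == pytest.approx(logit(leaf.n_lost / leaf.n_teeth), abs=1e-9)

    def test_all_outcomes_identical_returns_root_model(self):
        m = _merged(generate(SimConfig(n_patients=10, seed=72, p_bone_loss_missing=0.0)))
        y = np.zeros(len(m))
        est = GLMMTreeClassifier()
        with pytest.warns(UserWarning, match="identical"):
            est.fit(m[VARS], y, groups=m["patient_id"].to_numpy())
        assert est.n_leaves_ == 1
        assert est.root_.is_leaf

    def test_leaves_partition_categorical_grid(self, default_cohort):
        from periotree.cohort import (
            ABUTMENT_LEVELS, BONE_LOSS_CAT_LEVELS, FURCATION_LEVELS, YESNO_LEVELS,
        )

        cc, _ = __import__("periotree").complete_case_filter(default_cohort)
        m = cc.merged()
        est = GLMMTreeClassifier()
        est.fit(m[VARS], m["lost_by_T2"].to_numpy(), groups=m["patient_id"].to_numpy())
        grid = itertools.product(
            BONE_LOSS_CAT_LEVELS, FURCATION_LEVELS, ABUTMENT_LEVELS, (40.0, 70.0), YESNO_LEVELS
        )
        leaf_ids = {lf.node_id for lf in est.root_.leaves()}
        for bl, furc, abut, age, diab in grid:
            row = {
                "bone_loss_cat": bl, "furcation_class": furc, "abutment": abut,
                "age": age, "diabetes": diab, "jaw": "maxilla",
                "tooth_type": "premolar", "infrabony": "shallow",
                "gender": "female", "smoking": "never",
            }
            assert est.root_.route(row).node_id in leaf_ids

    def test_serialization_round_trip_reproduces_predictions_bitwise(self, default_cohort):
        cc, _ = __import__("periotree").complete_case_filter(default_cohort)
        m = cc.merged()
        est = GLMMTreeClassifier()
        est.fit(m[VARS], m["lost_by_T2"].to_numpy(), groups=m["patient_id"].to_numpy())
        doc = model_to_json(est)
        back = model_from_json(doc)
        p0 = est.predict_tooth_proba(m[VARS], mode="marginal")
        p1 = back.predict_tooth_proba(m[VARS], mode="marginal")
        assert np.array_equal(p0, p1)
        c0 = est.predict_tooth_proba(m[VARS], groups=m["patient_id"].to_numpy(), mode="conditional")
        c1 = back.predict_tooth_proba(m[VARS], groups=m["patient_id"].to_numpy(), mode="conditional")
        assert np.array_equal(c0, c1)
        assert model_to_json(back) == doc

    def test_refit_deterministic(self):
        m = _merged(generate(SimConfig(n_patients=60, seed=73, p_bone_loss_missing=0.0)))
        kw = dict(groups=m["patient_id"].to_numpy())
        a = GLMMTreeClassifier().fit(m[VARS], m["lost_by_T2"].to_numpy(), **kw)
        b = GLMMTreeClassifier().fit(m[VARS], m["lost_by_T2"].to_numpy(), **kw)
        assert model_to_json(a) == model_to_json(b)

    def test_conditional_uses_blup_marginal_integrates(self):
        m = _merged(generate(SimConfig(n_patients=80, seed=74, sigma_b=1.0, p_bone_loss_missing=0.0)))
        est = GLMMTreeClassifier()
        est.fit(m[VARS], m["lost_by_T2"].to_numpy(), groups=m["patient_id"].to_numpy())
        sub = m.head(40)
        marg = est.predict_tooth_proba(sub[VARS], mode="marginal")
        cond = est.predict_tooth_proba(sub[VARS], groups=sub["patient_id"].to_numpy(), mode="conditional")
        assert not np.allclose(marg, cond)  # BLUPs shift conditional predictions
        # unseen patients fall back to the marginal prediction
        cond_unseen = est.predict_tooth_proba(sub[VARS], groups=np.array(["ZZ"] * 40), mode="conditional")
        assert np.allclose(marg, cond_unseen)

    def test_unknown_level_raises_routing_error(self, default_cohort):
        from periotree.tree import RoutingError

        cc, _ = __import__("periotree").complete_case_filter(default_cohort)
        m = cc.merged()
        est = GLMMTreeClassifier()
        est.fit(m[VARS], m["lost_by_T2"].to_numpy(), groups=m["patient_id"].to_numpy())
        bad = m[VARS].head(3).copy()
        bad.loc[bad.index[0], est.partitioning_variables_[0]] = np.nan
        with pytest.raises((RoutingError, ValueError)):
            est.predict_tooth_proba(bad)

    def test_requires_dataframe(self):
        with pytest.raises(TypeError):
            GLMMTreeClassifier().fit(np.zeros((10, 2)), np.zeros(10))

    def test_sklearn_get_set_params_clone(self):
        from sklearn.base import clone

        est = GLMMTreeClassifier(alpha=0.01, min_node_size=30)
        est2 = clone(est)
        assert est2.get_params()["alpha"] == 0.01
        est2.set_params(max_depth=2)
        assert est2.max_depth == 2
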