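import numpy as np
import pytest
import statsmodels.api as sm

from conftest import make_binary_outcome
from pathscore.scores import (
    ComponentOR,
    combine_scores,
    common_score,
    component_or,
    determine_risk_alleles,
    lasso_select_common,
    rare_score,
    _l1_fit,
    _COV_SCALE,
)


class TestRareScore:
    def test_count_and_proportion(self):
        G = np.array([[1.0, 0.0, 2.0]])
        assert rare_score(G, "count")[0] == 3
        assert rare_score(G, "proportion")[0] == pytest.approx(0.5)

    def test_all_zero(self):
        G = np.zeros((4, 3))
        np.testing.assert_array_equal(rare_score(G, "count"), 0.0)

    def test_missing_dosage_convention(self):
        G = np.array([[1.0, np.nan, 2.0]])
        assert rare_score(G, "count")[0] == 3
        assert rare_score(G, "proportion")[0] == pytest.approx(3 / 4)

    def test_no_rare_snps_gives_zero_scores(self):
        assert rare_score(np.empty((5, 0)), "count").tolist() == [0.0] * 5

    def test_permutation_and_additivity(self, rng):
        G = rng.binomial(2, 0.05, size=(50, 6)).astype(float)
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            rare_score(G, "count"), rare_score(G[:, perm], "count")
        )
        np.testing.assert_allclose(
            rare_score(G, "count"),
            rare_score(G[:, :3], "count") + rare_score(G[:, 3:], "count"),
        )


class TestCommonScore:
    def test_minor_risk_sum(self):
        G = np.array([[1.0, 2.0]])
        d = {"a": "minor_is_risk", "b": "minor_is_risk"}
        assert common_score(G, ["a", "b"], d)[0] == 3

    def test_direction_flip(self):
        G = np.array([[1.0, 2.0]])
        d = {"a": "minor_is_risk", "b": "major_is_risk"}
        assert common_score(G, ["a", "b"], d)[0] == 1

    def test_all_major_risk_maximum(self):
        G = np.zeros((1, 3))
        d = {s: "major_is_risk" for s in "abc"}
        assert common_score(G, list("abc"), d)[0] == 6

    def test_recode_invariance(self, rng):
        """Recoding dosage d -> 2-d with a direction flip leaves the
        score unchanged."""
        G = rng.binomial(2, 0.3, size=(30, 2)).astype(float)
        d1 = {"a": "minor_is_risk", "b": "major_is_risk"}
        d2 = {"a": "major_is_risk", "b": "major_is_risk"}
        G2 = G.copy()
        G2[:, 0] = 2 - G2[:, 0]
        np.testing.assert_allclose(
            common_score(G, ["a", "b"], d1), common_score(G2, ["a", "b"], d2)
        )


class TestRiskAlleles:
    def test_risk_direction_follows_or(self):
        x, y = make_binary_outcome(
            dict(exposed_case=30, exposed_ctrl=20, unexposed_case=20,
                 unexposed_ctrl=30)
        )
        d = determine_risk_alleles(x.reshape(-1, 1), ["rs1"], y)
        assert d["rs1"] == "minor_is_risk"
        d = determine_risk_alleles((1 - x).reshape(-1, 1), ["rs1"], y)
        assert d["rs1"] == "major_is_risk"

    def test_degenerate_defaults_to_minor(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        d = determine_risk_alleles(np.zeros((20, 1)), ["rs1"], y)
        assert d["rs1"] == "minor_is_risk"


class TestComponentOR:
    def test_cross_product_value(self):
        x, y = make_binary_outcome(
            dict(exposed_case=30, exposed_ctrl=20, unexposed_case=20,
                 unexposed_ctrl=30)
        )
        comp = component_or(x, y)
        assert comp.usable
        assert comp.odds_ratio == pytest.approx(2.25, abs=1e-8)

    def test_null_or_near_one(self, rng):
        n = 10_000
        rs = rng.normal(size=n)
        y = rng.binomial(1, 0.3, size=n).astype(float)
        comp = component_or(rs, y)
        assert 0.85 < comp.odds_ratio < 1.18

    def test_constant_score_flagged(self):
        comp = component_or(np.ones(20), np.r_[np.ones(10), np.zeros(10)])
        assert not comp.usable

    def test_heavy_ties_flagged(self):
        rs = np.zeros(20)
        rs[:2] = 0.0  # median 0, nothing strictly above
        comp = component_or(rs, np.r_[np.ones(10), np.zeros(10)])
        assert not comp.usable


class TestCombine:
    def test_indicator_sum_above_both_medians(self):
        rs_r, rs_c = np.array([5.0]), np.array([4.0])
        out, testable = combine_scores(
            rs_r, rs_c,
            ComponentOR(1.4, 1.0, True), ComponentOR(1.3, 1.0, True),
        )
        assert out[0] == pytest.approx(2.7)

    def test_protective_component_gated_to_zero(self, rng):
        rs_r = rng.normal(size=100)
        rs_c = rng.normal(size=100)
        out, _ = combine_scores(
            rs_r, rs_c,
            ComponentOR(0.8, 0.0, True), ComponentOR(1.3, 0.0, True),
        )
        only_common, _ = combine_scores(
            None, rs_c, None, ComponentOR(1.3, 0.0, True)
        )
        np.testing.assert_allclose(out, only_common)

    def test_below_both_medians_zero(self):
        out, _ = combine_scores(
            np.array([-1.0]), np.array([-1.0]),
            ComponentOR(1.4, 0.0, True), ComponentOR(1.3, 0.0, True),
        )
        assert out[0] == 0.0

    def test_both_gated_untestable(self):
        out, testable = combine_scores(
            np.arange(10.0), np.arange(10.0),
            ComponentOR(0.9, 4.5, True), ComponentOR(0.7, 4.5, True),
        )
        assert not testable
        assert (out == 0).all()

    def test_indicator_mode_at_most_four_values(self, rng):
        rs_r = rng.normal(size=200)
        rs_c = rng.normal(size=200)
        out, _ = combine_scores(
            rs_r, rs_c,
            ComponentOR(1.5, 0.0, True), ComponentOR(1.2, 0.0, True),
        )
        assert len(np.unique(out)) <= 4
        expected = {0.0, 1.5, 1.2, 2.7}
        assert {round(v, 9) for v in np.unique(out)} <= expected

    def test_continuous_mode(self):
        rs_r = np.array([2.0])
        out, _ = combine_scores(
            rs_r, None, ComponentOR(1.5, 0.0, True), None,
            combine_mode="continuous",
        )
        assert out[0] == pytest.approx(3.0)


class TestLasso:
    def _signal_data(self, rng, n=600, p=10, beta=1.0):
        G = rng.binomial(2, 0.3, size=(n, p)).astype(float)
        cov = np.column_stack([rng.normal(size=n),
                               rng.binomial(1, 0.5, n)]).astype(float)
        eta = -0.5 + beta * G[:, 0] + 0.5 * cov[:, 0]
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        return G, cov, y

    def test_strong_signal_selected_null_mostly_not(self, rng):
        G, cov, y = self._signal_data(rng, beta=1.0)
        fit = lasso_select_common(G, [f"rs{j}" for j in range(10)], y, cov)
        assert "rs0" in fit.selected
        assert len(fit.selected) <= 4

    def test_pure_noise_usually_empty(self, rng):
        empties = 0
        for rep in range(10):
            G = rng.binomial(2, 0.3, size=(300, 8)).astype(float)
            y = rng.binomial(1, 0.4, size=300).astype(float)
            cov = rng.normal(size=(300, 2))
            fit = lasso_select_common(G, [f"rs{j}" for j in range(8)], y, cov,
                                      seed=rep)
            empties += fit.n_selected == 0
        assert empties >= 8

    def test_heavy_penalty_empty_light_penalty_full(self, rng):
        """Penalty limits: strongest path knot selects nothing, weakest
        recovers (almost) every informative SNP."""
        G, cov, y = self._signal_data(rng, beta=0.8)
        Xs = (G - G.mean(0)) / G.std(0)
        covs = (cov - cov.mean(0)) / cov.std(0)
        X = np.column_stack([Xs, covs * _COV_SCALE])
        lam_max = float(np.max(np.abs(Xs.T @ (y - y.mean()))))
        heavy = _l1_fit(X, y, C=1.0 / (1.5 * lam_max))
        assert (heavy.coef_[0][:10] == 0).all()
        light = _l1_fit(X, y, C=1e4)
        assert (light.coef_[0][:10] != 0).sum() >= 9

    def test_selection_monotone_along_path(self, rng):
        G, cov, y = self._signal_data(rng, beta=0.8)
        Xs = (G - G.mean(0)) / G.std(0)
        X = np.column_stack([Xs, ((cov - cov.mean(0)) / cov.std(0)) * _COV_SCALE])
        lam_max = float(np.max(np.abs(Xs.T @ (y - y.mean()))))
        sizes = []
        for lam in np.geomspace(lam_max * 1.5, lam_max * 0.01, 15):
            clf = _l1_fit(X, y, C=1.0 / lam)
            sizes.append(int((clf.coef_[0][:10] != 0).sum()))
        assert sizes == sorted(sizes)

    def test_matches_exact_per_parameter_penalty_oracle(self, rng):
        """The covariate up-scaling device reproduces the exact L1 fit
        with unpenalized covariates (statsmodels, per-parameter alpha)."""
        G, cov, y = self._signal_data(rng, n=500, p=8, beta=0.6)
        n, p = G.shape
        Xs = (G - G.mean(0)) / G.std(0)
        covs = (cov - cov.mean(0)) / cov.std(0)
        lam = 20.0
        clf = _l1_fit(np.column_stack([Xs, covs * _COV_SCALE]), y, C=1.0 / lam)
        Xsm = np.column_stack([np.ones(n), Xs, covs])
        alpha = np.r_[0.0, np.full(p, lam), np.zeros(covs.shape[1])]
        res = sm.Logit(y, Xsm).fit_regularized(
            method="l1", alpha=alpha, disp=0, acc=1e-10
        )
        np.testing.assert_allclose(
            clf.coef_[0][:p], np.asarray(res.params)[1 : p + 1], atol=2e-3
        )
        skl_sel = {j for j in range(p) if abs(clf.coef_[0][j]) > 1e-6}
        sm_sel = {j for j in range(p) if abs(res.params[j + 1]) > 1e-6}
        assert skl_sel == sm_sel

    def test_single_class_rejected(self, rng):
        G = rng.binomial(2, 0.3, size=(50, 3)).astype(float)
        with pytest.raises(ValueError, match="single class"):
            lasso_select_common(G, ["a", "b", "c"], np.ones(50),
                                np.zeros((50, 0)))

    def test_causal_common_selected_across_reps(self):
        """A clearly causal common SNP (log-OR 0.7, MAF 0.3) among 20
        null SNPs is selected in nearly every replicate."""
        hits = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(500 + rep)
            n = 2000
            G = rng.binomial(2, 0.3, size=(n, 21)).astype(float)
            cov = rng.normal(size=(n, 2))
            eta = -0.5 + 0.7 * G[:, 0]
            y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
            fit = lasso_select_common(
                G, [f"rs{j}" for j in range(21)], y, cov, seed=1
            )
            hits += "rs0" in fit.selected
        assert hits >= int(0.9 * reps)
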