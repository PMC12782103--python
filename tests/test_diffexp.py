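import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from panomix.data import OmicsMatrix, ResponseSpec
from panomix.diffexp import (
    Contrast,
    ModerationPrior,
    benjamini_hochberg,
    de_moderated,
    de_ols,
    de_voom,
    fit_moderation_prior,
    trigamma_inverse,
    volcano_table,
    voom_weights,
)
from panomix.simulate import SimSpec, simulate_study

RESP = ResponseSpec("group", "b", ("b", "a"))
AB = Contrast("a", "b")


def _two_group(Y, na, nb):
    labels = np.array(["a"] * na + ["b"] * nb)
    ds = OmicsMatrix(
        "x", pd.DataFrame(Y, columns=[f"g{i}" for i in range(Y.shape[1])]), False
    )
    return ds, labels


class TestBenjaminiHochberg:
    def test_stepup_hand_example(self):
        adj = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg(np.array([0.3]))[0] == 0.3

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            ours = benjamini_hochberg(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, theirs, atol=1e-12)

    def test_properties(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=100)
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p) and np.all(adj <= 1)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            benjamini_hochberg(np.array([0.5, 1.5]))


class TestDeOLS:
    def test_equal_means_null(self):
        Y = np.tile([[1.0], [1.0], [2.0], [1.0], [1.0], [2.0]], (1, 1))
        ds, labels = _two_group(Y, 3, 3)
        t = de_ols(ds, RESP, labels, AB).table
        assert t["t"].iloc[0] == 0.0 and t["p"].iloc[0] == 1.0

    def test_effect_orientation_a_minus_b(self):
        Y = np.array([[1.0], [1.0], [1.1], [0.0], [0.0], [0.0]])
        ds, labels = _two_group(Y, 3, 3)
        t = de_ols(ds, RESP, labels, AB).table
        assert t["log2fc"].iloc[0] == pytest.approx(31.0 / 30.0, rel=1e-12)
        flipped = de_ols(ds, RESP, labels, Contrast("b", "a")).table
        assert flipped["log2fc"].iloc[0] == pytest.approx(-31.0 / 30.0, rel=1e-12)

    def test_matches_pooled_t_and_anova_oracles(self):
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((14, 30))
        ds, labels = _two_group(Y, 6, 8)
        t = de_ols(ds, RESP, labels, AB).table
        for j in range(30):
            t_ref, p_ref = stats.ttest_ind(Y[:6, j], Y[6:, j], equal_var=True)
            assert t["t"].iloc[j] == pytest.approx(t_ref, abs=1e-10)
            assert t["p"].iloc[j] == pytest.approx(p_ref, abs=1e-10)
            _, p_anova = stats.f_oneway(Y[:6, j], Y[6:, j])
            assert t["p"].iloc[j] == pytest.approx(p_anova, abs=1e-10)

    def test_multilevel_residual_df_from_full_model(self):
        rng = np.random.default_rng(3)
        resp = ResponseSpec("g", "c", ("c", "a", "b"))
        labels = np.repeat(["a", "b", "c"], 5)
        Y = rng.standard_normal((15, 4))
        ds = OmicsMatrix("x", pd.DataFrame(Y, columns=list("wxyz")), False)
        t = de_ols(ds, resp, labels, Contrast("a", "c")).table
        assert (t["df"] == 12).all()  # n - g = 15 - 3

    def test_small_group_rejected(self):
        Y = np.ones((4, 3))
        ds, labels = _two_group(Y, 1, 3)
        with pytest.raises(ValueError, match="fewer than 2"):
            de_ols(ds, RESP, labels, AB)


class TestModerationPrior:
    def test_equal_variances_give_infinite_d0(self):
        prior = fit_moderation_prior(np.full(50, 2.5), d=6)
        assert np.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(2.5, rel=1e-12)

    def test_parameter_recovery_scaled_inv_chisq(self):
        rng = np.random.default_rng(7)
        d0, s0_sq, d = 4.0, 2.0, 6
        true_var = s0_sq * d0 / rng.chisquare(d0, size=5000)
        s_sq = true_var * rng.chisquare(d, size=5000) / d
        prior = fit_moderation_prior(s_sq, d)
        assert 3.2 <= prior.d0 <= 4.8
        assert 1.8 <= prior.s0_sq <= 2.2

    def test_trigamma_inverse_against_bisection(self):
        for y in [0.01, 0.1, 0.5, 1.0, 2.0, 10.0]:
            lo, hi = 1e-6, 1e8
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                if special.polygamma(1, mid) > y:
                    lo = mid
                else:
                    hi = mid
            assert trigamma_inverse(y) == pytest.approx(0.5 * (lo + hi), abs=1e-8)

    def test_posterior_variance_formula(self):
        prior = ModerationPrior(d0=4.0, s0_sq=1.0)
        assert prior.posterior_variance(np.array([2.0]), d=4)[0] == pytest.approx(1.5)

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            ModerationPrior(d0=0.0, s0_sq=1.0)
        with pytest.raises(ValueError):
            ModerationPrior(d0=1.0, s0_sq=0.0)


class TestDeModerated:
    def test_infinite_d0_is_z_statistic(self):
        rng = np.random.default_rng(4)
        Y = rng.standard_normal((12, 40))
        ds, labels = _two_group(Y, 6, 6)
        prior = ModerationPrior(d0=np.inf, s0_sq=1.0)
        t = de_moderated(ds, RESP, labels, AB, prior=prior).table
        v_c = 1 / 6 + 1 / 6
        expected_t = (Y[:6].mean(0) - Y[6:].mean(0)) / np.sqrt(1.0 * v_c)
        assert np.allclose(t["t"], expected_t, atol=1e-10)
        assert np.allclose(t["p"], 2 * stats.norm.sf(np.abs(expected_t)), atol=1e-12)

    def test_small_d0_limit_approaches_ols(self):
        rng = np.random.default_rng(5)
        Y = rng.standard_normal((10, 20))
        ds, labels = _two_group(Y, 5, 5)
        ols_t = de_ols(ds, RESP, labels, AB).table["t"].to_numpy()
        s_sq = None
        for d0 in [1e-4, 1e-6]:
            prior = ModerationPrior(d0=d0, s0_sq=5.0)
            mod_t = de_moderated(ds, RESP, labels, AB, prior=prior).table["t"].to_numpy()
            assert np.allclose(mod_t, ols_t, rtol=1e-3)

    def test_null_type_one_error_near_nominal(self):
        rng = np.random.default_rng(6)
        Y = rng.standard_normal((10, 2000))
        ds, labels = _two_group(Y, 5, 5)
        t = de_moderated(ds, RESP, labels, AB).table
        frac = (t["p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.015)

    def test_same_ordering_as_ols_under_equal_variances(self):
        """With identical residual patterns the three statistics agree in rank."""
        rng = np.random.default_rng(8)
        base_resid = rng.standard_normal(12)
        base_resid[:6] -= base_resid[:6].mean()
        base_resid[6:] -= base_resid[6:].mean()
        effects = rng.normal(0, 2, 30)
        Y = np.empty((12, 30))
        for j, eff in enumerate(effects):
            Y[:, j] = np.concatenate([np.full(6, eff), np.zeros(6)]) + base_resid
        ds, labels = _two_group(Y, 6, 6)
        ols = de_ols(ds, RESP, labels, AB).table
        mod = de_moderated(ds, RESP, labels, AB).table
        assert list(ols.sort_values("p")["feature"]) == list(
            mod.sort_values("p")["feature"]
        )


class TestVoom:
    def test_identical_count_rows_identical_weights(self, count_study):
        study, _ = count_study
        ds = study.datasets[0]
        frame = ds.frame.copy()
        frame.iloc[:, 1] = frame.iloc[:, 0]
        dup = OmicsMatrix("dup", frame, True)
        _, w = voom_weights(dup, study.response, study.response_labels)
        assert np.allclose(w[:, 0], w[:, 1], atol=1e-12)

    def test_weights_positive_finite_with_bounded_ratio(self, count_study):
        study, _ = count_study
        _, w = voom_weights(study.datasets[0], study.response, study.response_labels)
        assert np.all(w > 0) and np.all(np.isfinite(w))
        assert w.max() / w.min() <= 1e6 + 1e-6

    def test_low_count_decile_gets_lower_weight(self, count_study):
        study, _ = count_study
        ds = study.datasets[0]
        _, w = voom_weights(ds, study.response, study.response_labels)
        mean_count = ds.values.mean(axis=0)
        order = np.argsort(mean_count)
        dec = len(order) // 10
        assert w[:, order[:dec]].mean() < w[:, order[-dec:]].mean()

    def test_all_zero_sample_rejected(self, count_study):
        study, _ = count_study
        frame = study.datasets[0].frame.copy()
        frame.iloc[0] = 0.0
        with pytest.raises(ValueError, match="all-zero"):
            voom_weights(
                OmicsMatrix("z", frame, True), study.response, study.response_labels
            )

    def test_planted_fold_changes_recovered(self, count_study):
        study, truth = count_study
        de = de_voom(
            study.datasets[0], study.response, study.response_labels,
            Contrast("case", "control"), fdr=0.05,
        )
        sig = set(de.significant_features())
        planted = set(truth.planted["omics1"])
        recall = len(sig & planted) / len(planted)
        fdr_obs = len(sig - planted) / max(len(sig), 1)
        assert recall >= 0.6 and fdr_obs <= 0.15

    def test_null_counts_calibrated(self):
        study, _ = simulate_study(
            SimSpec(n=16, p=(1000,), q=(0,), delta=0.0,
                    noise="negative_binomial", seed=19)
        )
        de = de_voom(
            study.datasets[0], study.response, study.response_labels,
            Contrast("case", "control"),
        )
        frac = (de.table["p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.03)


class TestVolcano:
    def test_threshold_monotonicity(self, count_study):
        study, _ = count_study
        de = de_voom(
            study.datasets[0], study.response, study.response_labels,
            Contrast("case", "control"),
        )
        n_sig = [
            volcano_table(de, f)["significant"].sum() for f in [0.2, 0.1, 0.05, 0.01]
        ]
        assert all(a >= b for a, b in zip(n_sig, n_sig[1:]))
        assert volcano_table(de, 1.0)["significant"].sum() == (de.table["adj_p"] < 1).sum()
        assert volcano_table(de, 0.0)["significant"].sum() == 0
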