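import numpy as np
import pandas as pd
import pytest

from panomix.biomarker import (
    CVConfig,
    HyperGrid,
    elastic_net_path,
    ensemble,
    importance,
    panel_intersections,
    panel_network,
    panel_projection,
    repeated_cv_tune,
    roc_curve,
)
from panomix.data import OmicsMatrix, ResponseSpec, Study
from panomix.simulate import SimSpec, simulate_study

SMALL_GRID = HyperGrid(alphas=(0.1, 1.0), n_auto_lambdas=15)
FAST_CV = CVConfig(folds=3, repeats=2, seed=5)


def _standardized(rng, n, p):
    X = rng.standard_normal((n, p))
    return (X - X.mean(0)) / X.std(0)


class TestElasticNetPath:
    def test_large_lambda_zeroes_all_coefficients(self):
        rng = np.random.default_rng(0)
        X = _standardized(rng, 40, 10)
        y = rng.standard_normal(40)
        coefs, b0 = elastic_net_path(X, y, alpha=0.5, lambdas=np.array([1e4]))
        assert np.all(coefs == 0)
        assert b0 == pytest.approx(y.mean())

    @pytest.mark.parametrize("alpha", [0.0, 0.3, 1.0])
    def test_zero_lambda_equals_least_squares(self, alpha):
        rng = np.random.default_rng(1)
        X = _standardized(rng, 50, 5)
        y = X @ rng.normal(0, 1, 5) + 0.1 * rng.standard_normal(50)
        coefs, b0 = elastic_net_path(X, y, alpha=alpha, lambdas=np.array([1e-10]), tol=1e-10)
        beta_ls, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(50), X]), y, rcond=None
        )
        assert np.allclose(coefs[:, 0], beta_ls[1:], atol=1e-6)

    def test_univariate_lasso_is_soft_thresholding(self):
        """alpha=1, one standardized predictor: b = sign(rho)*max(|rho|-lam, 0)."""
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(20, 60))
            x = rng.standard_normal(n)
            x = (x - x.mean()) / x.std()
            y = rng.standard_normal(n) + rng.uniform(-2, 2) * x
            lam = float(rng.uniform(0.01, 1.5))
            rho = float(x @ (y - y.mean())) / n
            expected = np.sign(rho) * max(abs(rho) - lam, 0.0)
            coefs, _ = elastic_net_path(
                x.reshape(-1, 1), y, alpha=1.0, lambdas=np.array([lam]), tol=1e-12
            )
            assert coefs[0, 0] == pytest.approx(expected, abs=1e-8)

    def test_unstandardized_input_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="standardized"):
            elastic_net_path(
                rng.normal(10, 3, (20, 4)), rng.standard_normal(20), 0.5,
                np.array([0.1]),
            )


class TestRepeatedCVTune:
    def test_same_seed_reproduces_everything(self, small_study):
        study, _ = small_study
        ds = study.datasets[0]
        runs = [
            repeated_cv_tune(ds, study.response, study.response_labels,
                             SMALL_GRID, FAST_CV)
            for _ in range(2)
        ]
        assert runs[0].alpha == runs[1].alpha and runs[0].lam == runs[1].lam
        assert np.array_equal(runs[0].oof_scores, runs[1].oof_scores)
        assert runs[0].selected_features == runs[1].selected_features

    def test_pure_noise_auc_near_chance(self):
        study, _ = simulate_study(SimSpec(n=60, p=(200,), q=(0,), delta=0.0, seed=31))
        model = repeated_cv_tune(
            study.datasets[0], study.response, study.response_labels,
            SMALL_GRID, FAST_CV,
        )
        assert 0.35 <= model.cv_mean_metric <= 0.65

    def test_planted_signal_recovered(self):
        study, truth = simulate_study(
            SimSpec(n=80, p=(150,), q=(8,), delta=1.5, seed=33)
        )
        model = repeated_cv_tune(
            study.datasets[0], study.response, study.response_labels,
            SMALL_GRID, CVConfig(folds=5, repeats=3, seed=7),
        )
        planted = set(truth.planted["omics1"])
        assert model.cv_mean_metric >= 0.8
        assert len(set(model.selected_features) & planted) >= len(planted) * 0.6

    def test_standardization_hygiene(self, small_study):
        """Affine rescaling of raw features must not change panel or scores."""
        study, _ = small_study
        ds = study.datasets[0]
        scaled = ds.frame * 37.0 + 11.0
        ds2 = OmicsMatrix(ds.name, scaled, False)
        m1 = repeated_cv_tune(ds, study.response, study.response_labels,
                              SMALL_GRID, FAST_CV)
        m2 = repeated_cv_tune(ds2, study.response, study.response_labels,
                              SMALL_GRID, FAST_CV)
        assert m1.selected_features == m2.selected_features
        assert np.allclose(m1.oof_scores, m2.oof_scores, atol=1e-8)

    def test_folds_exceeding_class_count_rejected(self, small_study):
        study, _ = small_study
        with pytest.raises(ValueError, match="folds"):
            repeated_cv_tune(
                study.datasets[0], study.response, study.response_labels,
                SMALL_GRID, CVConfig(folds=30, repeats=1, seed=1),
            )


class TestROC:
    def test_perfect_separation(self):
        curve = roc_curve(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert curve.auc == 1.0

    def test_constant_scores_chance(self):
        curve = roc_curve(np.full(10, 0.5), np.array([1, 0] * 5))
        assert curve.auc == 0.5

    def test_curve_anchored_and_monotone(self):
        rng = np.random.default_rng(4)
        curve = roc_curve(rng.uniform(size=30), rng.integers(0, 2, 30))
        assert curve.fpr[0] == 0 and curve.tpr[0] == 0
        assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)

    def test_auc_equals_concordance_oracle(self):
        """Trapezoidal AUC equals the rank-sum concordance U/(n1*n0)."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(6, 30))
            scores = np.round(rng.uniform(size=n), 2)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            pos, neg = scores[labels == 1], scores[labels == 0]
            u = sum(
                1.0 if s1 > s0 else 0.5 if s1 == s0 else 0.0
                for s1 in pos for s0 in neg
            )
            assert roc_curve(scores, labels).auc == pytest.approx(
                u / (len(pos) * len(neg)), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(np.array([0.1, 0.2]), np.array([1, 1]))


class TestEnsemble:
    def _dummy_model(self, name, oof, labels, features):
        from panomix.biomarker import PanelModel

        coefs = pd.Series(1.0, index=features)
        return PanelModel(
            dataset_name=name, alpha=1.0, lam=0.1, intercept=0.0,
            coefficients=coefs, selected_features=features,
            oof_scores=np.asarray(oof, float), cv_metric_table=pd.DataFrame(),
            labels01=np.asarray(labels, float),
            sample_index=np.arange(len(labels)), cv_mean_metric=0.5,
        )

    def test_probability_averaging(self):
        labels = np.array([0, 1, 0, 1])
        m1 = self._dummy_model("a", [0.2, 0.9, 0.4, 0.6], labels, ["f1"])
        m2 = self._dummy_model("b", [0.8, 0.7, 0.2, 0.8], labels, ["f2"])
        res = ensemble([m1, m2])
        assert np.allclose(res.ensemble_oof, [0.5, 0.8, 0.3, 0.7])

    def test_identical_members_identical_roc(self):
        labels = np.array([0, 1, 0, 1, 1, 0])
        oof = [0.1, 0.8, 0.3, 0.9, 0.6, 0.2]
        ms = [self._dummy_model(n, oof, labels, ["f"]) for n in ("a", "b")]
        res = ensemble(ms)
        assert res.rocs["ensemble"].auc == res.rocs["a"].auc

    def test_label_mismatch_rejected(self):
        m1 = self._dummy_model("a", [0.2, 0.9], np.array([0, 1]), ["f1"])
        m2 = self._dummy_model("b", [0.8, 0.7], np.array([1, 0]), ["f2"])
        with pytest.raises(ValueError, match="mismatch"):
            ensemble([m1, m2])

    def test_complementary_signals_ensemble_beats_members(self):
        from panomix.simulate import simulate_complementary_study

        study, _ = simulate_complementary_study(n=100, p=60, q=8, delta=2.0, seed=2)
        models = [
            repeated_cv_tune(d, study.response, study.response_labels,
                             SMALL_GRID, CVConfig(folds=5, repeats=2, seed=2))
            for d in study.datasets
        ]
        res = ensemble(models)
        member_aucs = [res.rocs[m.dataset_name].auc for m in models]
        assert res.rocs["ensemble"].auc >= max(member_aucs) - 0.02


class TestPanelSummaries:
    def test_importance_ordering_and_exclusion(self):
        m = TestEnsemble()._dummy_model("a", [0.5], np.array([1.0]), [])
        m.coefficients = pd.Series({"x": 2.0, "y": -3.0, "z": 0.0})
        ranked = importance(m)
        assert list(ranked["feature"]) == ["y", "x"]

    def test_importance_tie_broken_alphabetically(self):
        m = TestEnsemble()._dummy_model("a", [0.5], np.array([1.0]), [])
        m.coefficients = pd.Series({"b": 1.0, "a": -1.0})
        assert list(importance(m)["feature"]) == ["a", "b"]

    def test_intersections_disjoint_and_identical(self):
        mk = TestEnsemble()._dummy_model
        labels = np.array([0.0, 1.0])
        m1 = mk("d1", [0.1, 0.9], labels, ["a", "b"])
        m2 = mk("d2", [0.1, 0.9], labels, ["c"])
        table = panel_intersections([m1, m2]).set_index("panels")["count"]
        assert table["d1"] == 2 and table["d2"] == 1 and table["d1+d2"] == 0
        m3 = mk("d2", [0.1, 0.9], labels, ["a", "b"])
        table2 = panel_intersections([m1, m3]).set_index("panels")["count"]
        assert table2["d1+d2"] == 2 and table2["d1"] == 0

    def test_intersections_partition_the_union(self):
        mk = TestEnsemble()._dummy_model
        rng = np.random.default_rng(6)
        labels = np.array([0.0, 1.0])
        feats = [f"f{i}" for i in range(20)]
        panels = [
            mk(f"d{j}", [0.1, 0.9], labels,
               sorted(rng.choice(feats, rng.integers(1, 15), replace=False)))
            for j in range(3)
        ]
        table = panel_intersections(panels)
        union = set().union(*(p.selected_features for p in panels))
        assert table["count"].sum() == len(union)


class TestPanelProjectionAndNetwork:
    def test_single_feature_projection(self, small_study):
        study, _ = small_study
        feat = study.datasets[0].feature_ids[0]
        pcas, hm = panel_projection(study, {"omics1": [feat]})
        assert pcas["omics1"].k == 1
        assert hm.shape[1] == 1

    def test_projection_deterministic(self, small_study):
        study, truth = small_study
        sel = {"omics1": truth.planted["omics1"], "omics2": truth.planted["omics2"]}
        _, hm1 = panel_projection(study, sel)
        _, hm2 = panel_projection(study, sel)
        assert hm1.equals(hm2)

    def test_missing_feature_rejected(self, small_study):
        study, _ = small_study
        with pytest.raises(ValueError, match="absent"):
            panel_projection(study, {"omics1": ["NOPE"]})

    def test_duplicated_feature_gets_r1_edge(self, small_study):
        study, _ = small_study
        f0 = study.datasets[0].feature_ids[0]
        dup = study.datasets[1].frame.copy()
        dup["COPY"] = study.datasets[0].frame[f0].to_numpy()
        study2 = Study(
            study.metadata,
            [study.datasets[0], OmicsMatrix("omics2", dup, False)],
            study.response,
        )
        edges = panel_network(
            study2, {"omics1": [f0], "omics2": ["COPY"]}, None, r_cutoff=0.999999
        )
        corr = edges[edges["edge_type"] == "correlation"]
        assert len(corr) == 1 and corr["weight"].iloc[0] == pytest.approx(1.0)

    def test_no_enrichment_means_correlation_edges_only(self, small_study):
        study, truth = small_study
        edges = panel_network(
            study, {"omics1": truth.planted["omics1"]}, None, r_cutoff=0.3
        )
        assert (edges["edge_type"] == "correlation").all()
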