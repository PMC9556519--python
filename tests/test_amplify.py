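"""Calibration ensembles and Shapley importance."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from hybridqc import amplify as amp
from hybridqc import ratings as rt
from hybridqc import synthetic as syn
from hybridqc.evaluation import roc_auc


def shapley_exact_oracle(predict, x_row, background):
    """Exact Shapley values by enumerating all feature subsets.

    Coalition value = mean model output with coalition features set to
    the explained row and the rest to background rows.
    """
    d = len(x_row)
    phi = np.zeros(d)
    features = list(range(d))
    for i in features:
        others = [f for f in features if f != i]
        for size in range(d):
            for subset in itertools.combinations(others, size):
                weight = (
                    math.factorial(size)
                    * math.factorial(d - size - 1)
                    / math.factorial(d)
                )
                with_i = background.copy()
                without_i = background.copy()
                for j in subset:
                    with_i[:, j] = x_row[j]
                    without_i[:, j] = x_row[j]
                with_i[:, i] = x_row[i]
                phi[i] += weight * (
                    predict(with_i).mean() - predict(without_i).mean()
                )
    return phi


class TestFeatureMatrix:
    def test_mode_q_has_31_columns(self, small_metrics):
        fm = amp.build_feature_matrix(metrics=small_metrics, mode="q")
        assert len(fm.columns) == 31
        assert all(v == "metric" for v in fm.provenance.values())

    def test_mode_f_per_rater_means(self, small_cohort):
        community = syn.simulate_community_ratings(
            small_cohort,
            n_raters=2,
            optimism=0.0,
            rater_quality=(np.array([1.0, 1.0]), np.array([0.0, 1.0])),
            seed=0,
        )
        fm = amp.build_feature_matrix(community=community, mode="f")
        # rater 1 passes everything (sens 1, spec 0)
        assert (fm.data["rater_001"] == 1.0).all()

    def test_mode_qf_column_count(self, small_metrics, small_community):
        fm = amp.build_feature_matrix(small_metrics, small_community, mode="q+f")
        n_raters = small_community["rater_id"].nunique()
        assert len(fm.columns) == 31 + n_raters
        kinds = pd.Series(fm.provenance)
        assert (kinds == "metric").sum() == 31
        assert (kinds == "rater").sum() == n_raters

    def test_mode_input_mismatch_rejected(self, small_metrics):
        with pytest.raises(ValueError, match="requires community"):
            amp.build_feature_matrix(metrics=small_metrics, mode="q+f")
        with pytest.raises(ValueError, match="mode must be"):
            amp.build_feature_matrix(metrics=small_metrics, mode="metrics")


class TestFitCalibration:
    @pytest.fixture(scope="class")
    def fitted(self, small_metrics, small_experts):
        features = amp.build_feature_matrix(metrics=small_metrics, mode="q")
        targets = rt.aggregate_expert(small_experts)["binary"].astype(int)
        targets.index = features.data.index
        return (
            amp.fit_calibration(features, targets, search_budget=2, seed=0),
            features,
            targets,
        )

    def test_default_cv_yields_six_members(self, fitted):
        ensemble, _, _ = fitted
        assert len(ensemble.members) == 6
        assert len(ensemble.weights) == 6
        assert all(0 <= w <= 1 for w in ensemble.weights)

    def test_oof_auc_matches_independent_recomputation(self, fitted):
        ensemble, _, _ = fitted
        oof = ensemble.oof_predictions
        recomputed = [
            roc_auc(g["y_true"], g["y_proba"])
            for _, g in oof.groupby("fold")
        ]
        np.testing.assert_allclose(sorted(recomputed), sorted(ensemble.weights))
        assert ensemble.cv_auc_mean == pytest.approx(np.mean(recomputed))

    def test_separable_problem_reaches_unit_auc(self):
        n = 120
        y = np.repeat([0, 1], n // 2)
        x = pd.DataFrame({"f": y * 10.0})
        fm = amp.FeatureMatrix(data=x, mode="q", provenance={"f": "metric"})
        ensemble = amp.fit_calibration(fm, y, search_budget=1, seed=0)
        assert ensemble.cv_auc_mean > 0.999
        assert min(ensemble.weights) > 0.999

    def test_single_class_rejected(self, small_metrics):
        features = amp.build_feature_matrix(metrics=small_metrics, mode="q")
        with pytest.raises(ValueError, match="per class"):
            amp.fit_calibration(features, np.ones(len(features), dtype=int))

    def test_roundtrip_serialization(self, fitted, tmp_path):
        ensemble, features, _ = fitted
        ensemble.save(tmp_path / "ens")
        loaded = amp.CalibrationEnsemble.load(tmp_path / "ens")
        np.testing.assert_allclose(loaded.weights, ensemble.weights)
        before = amp.ensemble_predict(ensemble, features)
        after = amp.ensemble_predict(loaded, features)
        np.testing.assert_allclose(before, after, atol=1e-6)


class TestEnsemblePredict:
    @staticmethod
    def _stub(probs):
        class Stub:
            def __init__(self, p):
                self.p = np.asarray(p)
                self.classes_ = np.array([0, 1])

            def predict_proba(self, x):
                return np.column_stack([1 - self.p, self.p])

        return Stub(probs)

    def _ensemble(self, member_probs, weights):
        return amp.CalibrationEnsemble(
            members=[self._stub(p) for p in member_probs],
            weights=list(weights),
            feature_names=["a"],
            mode="q",
        )

    def test_single_member_identity(self):
        ens = self._ensemble([[0.3, 0.7]], [0.8])
        data = pd.DataFrame({"a": [0, 0]})
        np.testing.assert_allclose(
            amp.ensemble_predict(ens, data), [0.3, 0.7]
        )

    def test_equal_weights_plain_mean(self):
        ens = self._ensemble([[0.2], [0.6]], [0.5, 0.5])
        out = amp.ensemble_predict(ens, pd.DataFrame({"a": [0]}))
        assert out.iloc[0] == pytest.approx(0.4)

    def test_weighted_mean_hand_arithmetic(self):
        # (0.9*0.2 + 0.6*0.8) / 1.5 = 0.44
        ens = self._ensemble([[0.2], [0.8]], [0.9, 0.6])
        out = amp.ensemble_predict(ens, pd.DataFrame({"a": [0]}))
        assert out.iloc[0] == pytest.approx(0.44)

    def test_monotone_in_member_probability(self):
        low = self._ensemble([[0.2], [0.5]], [0.7, 0.7])
        high = self._ensemble([[0.2], [0.9]], [0.7, 0.7])
        data = pd.DataFrame({"a": [0]})
        assert (
            amp.ensemble_predict(high, data).iloc[0]
            > amp.ensemble_predict(low, data).iloc[0]
        )

    def test_schema_mismatch_names_columns(self):
        ens = self._ensemble([[0.2]], [1.0])
        with pytest.raises(ValueError, match="missing=\\['a'\\]"):
            amp.ensemble_predict(ens, pd.DataFrame({"b": [0]}))


class TestShapley:
    def test_constant_feature_has_zero_importance(self, small_metrics, small_experts):
        features = amp.build_feature_matrix(metrics=small_metrics, mode="q")
        targets = rt.aggregate_expert(small_experts)["binary"].astype(int)
        targets.index = features.data.index
        ensemble = amp.fit_calibration(features, targets, search_budget=1, seed=0)
        importance = amp.shapley_importance(
            ensemble, features, n_samples=4, n_explain=40, seed=0
        )
        assert importance["raw_voxel_size_x"] == 0.0
        assert importance["t1_dimension_z"] == 0.0
        # informative metrics dominate the ranking
        assert importance.index[0] in syn.INFORMATIVE_METRICS

    def test_sampling_matches_exact_enumeration(self):
        rng = np.random.default_rng(0)
        d = 5
        x = pd.DataFrame(rng.normal(size=(30, d)), columns=list("abcde"))
        beta = np.array([2.0, -1.0, 0.5, 0.0, 1.5])

        class Linear:
            classes_ = np.array([0, 1])

            def predict_proba(self, arr):
                z = np.asarray(arr) @ beta
                return np.column_stack([1 - z, z])

        importance = amp.shapley_importance(
            Linear(), x, n_samples=200, n_background=30, seed=1
        )
        predict = lambda arr: arr @ beta
        bg = x.to_numpy()
        exact = np.mean(
            [np.abs(shapley_exact_oracle(predict, row, bg)) for row in bg[:10]],
            axis=0,
        )
        sampled_subset = amp.shapley_importance(
            Linear(), x.iloc[:10], n_samples=200, n_background=30, seed=1
        )
        # compare per-feature mean |phi| on the same explained rows;
        # the background differs slightly (subset), so tolerance is loose
        for f, value in zip("abcde", exact):
            assert sampled_subset[f] == pytest.approx(value, rel=0.2, abs=0.05)
        assert importance.is_monotonic_decreasing

    def test_additive_model_recovers_own_contributions(self):
        """For an additive model on independent features, the Shapley
        value of feature i at x is f_i(x_i) - E[f_i]."""
        rng = np.random.default_rng(2)
        d = 4
        x = pd.DataFrame(rng.normal(size=(60, d)), columns=list("wxyz"))
        weights = np.array([1.0, -2.0, 0.0, 0.5])

        class Additive:
            classes_ = np.array([0, 1])

            def predict_proba(self, arr):
                z = np.asarray(arr) @ weights
                return np.column_stack([1 - z, z])

        importance = amp.shapley_importance(
            Additive(), x, n_samples=100, n_background=60, seed=3
        )
        bg = x.to_numpy()
        expected = {
            c: np.abs(weights[i] * (bg[:, i] - bg[:, i].mean())).mean()
            for i, c in enumerate("wxyz")
        }
        for c in "wxyz":
            assert importance[c] == pytest.approx(expected[c], rel=0.1, abs=0.02)

    def test_unfitted_model_rejected(self, small_metrics):
        from xgboost import XGBClassifier

        features = amp.build_feature_matrix(metrics=small_metrics, mode="q")
        with pytest.raises(ValueError, match="unfitted"):
            amp.shapley_importance(XGBClassifier(), features, n_samples=1)


def test_dropping_most_reliable_rater_lowers_mode_f_auc():
    """The calibration weights raters: removing the single most
    informative rater's column costs cross-validated AUC (stochastic
    tendency over seeds)."""
    deltas = []
    for seed in range(3):
        cohort = syn.generate_cohort(250, seed=seed)
        sens = np.full(8, 0.95)
        spec = np.concatenate([[0.95], np.full(7, 0.3)])  # rater 1 is gold
        community = syn.simulate_community_ratings(
            cohort,
            n_raters=8,
            rater_quality=(sens, spec),
            optimism=0.1,
            seed=seed,
        )
        experts = syn.simulate_expert_ratings(cohort, seed=seed + 40)
        targets = rt.aggregate_expert(experts)["binary"].astype(int)
        fm = amp.build_feature_matrix(community=community, mode="f")
        targets.index = fm.data.index
        full = amp.fit_calibration(fm, targets, search_budget=1, seed=seed)
        reduced_data = fm.data.drop(columns=["rater_001"])
        fm_red = amp.FeatureMatrix(
            data=reduced_data,
            mode="f",
            provenance={c: "rater" for c in reduced_data.columns},
        )
        reduced = amp.fit_calibration(fm_red, targets, search_budget=1, seed=seed)
        deltas.append(full.cv_auc_mean - reduced.cv_auc_mean)
    assert np.mean(deltas) > 0
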