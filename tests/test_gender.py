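"""Gender model: Fisher LDA, CV, greedy selection, masculinity scoring."""

import json

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from facemasc.gender import (FisherLDA, GenderMasculinityModel,
                             GreedyForwardSelector, cross_validate,
                             cv_accuracy, fit_lda, gefs_select,
                             masculinity_score)
from facemasc.synthetic import FeatureTableConfig, generate_feature_table

VARS10 = FeatureTableConfig().distance_variables


def _two_gaussians(rng, n=200, gap=10.0, p=1):
    X = np.vstack([rng.normal(0, 1, size=(n // 2, p)),
                   rng.normal(gap, 1, size=(n // 2, p))])
    y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    return X, y


class TestFisherLDA:
    def test_separated_classes_near_perfect(self):
        rng = np.random.default_rng(0)
        X, y = _two_gaussians(rng, n=200, gap=10.0)
        model = FisherLDA().fit(X, y)
        assert np.mean(model.predict(X) == y) > 0.999

    def test_no_signal_is_chance(self):
        rng = np.random.default_rng(1)
        X, y = _two_gaussians(rng, n=4000, gap=0.0, p=2)
        model = FisherLDA().fit(X, y)
        acc = np.mean(model.predict(X) == y)
        assert 0.45 < acc < 0.58
        assert model.mean_pos_ == pytest.approx(model.mean_neg_, abs=0.2)

    def test_hand_dataset_matches_closed_form(self):
        """8-point, 2-feature dataset: axis = Sw^-1 (mu_b - mu_a)."""
        X = np.array([[1.0, 2.0], [2.0, 1.0], [1.5, 1.8], [0.5, 1.2],
                      [4.0, 5.0], [5.0, 4.2], [4.5, 5.5], [5.5, 4.8]])
        y = np.array(["a"] * 4 + ["b"] * 4)
        Xa, Xb = X[:4], X[4:]
        Sw = (np.cov(Xa.T, bias=False) * 3 + np.cov(Xb.T, bias=False) * 3) / 6
        oracle = np.linalg.inv(Sw) @ (Xb.mean(0) - Xa.mean(0))
        w = FisherLDA().fit(X, y).coef_
        np.testing.assert_allclose(w / np.linalg.norm(w),
                                   oracle / np.linalg.norm(oracle),
                                   atol=1e-8)

    def test_collinear_with_sklearn_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = rng.integers(12, 50)
            p = rng.integers(2, 6)
            X = rng.normal(size=(n, p))
            y = np.where(rng.random(n) < 0.5, "f", "m")
            if min((y == "f").sum(), (y == "m").sum()) < 3:
                continue
            ours = FisherLDA().fit(X, y).coef_
            ref = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y).coef_[0]
            cos = ours @ ref / (np.linalg.norm(ours) * np.linalg.norm(ref))
            assert abs(cos) > 1 - 1e-6

    def test_orientation_positive_class_on_top(self):
        rng = np.random.default_rng(3)
        X, y = _two_gaussians(rng)
        model = FisherLDA(positive_class="b").fit(X, y)
        assert model.mean_pos_ > model.mean_neg_

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            FisherLDA().fit(np.zeros((4, 2)), np.array(["a"] * 4))

    def test_singular_covariance_ridge_fallback(self, caplog):
        X = np.array([[0.0, 0.0], [0, 0], [1, 1], [1, 1]])
        y = np.array(["a", "a", "b", "b"])
        with caplog.at_level("WARNING"):
            model = FisherLDA().fit(X, y)
        assert np.all(np.isfinite(model.coef_))
        assert any("ridge" in r.message for r in caplog.records)


class TestCrossValidation:
    def test_separable_data_perfect(self):
        rng = np.random.default_rng(4)
        X, y = _two_gaussians(rng, n=100, gap=50.0)
        assert cross_validate(X, y, k=10, seed=0) == 1.0

    def test_deterministic_given_seed(self, feature_table):
        X = feature_table[VARS10]
        y = feature_table["sex"].to_numpy()
        a = cross_validate(X, y, seed=5)
        b = cross_validate(X, y, seed=5)
        assert a == b

    def test_permuted_labels_at_chance(self, feature_table):
        """Shuffled sex labels leave only chance accuracy (n = 355)."""
        X = feature_table[VARS10]
        y = feature_table["sex"].to_numpy()
        accs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            accs.append(cross_validate(X, rng.permutation(y), seed=seed))
        assert 0.40 <= np.mean(accs) <= 0.60
        assert np.min(accs) > 0.30

    def test_class_smaller_than_k_errors(self):
        X = np.zeros((6, 1))
        y = np.array(["a"] * 3 + ["b"] * 3)
        with pytest.raises(ValueError):
            cross_validate(X, y, k=10)


class TestGreedySelection:
    def _informative_plus_noise(self, seed, n=400, noise=10):
        rng = np.random.default_rng(seed)
        y = np.array(["f", "m"] * (n // 2))
        male = (y == "m").astype(float)
        cols = {
            "dimorphic_a": male * 2.2 + rng.normal(size=n),
            "dimorphic_b": male * 2.0 + rng.normal(size=n),
        }
        for i in range(noise):
            cols[f"noise_{i:02d}"] = rng.normal(size=n)
        return pd.DataFrame(cols), y

    def test_selects_informative_not_noise(self):
        hits = 0
        for seed in range(50):
            X, y = self._informative_plus_noise(seed)
            chosen = gefs_select(X, y, seed=seed)
            good = {"dimorphic_a", "dimorphic_b"}.issubset(chosen)
            clean = not any(c.startswith("noise") for c in chosen)
            hits += good and clean
        assert hits >= 45  # >= 90% of 50 seeds

    def test_all_noise_stops_at_chance(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(300, 6)),
                         columns=[f"n{i}" for i in range(6)])
        y = np.array(["f", "m"] * 150)
        sel = GreedyForwardSelector(seed=0).fit(X, y)
        assert 0.35 <= sel.cv_accuracy_ <= 0.65

    def test_max_features_one_picks_best_single(self):
        X, y = self._informative_plus_noise(3)
        chosen = gefs_select(X, y, max_features=1, seed=0)
        assert len(chosen) == 1
        assert chosen[0].startswith("dimorphic")

    def test_exhaustive_matches_brute_force(self):
        """Exhaustive mode equals an explicit all-subsets search."""
        import itertools

        rng = np.random.default_rng(10)
        y = np.array(["f", "m"] * 30)
        male = (y == "m").astype(float)
        X = pd.DataFrame({
            "a": male * 1.5 + rng.normal(size=60),
            "b": male * 1.0 + rng.normal(size=60),
            "c": rng.normal(size=60),
            "d": rng.normal(size=60),
        })
        sel = GreedyForwardSelector(seed=1, exhaustive=True,
                                    n_repeats=1).fit(X, y)
        best = -1.0
        for size in range(1, 5):
            for comb in itertools.combinations(sorted(X.columns), size):
                folds_acc = cv_accuracy(
                    FisherLDA(), X[list(comb)], y, k=10, seed=1)
                best = max(best, folds_acc)
        assert sel.cv_accuracy_ == pytest.approx(best, abs=1e-12)

    def test_greedy_close_to_exhaustive_optimum(self):
        X, y = self._informative_plus_noise(4, n=200, noise=4)
        greedy = GreedyForwardSelector(seed=2).fit(X, y)
        exhaustive = GreedyForwardSelector(seed=2, exhaustive=True).fit(X, y)
        assert greedy.cv_accuracy_ >= exhaustive.cv_accuracy_ - 0.02

    def test_invalid_max_features(self):
        X, y = self._informative_plus_noise(5)
        with pytest.raises(ValueError):
            GreedyForwardSelector(max_features=0).fit(X, y)


class TestMasculinityScore:
    @pytest.fixture(scope="class")
    def fitted(self, feature_table):
        model = GenderMasculinityModel(feature_subset=VARS10, seed=0)
        model.fit(feature_table[VARS10], feature_table["sex"].to_numpy())
        return model

    def test_training_scores_span_unit_interval(self, fitted, feature_table):
        s = fitted.masculinity_score(feature_table[VARS10])
        assert s.max() == 1.0
        assert s.min() == 0.0
        assert np.all((s >= 0) & (s <= 1))

    def test_midpoint_scores_between_class_means(self, fitted,
                                                 feature_table):
        X = feature_table[VARS10]
        y = feature_table["sex"].to_numpy()
        s = fitted.masculinity_score(X)
        mid_row = X.mean(axis=0).to_frame().T
        # place the synthetic face exactly at the projected midpoint
        w = fitted.lda_.coef_
        shift = -fitted.lda_.decision_function(mid_row)[0] / (w @ w)
        mid_row = mid_row + shift * w
        s_mid = float(fitted.masculinity_score(mid_row)[0])
        assert s[y == "female"].mean() < s_mid < s[y == "male"].mean()

    def test_monotone_along_axis(self, fitted, feature_table):
        X = feature_table[VARS10].iloc[[10]]
        w = fitted.lda_.coef_
        scores = [float(fitted.masculinity_score(X + t * w)[0])
                  for t in np.linspace(0, 5e-3, 8)]
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_out_of_sample_clipped(self, fitted, feature_table):
        X = feature_table[VARS10].iloc[[0]] + 100.0
        assert float(fitted.masculinity_score(X)[0]) in (0.0, 1.0)

    def test_missing_feature_errors(self, fitted, feature_table):
        X = feature_table[VARS10].drop(columns=[VARS10[0]])
        with pytest.raises(ValueError, match=VARS10[0]):
            fitted.masculinity_score(X)

    def test_json_round_trip(self, fitted, feature_table, tmp_path):
        path = tmp_path / "model.json"
        fitted.to_json(path)
        loaded = GenderMasculinityModel.from_json(path)
        X = feature_table[VARS10]
        np.testing.assert_allclose(loaded.masculinity_score(X),
                                   fitted.masculinity_score(X), atol=1e-12)
        payload = json.loads(path.read_text())
        assert payload["selected_features"] == fitted.selected_features_

    def test_single_vector_wrapper(self, fitted, feature_table):
        row = feature_table[VARS10].iloc[5]
        val = masculinity_score(fitted, row)
        assert 0.0 <= val <= 1.0

    def test_sexes_separate_on_calibrated_cohort(self, fitted,
                                                 feature_table):
        """Male faces score far above female faces (bimodal scores)."""
        s = fitted.masculinity_score(feature_table[VARS10])
        y = feature_table["sex"].to_numpy()
        male, female = s[y == "male"], s[y == "female"]
        assert male.mean() > female.mean()
        pooled = np.sqrt((male.var(ddof=1) + female.var(ddof=1)) / 2)
        assert (male.mean() - female.mean()) / pooled > 4.0


def test_fit_lda_wrapper(feature_table):
    model = fit_lda(feature_table, feature_table["sex"].to_numpy(),
                    feature_subset=VARS10)
    assert model.coef_.shape == (10,)
    assert model.positive_class_ == "male"
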