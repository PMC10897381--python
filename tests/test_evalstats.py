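import numpy as np
import pandas as pd
import pytest

from moxpa.classifier import TrainingConfig
from moxpa.evalstats import (
    classifier_f1_jaccard,
    feature_comparisons,
    jaccard_similarity,
    ols_compare,
    rmse_mae,
)


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [({1, 2}, {2, 3}, 1 / 3), ({1, 2}, {1, 2}, 1.0), ({1}, {2}, 0.0), (set(), set(), 1.0)],
    )
    def test_formula(self, a, b, expected):
        assert jaccard_similarity(a, b) == pytest.approx(expected)

    def test_symmetry(self):
        assert jaccard_similarity({1, 2, 3}, {3, 4}) == jaccard_similarity({3, 4}, {1, 2, 3})


class TestErrorMetrics:
    def test_identical_series_zero(self):
        assert rmse_mae([1, 2, 3], [1, 2, 3]) == (0.0, 0.0)

    def test_hand_substitution(self):
        rmse, mae = rmse_mae([0, 0], [3, 4])
        assert rmse == pytest.approx(np.sqrt(12.5))
        assert mae == pytest.approx(3.5)

    def test_homogeneity(self):
        rmse, mae = rmse_mae([1, 2, 4], [2, 1, 0])
        rmse3, mae3 = rmse_mae([3, 6, 12], [6, 3, 0])
        assert (rmse3, mae3) == (pytest.approx(3 * rmse), pytest.approx(3 * mae))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse_mae([1, 2], [1])


class TestQqOls:
    def test_identity_gives_perfect_fit(self, labelled_small):
        rep = ols_compare(labelled_small, labelled_small)
        for col, fit in rep.per_feature.items():
            assert fit["r2"] == pytest.approx(1.0)
            assert fit["rse"] == pytest.approx(0.0, abs=1e-8)
            assert fit["slope"] == pytest.approx(1.0)

    def test_against_closed_form_simple_regression(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.normal(size=20))
        y = np.sort(1.5 * rng.normal(size=20) + 2)
        rep = ols_compare(pd.DataFrame({"f": x}), pd.DataFrame({"f": y}))
        fit = rep.per_feature["f"]
        # covariance-formula oracle
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        intercept = y.mean() - slope * x.mean()
        resid = y - (intercept + slope * x)
        r2 = 1 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
        assert fit["slope"] == pytest.approx(slope, abs=1e-10)
        assert fit["intercept"] == pytest.approx(intercept, abs=1e-10)
        assert fit["r2"] == pytest.approx(r2, abs=1e-10)
        # adjusted R^2 and RSE by direct formula substitution
        n, p = 20, 1
        assert fit["adj_r2"] == pytest.approx(1 - (1 - r2) * (n - 1) / (n - p - 1), abs=1e-10)
        assert fit["rse"] == pytest.approx(np.sqrt(np.sum(resid**2) / (n - p - 1)), abs=1e-10)

    def test_adjusted_r2_formula_substitution(self):
        # R^2 = 0.5, N = 10, p = 2 -> 1 - (0.5 * 9) / 7
        assert 1 - (1 - 0.5) * (10 - 1) / (10 - 2 - 1) == pytest.approx(0.35714285714, abs=1e-9)

    def test_f_is_variance_ratio(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rep = ols_compare(pd.DataFrame({"f": 2 * base}), pd.DataFrame({"f": base}))
        assert rep.per_feature["f"]["f_value"] == pytest.approx(4.0)
        # symmetric: larger variance always in the numerator
        rep2 = ols_compare(pd.DataFrame({"f": base}), pd.DataFrame({"f": 2 * base}))
        assert rep2.per_feature["f"]["f_value"] == pytest.approx(4.0)

    def test_constant_feature_skipped_with_flag(self, labelled_small):
        synth = labelled_small.copy()
        synth["VPA"] = 0
        rep = ols_compare(labelled_small, synth)
        assert "VPA" in rep.skipped
        assert "VPA" not in rep.per_feature

    def test_size_mismatch_quantile_matched(self, labelled_small):
        rep = ols_compare(labelled_small, labelled_small.iloc[: len(labelled_small) // 2])
        assert all(fit["n"] == len(labelled_small) for fit in rep.per_feature.values())


class TestFeatureComparisons:
    def test_identity_gives_zero_distances(self, labelled_small):
        rep = feature_comparisons(labelled_small, labelled_small)
        assert max(rep.ks_distance.values()) == 0.0
        assert max(rep.cumsum_max_discrepancy.values()) == pytest.approx(0.0, abs=1e-12)
        assert max(rep.log_mean_diff.values()) == 0.0

    def test_shifted_feature_dominates_all_channels(self, labelled_small):
        synth = labelled_small.copy()
        shift = 10 * labelled_small["MPA"].std()
        synth["MPA"] = synth["MPA"] + shift
        rep = feature_comparisons(labelled_small, synth)
        for channel in (rep.log_mean_diff, rep.cumsum_max_discrepancy, rep.ks_distance):
            assert max(channel, key=lambda c: channel[c]) == "MPA"

    def test_ks_between_same_distribution_draws_small(self):
        rng = np.random.default_rng(1)
        a = pd.DataFrame({"x": rng.normal(size=5000)})
        b = pd.DataFrame({"x": rng.normal(size=5000)})
        rep = feature_comparisons(a, b)
        assert rep.ks_distance["x"] < 0.05

    def test_zero_mean_flagged_undefined(self):
        a = pd.DataFrame({"x": [-1.0, 0.0, 1.0, 2.0, -2.0]})
        rep = feature_comparisons(a, a)
        assert any("log-mean" in u for u in rep.undefined)


class TestClassifierPanel:
    CFG = TrainingConfig(epochs=25, seed=0)

    def test_synthetic_equal_to_real_train_gives_jaccard_one(self, labelled_small):
        from sklearn.model_selection import train_test_split

        y = labelled_small["Active"].to_numpy()
        tr, _ = train_test_split(
            np.arange(len(labelled_small)), test_size=0.25, random_state=0, stratify=y
        )
        synth = labelled_small.iloc[tr].reset_index(drop=True)
        out = classifier_f1_jaccard(labelled_small, synth, seed=0, mlp_config=self.CFG)
        assert out["compatible"]
        for name, entry in out["panel"].items():
            assert entry["jaccard"] == pytest.approx(1.0), name
            assert entry["f1_real"] == entry["f1_synthetic"]

    def test_single_class_synthetic_incompatible(self, labelled_small):
        synth = labelled_small.copy()
        synth["Active"] = 0
        out = classifier_f1_jaccard(labelled_small, synth, seed=0)
        assert out == {"compatible": False, "reason": "synthetic labels contain a single class"}

    def test_random_labels_score_below_real_baseline(self, labelled_small):
        rng = np.random.default_rng(2)
        noisy = labelled_small.copy()
        noisy["Active"] = rng.integers(0, 5, len(noisy))
        baseline = classifier_f1_jaccard(labelled_small, labelled_small, seed=0, mlp_config=self.CFG)
        degraded = classifier_f1_jaccard(labelled_small, noisy, seed=0, mlp_config=self.CFG)
        base_j = np.mean([e["jaccard"] for e in baseline["panel"].values()])
        deg_j = np.mean([e["jaccard"] for e in degraded["panel"].values()])
        assert deg_j < base_j
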