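import numpy as np
import pandas as pd
import pytest

from moxpa.classifier import (
    ConfusionMatrix,
    TrainingConfig,
    build_mlp,
    classification_metrics,
    confusion_from_labels,
    parameter_count,
    train_crossval,
    train_on_sources_evaluate_on_real,
)


def separable_table(n=200, seed=0):
    """Five-feature table with five well-separated class blobs in the
    (Steps, MPA) plane; the other features are uninformative noise."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 5, size=n)
    angle = y * 2 * np.pi / 5
    return pd.DataFrame({
        "Sedentary": rng.normal(70_000, 5000, n),
        "LPA": rng.normal(5000, 500, n),
        "MPA": 3000 + 2000 * np.sin(angle) + rng.normal(0, 100, n),
        "VPA": rng.normal(300, 50, n),
        "Steps": 10_000 + 6000 * np.cos(angle) + rng.normal(0, 300, n),
        "Active": y,
    })


class TestArchitecture:
    def test_default_parameter_count_is_2405(self):
        net, count = build_mlp()
        assert count == 2405
        assert count == parameter_count(5, (81, 18, 12, 10, 5), 5)

    def test_closed_form_oracle_matches_network(self):
        # brute-force count: sum of (fan_in + 1) * fan_out over the stack
        widths = [5, 81, 18, 12, 10, 5, 5]
        oracle = sum((widths[i] + 1) * widths[i + 1] for i in range(len(widths) - 1))
        net, count = build_mlp()
        assert count == oracle == sum(layer.W.size + layer.b.size for layer in net.layers)

    def test_six_dense_layers_relu_then_softmax(self):
        net, _ = build_mlp()
        assert len(net.layers) == 6
        assert [l.activation for l in net.layers] == ["relu"] * 5 + ["softmax"]

    def test_degenerate_config_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(hidden=(10,))


class TestMetrics:
    def test_perfect_classifier(self):
        cm = ConfusionMatrix(matrix=np.array([[5, 0], [0, 5]]), classes=[1, 0])
        r = classification_metrics(cm)
        assert (r.accuracy, r.f1, r.mcc) == (1.0, 1.0, 1.0)

    def test_printed_formula_substitution_exact(self):
        # TP=3, FP=1, FN=2, TN=4 for the positive class
        cm = ConfusionMatrix(matrix=np.array([[3, 2], [1, 4]]), classes=[1, 0])
        r = classification_metrics(cm)
        pc = r.per_class[1]
        assert pc["precision"] == pytest.approx(0.75, abs=1e-12)
        assert pc["recall"] == pytest.approx(0.6, abs=1e-12)
        assert pc["specificity"] == pytest.approx(0.8, abs=1e-12)
        assert pc["f1"] == pytest.approx(2 * 0.75 * 0.6 / 1.35, abs=1e-12)
        assert pc["mcc"] == pytest.approx(10 / np.sqrt(600), abs=1e-12)
        assert pc["accuracy"] == pytest.approx(0.7, abs=1e-12)

    def test_metric_identities(self):
        cm = confusion_from_labels([0, 0, 1, 1, 2, 2], [0, 1, 1, 1, 2, 0], classes=[0, 1, 2])
        r = classification_metrics(cm)
        for cls, pc in r.per_class.items():
            tp, fp, tn, fn = cm.counts(cls)
            if tp + fn:
                assert pc["recall"] == pytest.approx(1 - fn / (tp + fn))
            if pc["precision"] + pc["recall"] > 0:
                hm = 2 * pc["precision"] * pc["recall"] / (pc["precision"] + pc["recall"])
                assert pc["f1"] == pytest.approx(hm)

    def test_all_zero_matrix_flagged_not_raised(self):
        cm = ConfusionMatrix(matrix=np.zeros((2, 2), dtype=int), classes=[0, 1])
        r = classification_metrics(cm)
        assert r.accuracy == 0.0
        assert r.undefined  # zero denominators reported

    def test_counts_partition(self):
        cm = confusion_from_labels([0, 1, 2, 3, 4] * 4, [0, 1, 2, 3, 0] * 4)
        for cls in cm.classes:
            assert sum(cm.counts(cls)) == cm.n


class TestCrossValidation:
    def test_separable_toy_high_accuracy(self):
        table = separable_table()
        _, mean = train_crossval(table, TrainingConfig(epochs=120, seed=0))
        assert mean.accuracy > 0.95

    def test_shuffled_labels_give_chance_accuracy(self):
        table = separable_table(seed=1)
        rng = np.random.default_rng(0)
        table["Active"] = rng.permutation(table["Active"].to_numpy())
        _, mean = train_crossval(table, TrainingConfig(epochs=40, seed=0))
        assert mean.accuracy == pytest.approx(0.2, abs=0.1)

    def test_folds_partition_rows(self):
        from sklearn.model_selection import StratifiedKFold

        table = separable_table()
        y = table["Active"].to_numpy()
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        seen = np.concatenate([te for _, te in skf.split(table, y)])
        assert sorted(seen) == list(range(len(table)))

    def test_seeded_reproducibility(self):
        table = separable_table()
        cfg = TrainingConfig(epochs=20, seed=3)
        _, a = train_crossval(table, cfg)
        _, b = train_crossval(table, cfg)
        assert a.accuracy == b.accuracy and a.f1 == b.f1


class TestProtocol:
    def test_arm_record_counts(self, labelled_small):
        real = labelled_small
        synth = {"FGC": real.copy(), "FC": real.copy()}
        cfg = TrainingConfig(epochs=2, seed=0)
        res = train_on_sources_evaluate_on_real(real, synth, config=cfg, repeats=1)
        n = len(real)
        assert res["R"]["records"] == n
        assert res["FGC+R"]["records"] == 2 * n
        assert res["FGC+FC+R"]["records"] == 3 * n

    def test_column_mismatch_rejected(self, labelled_small):
        bad = labelled_small.rename(columns={"Steps": "steps"})
        with pytest.raises(ValueError, match="columns"):
            train_on_sources_evaluate_on_real(labelled_small, {"FGC": bad}, arms=["FGC+R"])
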