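import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pvlabel.bench import (
    ConfusionCounts,
    ModelSpec,
    confusion,
    cross_validate,
    efs,
    evaluate,
    fit_model,
    greedy_forward_selection,
    mcc,
    permutation_importance,
    split_dataset,
    threshold_sweep,
    train_and_evaluate,
    tune_hyperparams,
)

FAST_SPEC = ModelSpec(C=10.0, gamma=0.5)


def toy_table(n=120, n_pos=30, separation=4.0, seed=0, noise_cols=2):
    """Binary data where f1 separates the classes and the rest is noise."""
    rng = np.random.default_rng(seed)
    y = np.array([1] * n_pos + [0] * (n - n_pos))
    df = pd.DataFrame({"f1": rng.normal(0, 1, n) + separation * y})
    for j in range(noise_cols):
        df[f"noise{j}"] = rng.normal(0, 1, n)
    df["label"] = np.where(y == 1, "positive", "negative")
    return df


class TestMCC:
    def test_perfect_prediction(self):
        assert mcc(ConfusionCounts(5, 7, 0, 0)) == 1.0
        assert mcc(ConfusionCounts(0, 0, 5, 7)) == -1.0

    def test_balanced_random_is_zero(self):
        assert mcc(ConfusionCounts(5, 5, 5, 5)) == 0.0

    def test_hand_arithmetic(self):
        assert mcc(ConfusionCounts(3, 4, 1, 2)) == pytest.approx(10 / math.sqrt(600))

    def test_zero_factor_convention(self):
        assert mcc(ConfusionCounts(0, 10, 0, 3)) == 0.0

    def test_matches_sklearn_on_all_small_tables(self):
        """Exhaustive agreement with sklearn's MCC over all confusion tables
        with at most 12 samples (sklearn defines the zero-factor case as 0 too)."""
        from sklearn.metrics import matthews_corrcoef

        for tp, tn, fp, fn in itertools.product(range(13), repeat=4):
            total = tp + tn + fp + fn
            if not 0 < total <= 12:
                continue
            y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
            y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
            ours = mcc(ConfusionCounts(tp, tn, fp, fn))
            assert ours == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)

    def test_confusion_counts_total(self):
        c = confusion([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert c.to_dict() == {"tp": 2, "tn": 1, "fp": 1, "fn": 1}
        assert c.total == 5


class TestSplit:
    def test_stratified_counts(self):
        table = toy_table(n=100, n_pos=10)
        train, test = split_dataset(table, ratio=0.7, seed=0)
        assert (train.label == "positive").sum() == 7
        assert (test.label == "positive").sum() == 3
        assert len(train) == 70 and len(test) == 30

    def test_deterministic(self):
        table = toy_table()
        a, _ = split_dataset(table, seed=5)
        b, _ = split_dataset(table, seed=5)
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("ratio", [0.0, 1.0, 1.5])
    def test_degenerate_ratio_rejected(self, ratio):
        with pytest.raises(ValueError, match="ratio"):
            split_dataset(toy_table(), ratio=ratio)

    def test_single_class_rejected(self):
        table = toy_table()
        table["label"] = "negative"
        with pytest.raises(ValueError, match="class"):
            split_dataset(table)


class TestCrossValidate:
    def test_separable_data_perfect_cv(self):
        cv = cross_validate(FAST_SPEC, toy_table(separation=8.0), ["f1"], k=5)
        assert cv.mean("mcc") == 1.0
        assert cv.sd("mcc") == 0.0

    def test_shuffled_labels_near_zero(self):
        table = toy_table(n=200, n_pos=100, separation=4.0, seed=1)
        rng = np.random.default_rng(2)
        table["label"] = rng.permutation(table["label"].to_numpy())
        cv = cross_validate(FAST_SPEC, table, ["f1"], k=5)
        assert abs(cv.mean("mcc")) < 0.15

    def test_too_few_positives_advises_smaller_k(self):
        table = toy_table(n=50, n_pos=3)
        with pytest.raises(ValueError, match="smaller k"):
            cross_validate(FAST_SPEC, table, ["f1"], k=5)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(FAST_SPEC, toy_table(), ["f1"], k=1)


class TestEFS:
    def test_separating_feature_selected(self):
        result = efs(toy_table(separation=8.0), FAST_SPEC, subset_sizes=(1, 2), k=3)
        assert result.best_subset == ("f1",)
        assert result.best_score == 1.0

    def test_duplicated_winner_still_size_one(self):
        table = toy_table(separation=8.0)
        table["f1_copy"] = table["f1"]
        result = efs(
            table, FAST_SPEC, subset_sizes=(1, 2),
            feature_cols=["f1", "f1_copy", "noise0"], k=3,
        )
        assert len(result.best_subset) == 1  # ties break toward smaller subsets

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            efs(toy_table(), FAST_SPEC, subset_sizes={0})

    def test_budget_exceeded_names_count(self):
        with pytest.raises(ValueError, match="subsets exceed"):
            efs(toy_table(), FAST_SPEC, subset_sizes=(1, 2), budget=3)

    def test_greedy_fallback_finds_separator(self):
        result = greedy_forward_selection(
            toy_table(separation=8.0), FAST_SPEC, max_size=2, k=3
        )
        assert "f1" in result.best_subset
        assert result.best_score == 1.0


class TestTuning:
    def test_single_iteration_returns_sampled_spec(self):
        spec, trials = tune_hyperparams(
            toy_table(separation=8.0), ["f1"], FAST_SPEC, iterations=1, k=3
        )
        assert len(trials) == 1
        assert spec.C == trials.loc[0, "C"]

    def test_separable_reaches_perfect_cv(self):
        spec, trials = tune_hyperparams(
            toy_table(separation=8.0), ["f1"], FAST_SPEC, iterations=20, k=3, seed=3
        )
        assert trials["mean_mcc"].max() == 1.0

    def test_deterministic_for_fixed_seed(self):
        a, _ = tune_hyperparams(toy_table(), ["f1"], FAST_SPEC, iterations=5, k=3, seed=9)
        b, _ = tune_hyperparams(toy_table(), ["f1"], FAST_SPEC, iterations=5, k=3, seed=9)
        assert (a.C, a.gamma) == (b.C, b.gamma)

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError, match="C range"):
            tune_hyperparams(toy_table(), ["f1"], FAST_SPEC, c_range=(0.0, 0.0))


class TestSpecValidation:
    def test_search_box_enforced(self):
        with pytest.raises(ValueError, match="C="):
            ModelSpec(C=5000.0)
        with pytest.raises(ValueError, match="gamma="):
            ModelSpec(gamma=0.0001)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            ModelSpec(kind="random_forest")


@pytest.fixture(scope="module")
def model_and_data():
    table = toy_table(n=160, n_pos=40, separation=5.0, seed=4)
    train, test = split_dataset(table, seed=0)
    model = fit_model(FAST_SPEC, train, ["f1", "noise0", "noise1"])
    return model, train, test


class TestFittedModel:
    def test_evaluate_reports_consistent_confusion(self, model_and_data):
        model, _, test = model_and_data
        report = evaluate(model, test)
        assert report["confusion"]["tp"] + report["confusion"]["fn"] \
            == (test.label == "positive").sum()
        assert report["mcc"] > 0.8

    def test_permutation_importance_ranks_separator_first(self, model_and_data):
        model, _, test = model_and_data
        imp = permutation_importance(model, test, n_repeats=5, seed=0)
        assert imp.loc[0, "feature"] == "f1"
        noise = imp[imp.feature != "f1"]
        assert (noise.importance.abs() <= 2 * noise.sd.clip(lower=0.05)).all()

    def test_permutation_importance_reproducible(self, model_and_data):
        model, _, test = model_and_data
        a = permutation_importance(model, test, n_repeats=1, seed=3)
        b = permutation_importance(model, test, n_repeats=1, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_threshold_sweep_boundaries_and_monotone_recall(self, model_and_data):
        model, _, test = model_and_data
        grid = [0.001, 0.1, 0.5, 0.9, 0.999]
        sweep = threshold_sweep(model, test, thresholds=grid)
        assert sweep.loc[0, "recall"] == 1.0  # threshold -> 0: everything positive
        assert sweep.loc[len(grid) - 1, "recall"] == 0.0
        assert (np.diff(sweep["recall"]) <= 1e-12).all()

    def test_threshold_outside_unit_interval_rejected(self, model_and_data):
        model, _, test = model_and_data
        with pytest.raises(ValueError, match="threshold"):
            threshold_sweep(model, test, thresholds=[1.5])


def test_train_and_evaluate_end_to_end_on_toy_data():
    report = train_and_evaluate(
        toy_table(n=200, n_pos=50, separation=6.0, seed=8),
        spec=FAST_SPEC, efs_sizes=(1,), k=3, tune_iterations=3, seed=0,
    )
    assert report.selected_features == ("f1",)
    assert report.test["mcc"] == 1.0
    assert report.cv["mcc"]["mean"] == 1.0
    d = report.to_dict()
    assert set(d["cv"]) == {"mcc", "precision", "recall", "auc"}


@pytest.mark.parametrize("kind", ["gradient_boosting_a", "gradient_boosting_b"])
def test_boosting_backends_plug_in(kind):
    spec = ModelSpec(kind=kind, transform="none")
    cv = cross_validate(spec, toy_table(separation=8.0, seed=2), ["f1"], k=3)
    assert cv.mean("mcc") > 0.9
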