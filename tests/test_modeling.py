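import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import precision_recall_fscore_support

from conftest import random_feature_matrix, small_feature_matrix
from gaitmood import modeling
from gaitmood.features import make_selector, zscore
from gaitmood.modeling import (
    CVConfig,
    TooFewCases,
    binarize_item,
    confusion_counts,
    cross_validate_classification,
    cross_validate_regression,
    precision_recall_f,
    run_study,
)


class TestBinarizeItem:
    def test_zero_versus_any_endorsement(self):
        np.testing.assert_array_equal(binarize_item([0, 1, 2, 3]), [0, 1, 1, 1])

    def test_all_zero_scores(self):
        assert binarize_item([0] * 5).sum() == 0

    def test_observed_item_distribution_split(self):
        # 25 zeros and 136 + 4 + 1 nonzero answers on the anhedonia item
        scores = [0] * 25 + [1] * 136 + [2] * 4 + [3] * 1
        labels = binarize_item(scores)
        assert (labels == 0).sum() == 25
        assert (labels == 1).sum() == 141

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binarize_item([0, 4])


class TestFolds:
    @pytest.mark.parametrize("n", [20, 57, 100])
    def test_shuffled_folds_partition_subjects(self, n):
        folds = modeling._shuffled_folds(n, 10, rng_seed=1)
        flat = np.concatenate(folds)
        assert len(folds) == 10
        np.testing.assert_array_equal(np.sort(flat), np.arange(n))

    def test_stratified_folds_partition_and_balance(self):
        labels = np.array([0] * 30 + [1] * 70)
        folds = modeling._stratified_folds(labels, 10, rng_seed=2)
        flat = np.concatenate(folds)
        np.testing.assert_array_equal(np.sort(flat), np.arange(100))
        for fold in folds:
            assert (labels[fold] == 0).sum() == 3
            assert (labels[fold] == 1).sum() == 7


class TestRegressionCV:
    def test_target_leaked_into_feature_recovers_r_near_one(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=60)
        X = rng.normal(size=(60, 10))
        X[:, 4] = y
        fm = small_feature_matrix(X)
        res = cross_validate_regression(fm, y, "LR", CVConfig(rng_seed=1))
        assert res.pearson_r >= 0.99

    @pytest.mark.parametrize("model", ["SLR", "LR", "eSVR", "nSVR", "GP"])
    def test_all_models_run_and_bound_r(self, model):
        rng = np.random.default_rng(3)
        y = rng.normal(size=40)
        X = y[:, None] * 0.5 + rng.normal(size=(40, 6))
        res = cross_validate_regression(
            small_feature_matrix(X), y, model, CVConfig(rng_seed=4)
        )
        assert -1.0 <= res.pearson_r <= 1.0
        assert res.n == 40

    def test_shuffled_target_gives_null_centered_r(self):
        """Permutation-null oracle: mean CV r over 200 shuffles is ~0.

        Pooled out-of-fold r is only null-centered when predictions carry
        real variance; a near-mean predictor anti-tracks fold composition
        and biases r negative, so the null check uses a feature count large
        enough for the fit to interpolate noise.
        """
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 40))
        fm = small_feature_matrix(X)
        y = rng.normal(size=60)
        rs = []
        for rep in range(200):
            y_shuf = rng.permutation(y)
            res = cross_validate_regression(fm, y_shuf, "LR", CVConfig(rng_seed=rep))
            rs.append(res.pearson_r)
        rs = np.array(rs)
        se = rs.std(ddof=1) / np.sqrt(len(rs))
        assert abs(rs.mean()) < 3 * se

    def test_unknown_model_rejected(self):
        fm = small_feature_matrix(np.random.default_rng(0).normal(size=(20, 4)))
        with pytest.raises(ValueError, match="unknown regression model"):
            cross_validate_regression(fm, np.arange(20.0), "XGB", CVConfig())

    def test_slr_never_beats_lr_on_training_data(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=50)
        slr = modeling._SingleFeatureRegressor().fit(X, y)
        lr = modeling._make_regressor("LR").fit(X, y)
        sse_slr = np.sum((y - slr.predict(X)) ** 2)
        sse_lr = np.sum((y - lr.predict(X)) ** 2)
        assert sse_lr <= sse_slr + 1e-8

    def test_nested_selection_uses_only_training_rows(self):
        """A feature equal to the target on one test fold only must not be
        selected by folds that exclude it from training."""
        rng = np.random.default_rng(8)
        fm = zscore(random_feature_matrix(40, rng))
        y = rng.normal(size=40)
        res = cross_validate_regression(
            fm, y, "LR", CVConfig(rng_seed=9, nested_selection=True),
            selector=make_selector(),
        )
        assert np.isfinite(res.pearson_r)


class TestClassificationCV:
    def test_perfectly_separable_labels(self):
        rng = np.random.default_rng(0)
        labels = np.array([0] * 30 + [1] * 30)
        X = rng.normal(size=(60, 5))
        X[:, 2] = labels * 4.0 - 2.0
        res = cross_validate_classification(
            small_feature_matrix(X), labels, "SL", CVConfig(rng_seed=1)
        )
        assert (res.precision, res.recall, res.f_measure) == (1.0, 1.0, 1.0)

    def test_all_positive_predictor_arithmetic(self):
        # predicting everyone symptomatic on a 141/25 split
        labels = np.array([1] * 141 + [0] * 25)
        preds = np.ones(166, dtype=int)
        tp, fp, fn, tn = confusion_counts(labels, preds)
        precision, recall, f = precision_recall_f(tp, fp, fn)
        assert recall == 1.0
        assert precision == pytest.approx(141 / 166)

    def test_f_measure_is_harmonic_mean(self):
        p, r = 0.85, 0.95
        tp, fp, fn = 1700, 300, int(round(1700 / r - 1700))
        precision, recall, f = precision_recall_f(tp, fp, fn)
        assert precision == pytest.approx(p)
        assert recall == pytest.approx(r, abs=1e-3)
        assert f == pytest.approx(2 * p * r / (p + r), abs=1e-3)

    @pytest.mark.parametrize("model", ["SL", "KStarSurrogate", "CSVC"])
    def test_metrics_match_sklearn_oracle(self, model):
        rng = np.random.default_rng(2)
        labels = (rng.random(80) < 0.6).astype(int)
        X = rng.normal(size=(80, 6)) + labels[:, None]
        res = cross_validate_classification(
            small_feature_matrix(X), labels, model, CVConfig(rng_seed=3)
        )
        p, r, f, _ = precision_recall_fscore_support(
            res.targets, res.predictions, average="binary", pos_label=1,
            zero_division=0.0,
        )
        assert res.precision == pytest.approx(p)
        assert res.recall == pytest.approx(r)
        assert res.f_measure == pytest.approx(f)

    def test_too_few_symptomatic_cases_signal(self):
        labels = np.array([0] * 60 + [1] * 4)
        X = np.random.default_rng(4).normal(size=(64, 5))
        with pytest.raises(TooFewCases, match="minority class"):
            cross_validate_classification(
                small_feature_matrix(X), labels, "SL", CVConfig(rng_seed=5)
            )


class TestPermutationPvalue:
    def test_correlated_pairs_give_small_p(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=100)
        preds = y + rng.normal(scale=0.5, size=100)
        p = modeling.permutation_pvalue(preds, y, n_permutations=2000, rng_seed=1)
        assert p < 0.01

    def test_independent_pairs_give_large_p(self):
        rng = np.random.default_rng(2)
        p = modeling.permutation_pvalue(
            rng.normal(size=100), rng.normal(size=100),
            n_permutations=2000, rng_seed=3,
        )
        assert p > 0.01


def study_inputs(n=90, seed=0, item9_positive=3):
    rng = np.random.default_rng(seed)
    fm = zscore(random_feature_matrix(n, rng))
    items = rng.integers(0, 3, size=(n, 9))
    items[:, 8] = 0
    items[:item9_positive, 8] = 1
    subjects = pd.DataFrame(
        {
            "subject_id": fm.subject_ids,
            "gender": np.where(rng.random(n) < 0.5, "male", "female"),
            "age": 24.0,
            "gad7": rng.integers(0, 21, size=n),
            "phq9": items.sum(axis=1),
        }
    )
    for i in range(9):
        subjects[f"phq9_item{i + 1}"] = items[:, i]
    return fm, subjects


@pytest.fixture(scope="module")
def tables():
    fm, subjects = study_inputs()
    config = CVConfig(rng_seed=7)
    return run_study(
        fm, subjects, config,
        regression_models=("SLR", "LR"),
        classification_models=("SL", "CSVC"),
    )


class TestRunStudy:
    def test_regression_table_layout(self, tables):
        reg = tables["regression"]
        assert set(reg.target) == {"gad7", "phq9"}
        # one row per target x stratum x model
        assert len(reg) == 2 * 3 * 2
        assert reg.r.between(-1, 1).all()

    def test_item9_marked_unavailable(self, tables):
        cls = tables["classification"]
        item9 = cls[cls.item == "phq9_item9"]
        assert (item9.note.str.contains("no valid results")).all()
        assert item9.precision.isna().all()

    def test_classification_metrics_in_range(self, tables):
        cls = tables["classification"]
        ok = cls[cls.note == ""]
        assert len(ok) > 0
        for col in ("precision", "recall", "f"):
            assert ok[col].between(0, 1).all()

    def test_identical_seed_reproduces_tables(self):
        fm, subjects = study_inputs(n=40, seed=1)
        kwargs = dict(
            regression_models=("LR",), classification_models=("SL",),
        )
        a = run_study(fm, subjects, CVConfig(rng_seed=3), **kwargs)
        b = run_study(fm, subjects, CVConfig(rng_seed=3), **kwargs)
        pd.testing.assert_frame_equal(a["regression"], b["regression"])
        pd.testing.assert_frame_equal(a["classification"], b["classification"])
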