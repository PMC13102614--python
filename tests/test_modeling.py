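import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from adspeech import synthetic
from adspeech.errors import DataError, EmptyInputError, InvalidConfigError
from adspeech.modeling import (FAMILIES, ConfusionCounts, ModelSpec,
                               bootstrap_fold_ci, classification_metrics,
                               confusion_counts, cross_validated_predictions,
                               default_model_specs, evaluate_models,
                               rank_area_metrics, _preprocess_fit)
from adspeech.selection import make_stratified_folds


def _labels(n_ad, n_chc):
    ids = [f"a{i}" for i in range(n_ad)] + [f"c{i}" for i in range(n_chc)]
    return pd.Series(["AD"] * n_ad + ["CHC"] * n_chc, index=ids)


# ---------------------------------------------------------------------------
# confusion counting


def test_all_correct_has_no_errors():
    c = confusion_counts(["AD", "AD", "CHC"], [0.9, 0.8, 0.1])
    assert (c.FP, c.FN) == (0, 0)
    assert (c.TP, c.TN) == (2, 1)


def test_boundary_probability_predicts_positive():
    c = confusion_counts(["AD", "CHC"], [0.5, 0.5], cut=0.5)
    assert (c.TP, c.FP, c.FN, c.TN) == (1, 1, 0, 0)


def test_four_balanced_errors_in_44():
    labels = ["AD"] * 22 + ["CHC"] * 22
    probs = [0.9] * 20 + [0.1] * 2 + [0.1] * 20 + [0.9] * 2
    c = confusion_counts(labels, probs)
    assert (c.TP, c.TN, c.FP, c.FN) == (20, 20, 2, 2)


def test_probabilities_outside_unit_interval_rejected():
    with pytest.raises(DataError):
        confusion_counts(["AD"], [1.2])


# ---------------------------------------------------------------------------
# metric formulas


def test_metrics_on_pooled_44_case_confusion():
    m = classification_metrics(ConfusionCounts(TP=20, TN=20, FP=2, FN=2))
    for k in ("accuracy", "sensitivity", "specificity", "f1"):
        assert m[k] == pytest.approx(20 / 22, abs=1e-12), k
    assert m["mcc"] == pytest.approx(18 / 22, abs=1e-12)


def test_perfect_and_inverted_predictions():
    perfect = classification_metrics(ConfusionCounts(10, 10, 0, 0))
    assert all(perfect[k] == 1.0 for k in perfect)
    a = classification_metrics(ConfusionCounts(7, 9, 3, 1))
    b = classification_metrics(ConfusionCounts(1, 3, 9, 7))  # total inversion
    assert b["mcc"] == pytest.approx(-a["mcc"], abs=1e-12)


def test_zero_denominator_conventions():
    m = classification_metrics(ConfusionCounts(0, 5, 0, 0))  # no positives
    assert m["f1"] == 0.0 and m["mcc"] == 0.0 and m["accuracy"] == 1.0
    with pytest.raises(EmptyInputError):
        classification_metrics(ConfusionCounts(0, 0, 0, 0))


def test_metric_formulas_match_independent_oracle_small_grid():
    """Spot equivalence with an oracle that expands each confusion matrix
    into label vectors and recomputes the metrics from first principles
    (MCC as the Pearson correlation of the two binary vectors)."""
    for tp, tn, fp, fn in itertools.product(range(4), repeat=4):
        if tp + tn + fp + fn == 0:
            continue
        mine = classification_metrics(ConfusionCounts(tp, tn, fp, fn))
        y = np.array([1] * tp + [0] * tn + [0] * fp + [1] * fn)
        p = np.array([1] * tp + [0] * tn + [1] * fp + [0] * fn)
        assert mine["accuracy"] == pytest.approx(np.mean(y == p), abs=1e-12)
        sens = np.mean(p[y == 1]) if tp + fn else 0.0
        spec = 1 - np.mean(p[y == 0]) if tn + fp else 0.0
        assert mine["sensitivity"] == pytest.approx(sens, abs=1e-12)
        assert mine["specificity"] == pytest.approx(spec, abs=1e-12)
        if y.std() > 0 and p.std() > 0:
            assert mine["mcc"] == pytest.approx(np.corrcoef(y, p)[0, 1],
                                                abs=1e-12)
        else:
            assert mine["mcc"] == 0.0


# ---------------------------------------------------------------------------
# rank-area metrics


def test_auroc_from_pairwise_concordance():
    m = rank_area_metrics([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1])
    assert m["auroc"] == pytest.approx(0.75)


def test_tied_scores_give_chance_auroc_and_prevalence_auprc():
    m = rank_area_metrics(["AD", "CHC", "CHC", "CHC"], [0.4] * 4)
    assert m["auroc"] == pytest.approx(0.5)
    assert m["auprc"] == pytest.approx(0.25)


def test_perfect_separation():
    m = rank_area_metrics(["AD", "AD", "CHC"], [0.9, 0.8, 0.2])
    assert m["auroc"] == 1.0 and m["auprc"] == 1.0


def test_single_class_raises():
    with pytest.raises(EmptyInputError):
        rank_area_metrics(["AD", "AD"], [0.2, 0.9])


def test_concordance_equals_curve_area_on_random_scores():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = int(rng.integers(6, 40))
        y = rng.integers(0, 2, size=n)
        if y.sum() in (0, n):
            continue
        p = np.round(rng.random(n), 2)  # coarse grid forces ties
        mine = rank_area_metrics(y, p)["auroc"]
        assert mine == pytest.approx(roc_auc_score(y, p), abs=1e-12)


# ---------------------------------------------------------------------------
# bootstrap confidence intervals


def test_degenerate_and_bounded_intervals():
    lo, hi = bootstrap_fold_ci([0.8, 0.8, 0.8], seed=0)
    assert (lo, hi) == pytest.approx((0.8, 0.8), abs=1e-12)
    vals = [0.6, 0.7, 0.9, 0.8, 1.0]
    lo, hi = bootstrap_fold_ci(vals, seed=1)
    assert min(vals) <= lo <= hi <= max(vals)
    with pytest.raises(DataError):
        bootstrap_fold_ci([0.5])


def test_bootstrap_matches_independent_reimplementation():
    vals = np.array([0.8, 0.9, 1.0, 0.9, 0.95])
    mine = bootstrap_fold_ci(vals, B=1000, seed=1)
    rng = np.random.default_rng(1)
    means = [vals[rng.integers(0, 5, size=5)].mean() for _ in range(1000)]
    lo, hi = np.quantile(means, [0.025, 0.975])
    assert mine == pytest.approx((lo, hi), abs=1e-12)


# ---------------------------------------------------------------------------
# cross-validated training


def _separable_cohort(n=40):
    rng = np.random.default_rng(3)
    y = _labels(n // 2, n // 2)
    X = pd.DataFrame(0.3 * rng.standard_normal((n, 3)),
                     columns=["a", "b", "c"], index=y.index)
    X["a"] = np.where(y == "AD", 4.0, -4.0) + 0.1 * rng.standard_normal(n)
    return X, y


def test_separable_cohort_perfectly_classified_by_logistic():
    X, y = _separable_cohort()
    folds = make_stratified_folds(y, k=5, seed=0)
    oof, models = cross_validated_predictions(
        X, y, ModelSpec(family="logistic_regression"), folds)
    assert len(models) == 5
    c = confusion_counts(oof["label"], oof["probability"])
    assert (c.FP, c.FN) == (0, 0)


def test_preprocessing_ignores_held_out_rows():
    X, y = _separable_cohort()
    Xa = X.to_numpy()
    Xb = Xa.copy()
    Xb[:4] = 1e6  # pretend these are a held-out fold
    tr = list(range(4, 20))
    for got, ref in zip(_preprocess_fit(Xa[tr]), _preprocess_fit(Xb[tr])):
        assert np.array_equal(got, ref)


def test_predictions_deterministic_per_seed():
    X, y = _separable_cohort()
    folds = make_stratified_folds(y, k=5, seed=0)
    spec = ModelSpec(family="random_forest")
    a, _ = cross_validated_predictions(X, y, spec, folds, seed=5)
    b, _ = cross_validated_predictions(X, y, spec, folds, seed=5)
    assert a["probability"].equals(b["probability"])


def test_non_finite_feature_is_a_named_data_error():
    X, y = _separable_cohort()
    X.loc[:, "b"] = np.inf
    folds = make_stratified_folds(y, k=5, seed=0)
    with pytest.raises(DataError, match="b"):
        cross_validated_predictions(X, y, ModelSpec(family="logistic_regression"),
                                    folds)


def test_unknown_family_rejected():
    with pytest.raises(InvalidConfigError):
        ModelSpec(family="perceptron")


# ---------------------------------------------------------------------------
# full evaluation report


def test_report_structure_five_families_seven_metrics(planted_cohort):
    X, y = planted_cohort
    stable = list(synthetic.DEFAULT_EFFECT_FEATURES)
    folds = make_stratified_folds(y, k=5, seed=0)
    reports = evaluate_models(X, y, stable, default_model_specs(),
                              folds=folds, seed=0, bootstrap_B=100)
    assert set(reports) == set(FAMILIES)
    for rep in reports.values():
        assert set(rep.mean) == {"accuracy", "f1", "sensitivity",
                                 "specificity", "mcc", "auroc", "auprc"}
        assert rep.pooled_confusion.total == 44
        # pooled counts equal the sum over folds by construction; mean/SD
        # recomputable from the stored fold values
        for m, vals in rep.fold_metrics.items():
            assert rep.mean[m] == pytest.approx(np.nanmean(vals))
        assert not rep.oof["probability"].isna().any()
        for m in ("accuracy", "f1", "sensitivity", "specificity",
                  "auroc", "auprc"):
            assert 0.0 <= rep.mean[m] <= 1.0
        assert -1.0 <= rep.mean["mcc"] <= 1.0
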