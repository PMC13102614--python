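"""Cross-validated classification and evaluation.

Five classifier families — regularized logistic regression, RBF-kernel
SVM, random forest, gradient-boosted trees and XGBoost — are trained on
the stable feature set under stratified k-fold cross-validation.  Inside
each fold, mean imputation and z-scaling are fit on the training split
only and applied to the held-out split, so no statistic of the test fold
leaks into preprocessing.  Hyperparameters are fixed across folds.

Evaluation covers accuracy, F1 (positive class = AD), sensitivity,
specificity, precision, Matthews correlation, AUROC (tie-aware pairwise
concordance) and AUPRC (step-interpolated average precision), reported
per fold and as mean +/- SD, plus a fold-aggregated confusion matrix and
95% percentile bootstrap confidence intervals obtained by resampling the
fold-level metric values with replacement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score
from sklearn.svm import SVC

from .errors import DataError, EmptyInputError, InvalidConfigError
from .selection import POSITIVE, FoldSplit, make_stratified_folds

FAMILIES = ("logistic_regression", "svm_rbf", "random_forest",
            "gradient_boosting", "xgboost")

METRIC_NAMES = ("accuracy", "f1", "sensitivity", "specificity",
                "mcc", "auroc", "auprc")


@dataclass(frozen=True)
class ModelSpec:
    """One classifier family with its fixed hyperparameters."""

    family: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise InvalidConfigError(f"unknown model family {self.family!r}")

    def build(self, seed: int = 0):
        hp = dict(self.hyperparameters)
        if self.family == "logistic_regression":
            return LogisticRegression(**{"max_iter": 3000, "class_weight": "balanced",
                                         "C": 0.5, **hp})
        if self.family == "svm_rbf":
            return SVC(**{"kernel": "rbf", "probability": True,
                          "class_weight": "balanced", "C": 1.0, "gamma": "scale",
                          "random_state": seed, **hp})
        if self.family == "random_forest":
            return RandomForestClassifier(**{"n_estimators": 200, "max_depth": 4,
                                             "class_weight": "balanced",
                                             "random_state": seed, **hp})
        if self.family == "gradient_boosting":
            return GradientBoostingClassifier(**{"n_estimators": 200,
                                                 "learning_rate": 0.05,
                                                 "max_depth": 3,
                                                 "random_state": seed, **hp})
        from xgboost import XGBClassifier
        return XGBClassifier(**{"n_estimators": 200, "learning_rate": 0.05,
                                "max_depth": 3, "eval_metric": "logloss",
                                "random_state": seed, **hp})


def default_model_specs() -> dict[str, ModelSpec]:
    """The five classifier configurations used throughout the package."""
    return {f: ModelSpec(family=f) for f in FAMILIES}


@dataclass
class ConfusionCounts:
    """Binary confusion counts with AD as the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.TN + other.TN,
                               self.FP + other.FP, self.FN + other.FN)

    def to_dict(self) -> dict:
        return {"TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN}


@dataclass
class MetricsReport:
    """Evaluation outputs of one classifier family."""

    family: str
    fold_metrics: dict          # metric -> list of per-fold values (NaN if undefined)
    mean: dict                  # metric -> mean over defined folds
    sd: dict                    # metric -> SD over defined folds
    ci: dict                    # metric -> (lo, hi) 95% fold-bootstrap CI
    pooled_confusion: ConfusionCounts
    pooled: dict                # metric -> pooled out-of-fold value
    roc_curve: list             # pooled (fpr, tpr) points
    pr_curve: list              # pooled (recall, precision) points
    oof: pd.DataFrame           # id, fold, label, probability, predicted

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "fold_metrics": {k: list(v) for k, v in self.fold_metrics.items()},
            "mean": dict(self.mean),
            "sd": dict(self.sd),
            "ci": {k: list(v) for k, v in self.ci.items()},
            "pooled_confusion": self.pooled_confusion.to_dict(),
            "pooled": dict(self.pooled),
            "roc_curve": [list(p) for p in self.roc_curve],
            "pr_curve": [list(p) for p in self.pr_curve],
            "oof": self.oof.reset_index().to_dict(orient="list"),
        }


# ---------------------------------------------------------------------------
# metric formulas


def confusion_counts(labels, probabilities, cut: float = 0.5) -> ConfusionCounts:
    """Threshold predicted probabilities (AD when p >= cut) and count."""
    y = np.asarray([1 if v == POSITIVE else int(v) if v in (0, 1) else 0
                    for v in labels])
    p = np.asarray(probabilities, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise DataError("probabilities must lie in [0, 1]")
    pred = (p >= cut).astype(int)
    return ConfusionCounts(
        TP=int(((pred == 1) & (y == 1)).sum()),
        TN=int(((pred == 0) & (y == 0)).sum()),
        FP=int(((pred == 1) & (y == 0)).sum()),
        FN=int(((pred == 0) & (y == 1)).sum()),
    )


def classification_metrics(c: ConfusionCounts) -> dict:
    """Accuracy, F1, sensitivity, specificity, precision and MCC.

    Zero-denominator conventions: precision, recall and F1 are 0 when
    their denominator vanishes; MCC is 0 when any factor of its
    denominator is 0.
    """
    if c.total == 0:
        raise EmptyInputError("confusion counts are all zero")
    tp, tn, fp, fn = c.TP, c.TN, c.FP, c.FN
    accuracy = (tp + tn) / c.total
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    specificity = tn / (tn + fp) if tn + fp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return {"accuracy": accuracy, "f1": f1, "sensitivity": recall,
            "specificity": specificity, "precision": precision, "mcc": mcc}


def rank_area_metrics(labels, probabilities) -> dict:
    """AUROC and AUPRC of a score vector.

    AUROC is the probability that a random positive outscores a random
    negative, ties counted one half (tie-aware Mann-Whitney concordance).
    AUPRC is step-interpolated average precision over recall.  Raises
    :class:`EmptyInputError` when only one class is present.
    """
    y = np.asarray([1 if v == POSITIVE else int(v) if v in (0, 1) else 0
                    for v in labels])
    p = np.asarray(probabilities, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise EmptyInputError("both classes required for rank-area metrics")
    ranks = rankdata(p)
    auroc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    auprc = float(average_precision_score(y, p))
    return {"auroc": float(auroc), "auprc": auprc}


def roc_points(labels, probabilities) -> list[tuple[float, float]]:
    from sklearn.metrics import roc_curve as _roc
    y = np.asarray([1 if v == POSITIVE else int(v) if v in (0, 1) else 0
                    for v in labels])
    fpr, tpr, _ = _roc(y, np.asarray(probabilities, dtype=float))
    return list(zip(fpr.tolist(), tpr.tolist()))


def pr_points(labels, probabilities) -> list[tuple[float, float]]:
    from sklearn.metrics import precision_recall_curve as _prc
    y = np.asarray([1 if v == POSITIVE else int(v) if v in (0, 1) else 0
                    for v in labels])
    prec, rec, _ = _prc(y, np.asarray(probabilities, dtype=float))
    return list(zip(rec.tolist(), prec.tolist()))


def bootstrap_fold_ci(fold_metric_values, B: int = 1000, level: float = 0.95,
                      seed: int = 0) -> tuple[float, float]:
    """Percentile CI of the mean metric from resampling folds.

    Fold-level metric values are resampled with replacement ``B`` times;
    the interval is the (1-level)/2 and 1-(1-level)/2 percentiles of the
    resampled means.
    """
    vals = np.asarray([v for v in fold_metric_values if not math.isnan(v)],
                      dtype=float)
    if len(vals) < 2:
        raise DataError("bootstrap CI requires at least 2 fold values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(vals), size=(B, len(vals)))
    means = vals[idx].mean(axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(means, [alpha, 1 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# cross-validated training


def _preprocess_fit(X_train: np.ndarray):
    """Mean-imputation values and z-scaling parameters from the training
    split only (leakage-safe)."""
    col_mean = np.nanmean(X_train, axis=0)
    if np.isnan(col_mean).any():
        raise DataError("a feature column is entirely missing in a training split")
    Xf = np.where(np.isnan(X_train), col_mean, X_train)
    mu = Xf.mean(axis=0)
    sd = Xf.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return col_mean, mu, sd


def _preprocess_apply(X, col_mean, mu, sd, columns) -> np.ndarray:
    Xf = np.where(np.isnan(X), col_mean, X)
    if not np.isfinite(Xf).all():
        bad = [columns[j] for j in np.argwhere(~np.isfinite(Xf))[:, 1]]
        raise DataError(f"non-finite feature after imputation: {sorted(set(bad))}")
    return (Xf - mu) / sd


def cross_validated_predictions(
    feature_table: pd.DataFrame,
    labels: pd.Series,
    model_spec: ModelSpec,
    folds: FoldSplit,
    seed: int = 0,
):
    """Out-of-fold AD probabilities under leakage-safe preprocessing.

    Returns ``(oof, models)``: a DataFrame (index id; columns fold, label,
    probability) and the list of per-fold fitted models.
    """
    ids = list(feature_table.index)
    X_all = feature_table.to_numpy(dtype=float)
    y_all = (labels.loc[ids].to_numpy() == POSITIVE).astype(int)
    pos = {pid: i for i, pid in enumerate(ids)}

    prob = pd.Series(np.nan, index=ids)
    fold_of = pd.Series(-1, index=ids, dtype=int)
    models = []
    for fold in range(folds.k):
        tr = [pos[i] for i in folds.train_ids(fold)]
        te = [pos[i] for i in folds.test_ids(fold)]
        col_mean, mu, sd = _preprocess_fit(X_all[tr])
        Xtr = _preprocess_apply(X_all[tr], col_mean, mu, sd, feature_table.columns)
        Xte = _preprocess_apply(X_all[te], col_mean, mu, sd, feature_table.columns)
        model = model_spec.build(seed=seed).fit(Xtr, y_all[tr])
        p = model.predict_proba(Xte)[:, list(model.classes_).index(1)]
        for j, i in enumerate(te):
            prob.iloc[i] = p[j]
            fold_of.iloc[i] = fold
        models.append(model)
    oof = pd.DataFrame({"fold": fold_of, "label": labels.loc[ids],
                        "probability": prob})
    oof.index.name = "id"
    return oof, models


def evaluate_model(
    feature_table: pd.DataFrame,
    labels: pd.Series,
    model_spec: ModelSpec,
    folds: FoldSplit,
    seed: int = 0,
    cut: float = 0.5,
    bootstrap_B: int = 1000,
) -> MetricsReport:
    """Full cross-validated evaluation of one classifier family."""
    oof, _ = cross_validated_predictions(feature_table, labels, model_spec,
                                         folds, seed=seed)
    fold_metrics: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    pooled_conf = ConfusionCounts(0, 0, 0, 0)
    for fold in range(folds.k):
        sub = oof[oof["fold"] == fold]
        conf = confusion_counts(sub["label"], sub["probability"], cut=cut)
        pooled_conf = pooled_conf + conf
        cm = classification_metrics(conf)
        for m in ("accuracy", "f1", "sensitivity", "specificity", "mcc"):
            fold_metrics[m].append(cm[m])
        try:
            ra = rank_area_metrics(sub["label"], sub["probability"])
            fold_metrics["auroc"].append(ra["auroc"])
            fold_metrics["auprc"].append(ra["auprc"])
        except EmptyInputError:
            warnings.warn(f"fold {fold} has a single class; AUROC/AUPRC "
                          "undefined and excluded from the fold mean",
                          stacklevel=2)
            fold_metrics["auroc"].append(float("nan"))
            fold_metrics["auprc"].append(float("nan"))

    mean = {m: float(np.nanmean(v)) for m, v in fold_metrics.items()}
    sd = {m: float(np.nanstd(v, ddof=1)) for m, v in fold_metrics.items()}
    ci = {m: bootstrap_fold_ci(v, B=bootstrap_B, seed=seed)
          for m, v in fold_metrics.items()}

    pooled = classification_metrics(pooled_conf)
    pooled.update(rank_area_metrics(oof["label"], oof["probability"]))
    oof_out = oof.copy()
    oof_out["predicted"] = np.where(oof["probability"] >= cut, POSITIVE, "CHC")
    return MetricsReport(
        family=model_spec.family,
        fold_metrics=fold_metrics, mean=mean, sd=sd, ci=ci,
        pooled_confusion=pooled_conf, pooled=pooled,
        roc_curve=roc_points(oof["label"], oof["probability"]),
        pr_curve=pr_points(oof["label"], oof["probability"]),
        oof=oof_out,
    )


def evaluate_models(
    feature_table: pd.DataFrame,
    labels: pd.Series,
    stable_set: list[str],
    model_specs: dict[str, ModelSpec] | None = None,
    folds: FoldSplit | None = None,
    seed: int = 0,
    bootstrap_B: int = 1000,
) -> dict[str, MetricsReport]:
    """Evaluate every classifier family on the stable feature set."""
    specs = model_specs or default_model_specs()
    split = folds or make_stratified_folds(labels, k=5, seed=seed)
    sub = feature_table[list(stable_set)]
    return {name: evaluate_model(sub, labels, spec, split, seed=seed,
                                 bootstrap_B=bootstrap_B)
            for name, spec in specs.items()}
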