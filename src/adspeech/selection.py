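"""Two-stage stability-based recursive feature elimination.

Stage one runs recursive feature elimination (RFE) with an L2-regularized
logistic-regression scorer separately inside each training split of a
stratified k-fold partition: features are standardized on the training
split, the model is fit, and the feature with the smallest absolute
coefficient is dropped, one per iteration, until ``m`` survive.  Stage two
aggregates the per-fold selections into selection frequencies; features
chosen in at least a threshold fraction of folds (default 0.6, i.e. 3 of
5) form the stable set.

The per-fold target size ``m`` must exceed the expected stable-set size;
the cross-fold aggregation then prunes fold-idiosyncratic picks.  Ties in
coefficient magnitude are broken deterministically by registry order (the
earlier registry index survives).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from . import registry
from .errors import InvalidConfigError, StratificationError

#: Positive class label.
POSITIVE = "AD"


@dataclass(frozen=True)
class FoldSplit:
    """A stratified k-fold partition of the cohort."""

    k: int
    assignments: dict  # participant id -> fold index
    seed: int

    def test_ids(self, fold: int) -> list:
        return [pid for pid, f in self.assignments.items() if f == fold]

    def train_ids(self, fold: int) -> list:
        return [pid for pid, f in self.assignments.items() if f != fold]


@dataclass
class SelectionResult:
    """Per-fold RFE selections, cross-fold frequencies and the stable set."""

    per_fold_selected: list  # k lists of feature codes
    frequency: dict          # code -> selected-fold fraction
    stable_set: list         # codes with frequency >= threshold, registry order
    threshold: float
    m: int

    def to_dict(self) -> dict:
        return {
            "per_fold_selected": [list(s) for s in self.per_fold_selected],
            "frequency": dict(self.frequency),
            "stable_set": list(self.stable_set),
            "threshold": self.threshold,
            "m": self.m,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionResult":
        return cls(per_fold_selected=[list(s) for s in d["per_fold_selected"]],
                   frequency=dict(d["frequency"]), stable_set=list(d["stable_set"]),
                   threshold=d["threshold"], m=d["m"])


def _rfe_estimator(seed: int | None = None) -> LogisticRegression:
    # scorer settings mirror the final logistic-regression model so that
    # selection and modeling agree on what "informative" means
    return LogisticRegression(max_iter=3000, class_weight="balanced", C=0.5)


def make_stratified_folds(labels: pd.Series, k: int = 5, seed: int = 0) -> FoldSplit:
    """Stratified k-fold partition preserving the class distribution.

    Per-fold class counts deviate from exact proportionality by at most
    one.  Deterministic for a fixed seed.
    """
    counts = labels.value_counts()
    if (counts < k).any():
        small = counts[counts < k]
        raise StratificationError(
            f"class(es) with fewer members than k={k}: {small.to_dict()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    ids = np.asarray(labels.index)
    assignments: dict = {}
    for fold, (_, test_idx) in enumerate(skf.split(ids, labels.to_numpy())):
        for i in test_idx:
            assignments[ids[i]] = fold
    return FoldSplit(k=k, assignments=assignments, seed=seed)


def rfe_rank(train_features: pd.DataFrame, train_labels: pd.Series,
             m: int, step: int = 1) -> list[str]:
    """Recursive feature elimination down to ``m`` features.

    Features are standardized on the training data once; at each iteration
    the logistic scorer is refit on the survivors and the ``step`` features
    with the smallest |coefficient| are dropped.  A constant (zero
    variance) feature cannot be standardized meaningfully and is dropped
    first.  Coefficient ties break by registry order: the earlier registry
    index survives.
    """
    cols = list(train_features.columns)
    if m >= len(cols):
        return cols
    if m < 1:
        raise InvalidConfigError("m must be >= 1")

    X = train_features.to_numpy(dtype=float)
    y = (train_labels.to_numpy() == POSITIVE).astype(int)

    constant = [c for i, c in enumerate(cols) if np.std(X[:, i]) == 0.0]
    surviving = [c for c in cols if c not in constant]
    if constant:
        import warnings
        warnings.warn(f"constant feature(s) dropped before RFE: {constant}",
                      stacklevel=2)
    if len(surviving) < m:
        return surviving

    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    col_idx = {c: i for i, c in enumerate(cols)}

    def reg_index(code: str) -> int:
        try:
            return registry.index(code)
        except Exception:
            return cols.index(code)

    while len(surviving) > m:
        idx = [col_idx[c] for c in surviving]
        est = _rfe_estimator().fit(Xs[:, idx], y)
        coefs = np.abs(est.coef_.ravel())
        n_drop = min(step, len(surviving) - m)
        # drop smallest |coef|; on ties the later registry index goes first
        order = sorted(range(len(surviving)),
                       key=lambda j: (coefs[j], -reg_index(surviving[j])))
        for j in sorted(order[:n_drop], reverse=True):
            del surviving[j]
    return surviving


def stability_select(
    feature_table: pd.DataFrame,
    labels: pd.Series,
    k: int = 5,
    m: int = 10,
    threshold: float = 0.6,
    seed: int = 0,
    folds: FoldSplit | None = None,
) -> SelectionResult:
    """Stability selection: per-fold RFE aggregated into a stable set.

    ``feature_table`` holds only feature columns (no label).  RFE runs on
    each training split independently (standardization refit per fold);
    ``frequency[f]`` is the fraction of folds selecting ``f`` and the
    stable set is ``{f : frequency[f] >= threshold}`` in registry order.
    """
    if not 0 < threshold <= 1:
        raise InvalidConfigError("threshold must be in (0, 1]")
    split = folds or make_stratified_folds(labels, k=k, seed=seed)
    per_fold: list[list[str]] = []
    for fold in range(split.k):
        tr = split.train_ids(fold)
        per_fold.append(rfe_rank(feature_table.loc[tr], labels.loc[tr], m=m))
    frequency = {c: sum(c in s for s in per_fold) / split.k
                 for c in feature_table.columns}
    stable = [c for c in feature_table.columns if frequency[c] >= threshold]
    stable.sort(key=lambda c: registry.index(c) if c in registry.CODES else 10**6)
    return SelectionResult(per_fold_selected=per_fold, frequency=frequency,
                           stable_set=stable, threshold=threshold, m=m)
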