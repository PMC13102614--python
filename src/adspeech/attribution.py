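"""Exact Shapley attribution of classifier predictions.

Each prediction is decomposed into a baseline expectation E[f(x)] over a
background set plus one additive contribution phi_i per feature, so that
``base + sum(phi) = f(x)`` exactly.  Two exact routes are provided:

* the **closed form for linear models**: with coefficients beta and
  background means mu, ``phi_i = beta_i * (x_i - mu_i)`` and
  ``base = beta . mu + intercept``;
* **exhaustive coalition enumeration** for arbitrary models: the Shapley
  formula over all 2^p coalitions with an interventional (marginal) value
  function ``v(S)`` = mean model output over background rows whose
  features in ``S`` are replaced by the explained point's values.
  Tractable at the stable-set sizes this pipeline produces (p <= 15);
  for linear models it reproduces the closed form and serves as the
  model-agnostic oracle.

The reference explained model is logistic regression refit on the full
cohort over the stable set, explained on the log-odds scale; the
background set is the training data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from . import registry
from .errors import DataError, TractabilityError

MAX_ENUM_FEATURES = 15


@dataclass
class AttributionResult:
    """Per-participant Shapley decompositions and global importance.

    ``phi`` has one row per explained participant and one column per
    feature; for every row ``base_value + phi.sum() = final_value`` to
    numerical precision.  ``global_share`` expresses each feature's mean
    |phi| as a percent of the total (shares sum to 100).
    """

    base_value: float
    phi: pd.DataFrame
    final_value: pd.Series

    @property
    def global_mean_abs(self) -> pd.Series:
        return self.phi.abs().mean(axis=0)

    @property
    def global_share(self) -> pd.Series:
        g = self.global_mean_abs
        return 100.0 * g / g.sum()

    def ranking(self) -> list[str]:
        """Features by descending mean |phi|; registry order breaks ties."""
        g = self.global_mean_abs
        return sorted(g.index,
                      key=lambda c: (-g[c], registry.index(c)
                                     if c in registry.CODES else 10**6))

    def to_dict(self) -> dict:
        return {"base_value": self.base_value,
                "phi": self.phi.reset_index().to_dict(orient="list"),
                "final_value": self.final_value.to_dict(),
                "global_mean_abs": self.global_mean_abs.to_dict(),
                "global_share": self.global_share.to_dict()}


def shapley_linear(coefficients, intercept: float, X, background_means,
                   index=None, columns=None) -> AttributionResult:
    """Closed-form Shapley attribution for a linear model.

    ``X`` may be one row or a matrix of explained points.  For a model
    linear in its features the exact Shapley value under a marginal
    background expectation is ``beta_i * (x_i - mu_i)``.
    """
    beta = np.asarray(coefficients, dtype=float).ravel()
    mu = np.asarray(background_means, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != beta.size or mu.size != beta.size:
        raise DataError(
            f"dimension mismatch: beta {beta.size}, mu {mu.size}, X {X.shape[1]}")
    phi = (X - mu) * beta
    base = float(beta @ mu + intercept)
    final = base + phi.sum(axis=1)
    idx = list(index) if index is not None else list(range(X.shape[0]))
    cols = list(columns) if columns is not None else list(range(beta.size))
    return AttributionResult(
        base_value=base,
        phi=pd.DataFrame(phi, index=idx, columns=cols),
        final_value=pd.Series(final, index=idx),
    )


def shapley_enumeration(model_fn, X, background, index=None,
                        columns=None) -> AttributionResult:
    """Exact Shapley values by exhaustive coalition enumeration.

    ``model_fn`` maps a feature matrix to a vector of model outputs (use
    the log-odds/decision function for classifiers).  ``background`` is
    the reference matrix defining the marginal expectation; ``v(S)`` is
    the mean output over background rows with the coalition's features
    overridden by the explained point.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    p = X.shape[1]
    if bg.shape[1] != p:
        raise DataError("background and X differ in feature count")
    if p > MAX_ENUM_FEATURES:
        raise TractabilityError(
            f"exact enumeration over 2^{p} coalitions is intractable; use "
            "the linear closed form or a sampling approximation")

    feats = list(range(p))
    weights = {s: math.factorial(s) * math.factorial(p - s - 1) / math.factorial(p)
               for s in range(p)}

    base = float(np.mean(model_fn(bg)))
    n_rows = X.shape[0]
    phi = np.zeros((n_rows, p))
    for r in range(n_rows):
        x = X[r]
        v: dict[frozenset, float] = {}
        for size in range(p + 1):
            for S in combinations(feats, size):
                mixed = bg.copy()
                mixed[:, list(S)] = x[list(S)]
                v[frozenset(S)] = float(np.mean(model_fn(mixed)))
        for i in feats:
            others = [f for f in feats if f != i]
            total = 0.0
            for size in range(p):
                for S in combinations(others, size):
                    fs = frozenset(S)
                    total += weights[size] * (v[fs | {i}] - v[fs])
            phi[r, i] = total

    idx = list(index) if index is not None else list(range(n_rows))
    cols = list(columns) if columns is not None else feats
    return AttributionResult(
        base_value=base,
        phi=pd.DataFrame(phi, index=idx, columns=cols),
        final_value=pd.Series(base + phi.sum(axis=1), index=idx),
    )


def global_importance(result: AttributionResult) -> pd.DataFrame:
    """Global importance table: mean |phi|, percent share, rank."""
    order = result.ranking()
    g = result.global_mean_abs
    share = result.global_share
    return pd.DataFrame({"mean_abs_phi": [g[c] for c in order],
                         "share_pct": [share[c] for c in order],
                         "rank": range(1, len(order) + 1)},
                        index=pd.Index(order, name="feature"))


def explain_case(base_value: float, contributions: dict) -> dict:
    """Waterfall decomposition of one prediction.

    Orders contributions by descending |phi| and accumulates from the
    baseline; the last cumulative value is the final model output.
    Returns ``{base, steps: [(feature, phi, cumulative)], final}``.
    """
    order = sorted(contributions, key=lambda c: -abs(contributions[c]))
    steps = []
    running = base_value
    for c in order:
        running += contributions[c]
        steps.append({"feature": c, "phi": float(contributions[c]),
                      "cumulative": float(running)})
    return {"base": float(base_value), "steps": steps, "final": float(running)}


def explain_logistic_refit(feature_table: pd.DataFrame, labels,
                           stable_set: list[str]) -> AttributionResult:
    """Reference attribution: logistic regression refit on the full cohort.

    The model is refit on z-scaled stable-set features over all
    participants and explained on the log-odds scale with the full cohort
    as background, matching the closed-form linear route.
    """
    from sklearn.linear_model import LogisticRegression

    from .selection import POSITIVE

    X = feature_table[list(stable_set)].to_numpy(dtype=float)
    y = (np.asarray(labels) == POSITIVE).astype(int)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    model = LogisticRegression(max_iter=3000, class_weight="balanced", C=0.5)
    model.fit(Z, y)
    return shapley_linear(model.coef_.ravel(), float(model.intercept_[0]),
                          Z, Z.mean(axis=0),
                          index=feature_table.index, columns=list(stable_set))
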