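"""Nonparametric validation of the linear mixed model.

A flexible regression is fitted to log active minutes with *all* DAG
predictors — flexible learners are insensitive to which covariates are
confounders, so no adjustment-set selection is needed — and its partial
dependence curves are compared against the LMM's marginal means.  Agreement
of trends between the deductive (linear, DAG-guided) and inductive
(tree-ensemble) routes supports the adjustment set and the linear model;
the comparison is one-way and is never iterated back into the linear model.

The per-dog grouping factor is emulated by backfitting, in the style of
mixed-effects random forests: the ensemble is fitted to the outcome minus
current dog intercepts, and the intercepts are re-estimated as shrunken
per-dog residual means (shrinkage ``n_i tau2 / (n_i tau2 + sigma2)`` with
moment-based variance components), alternating for a few rounds.  Plain
per-dog demeaning would wipe out the signal of dog-level covariates (breed
size, sex, age) before the trees ever saw it; the backfitting scheme leaves
that signal to the trees and lets the intercepts absorb only residual
dog-level deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy import stats

from .lmm import MarginalMeansTable

__all__ = [
    "FlexibleModel",
    "CurveComparison",
    "fit_flexible_model",
    "partial_dependence",
    "compare_marginal_curves",
]


@dataclass
class FlexibleModel:
    """Handle for a fitted tree-ensemble flexibility check."""

    backend: str
    booster: lgb.LGBMRegressor = field(repr=False)
    predictors: tuple[str, ...]
    group: str
    group_effects: pd.Series = field(repr=False)  # shrunken dog intercepts
    var_random: float
    var_residual: float
    categories: dict[str, list[str]] = field(repr=False, default_factory=dict)
    log_outcome: bool = True

    def _encode(self, data: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(index=data.index)
        for c in self.predictors:
            if c in self.categories:
                X[c] = pd.Categorical(
                    data[c].astype(str), categories=self.categories[c]
                )
            else:
                X[c] = np.asarray(data[c], dtype=float)
        return X

    def predict_log(self, data: pd.DataFrame, include_group: bool = True) -> np.ndarray:
        """Predicted log active minutes; the dog intercept is added when the
        dog is known, zero (the population level) otherwise."""
        pred = self.booster.predict(self._encode(data))
        if include_group:
            pred = pred + (
                self.group_effects.reindex(np.asarray(data[self.group]))
                .fillna(0.0)
                .to_numpy()
            )
        return pred


def fit_flexible_model(
    data: pd.DataFrame,
    predictors: Sequence[str],
    group: str = "dog_id",
    seed: int = 0,
    outcome: str = "active_minutes",
    log_outcome: bool = True,
    n_estimators: int = 400,
    learning_rate: float = 0.05,
    num_leaves: int = 31,
    n_backfit: int = 3,
) -> FlexibleModel:
    """Fit the gradient-boosted ensemble with backfitted dog intercepts.

    Deterministic under a fixed seed (single-threaded, no row/column
    subsampling).  Requires at least two grouping levels.
    """
    groups = np.asarray(data[group])
    codes, uniques = pd.factorize(groups)
    if len(uniques) < 2:
        raise ValueError("need at least two grouping levels")
    missing = [c for c in predictors if c not in data.columns]
    if missing:
        raise KeyError(f"predictors missing from data: {missing}")
    y = np.asarray(data[outcome], dtype=float)
    if log_outcome:
        if np.any(y <= 0):
            raise ValueError("outcome must be positive before logging")
        y = np.log(y)

    categories: dict[str, list[str]] = {}
    for c in predictors:
        s = data[c]
        if not pd.api.types.is_numeric_dtype(s) or isinstance(
            s.dtype, pd.CategoricalDtype
        ):
            categories[c] = sorted(map(str, pd.unique(s.astype(str))))

    booster = lgb.LGBMRegressor(
        n_estimators=n_estimators,
        learning_rate=learning_rate,
        num_leaves=num_leaves,
        random_state=int(seed),
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbose=-1,
    )
    model = FlexibleModel(
        backend="gbm-backfit",
        booster=booster,
        predictors=tuple(predictors),
        group=group,
        group_effects=pd.Series(0.0, index=uniques),
        var_random=0.0,
        var_residual=1.0,
        categories=categories,
        log_outcome=log_outcome,
    )
    X = model._encode(data)
    counts = np.bincount(codes).astype(float)
    u = np.zeros(len(uniques))
    tau2 = sigma2 = 1.0
    for _ in range(max(n_backfit, 1)):
        booster.fit(X, y - u[codes], categorical_feature=list(categories))
        resid = y - booster.predict(X)
        means = np.bincount(codes, weights=resid) / counts
        within = resid - means[codes]
        sigma2 = float(np.var(within)) if len(y) > len(uniques) else 1e-8
        between = float(np.var(means, ddof=1))
        tau2 = max(between - sigma2 / counts.mean(), 1e-8)
        u = means * (counts * tau2) / (counts * tau2 + sigma2)
    model.group_effects = pd.Series(u, index=uniques)
    model.var_random = tau2
    model.var_residual = sigma2
    return model


def partial_dependence(
    model: FlexibleModel,
    data: pd.DataFrame,
    focal: str,
    grid: Sequence,
) -> np.ndarray:
    """Response-scale partial dependence of the flexible model.

    For each grid point the focal column is overwritten across the whole
    dataset, population-level predictions (zero dog intercept) are averaged
    on the log scale and back-transformed.
    """
    out = np.empty(len(grid))
    work = data.copy()
    for i, g in enumerate(grid):
        work[focal] = g
        out[i] = float(
            np.exp(np.mean(model.predict_log(work, include_group=False)))
        )
    return out


@dataclass
class CurveComparison:
    focal: str
    grid: list
    lmm_predictions: np.ndarray
    flexible_predictions: np.ndarray
    max_abs_diff: float
    rank_correlation: float


def compare_marginal_curves(
    lmm_table: MarginalMeansTable,
    flex_model: FlexibleModel,
    data: pd.DataFrame,
    focal: str,
    grid: Sequence,
) -> CurveComparison:
    """Compare LMM marginal means with flexible-model partial dependence.

    The grids must match the LMM table exactly.  Reports the maximum
    absolute difference in predicted minutes and the Spearman rank
    correlation of the two curves.  Note the two curves average over
    covariates differently (reference grid vs data averaging), so level
    offsets are expected; the comparison is about trends.
    """
    grid = list(grid)
    if list(lmm_table.table["level"]) != grid or lmm_table.focal != focal:
        raise ValueError("grid/focal mismatch between LMM table and request")
    lmm_pred = lmm_table.table["prediction"].to_numpy()
    flex_pred = partial_dependence(flex_model, data, focal, grid)
    if len(grid) < 2 or np.allclose(lmm_pred, lmm_pred[0]) or np.allclose(
        flex_pred, flex_pred[0]
    ):
        rc = np.nan
    else:
        rc = float(stats.spearmanr(lmm_pred, flex_pred).statistic)
    return CurveComparison(
        focal=focal,
        grid=grid,
        lmm_predictions=lmm_pred,
        flexible_predictions=flex_pred,
        max_abs_diff=float(np.max(np.abs(lmm_pred - flex_pred))),
        rank_correlation=rc,
    )
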