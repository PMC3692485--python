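"""Cross-cell-type transfer of the expression model.

Signals measured in two cell types sit on different scales (depth,
antibody efficiency), so each shared variable is first put on the
reference cell's scale with a per-variable affine map derived from a
regression line between matched exons.  A model trained on the normalized
training cell is then applied to the reference cell, overall and within
subsets of exons whose expression changed by at least 2-, 5- or 10-fold
between the two cell types.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regress import FitResult, fit_linear, transfer_predict

logger = logging.getLogger(__name__)

__all__ = [
    "AffineMap",
    "fit_affine_normalizer",
    "fold_change_filter",
    "cross_cell_pipeline",
    "CrossCellResult",
]


@dataclass(slots=True)
class AffineMap:
    """Per-variable normalization ``x -> intercept + slope * x``.

    Fitted as the OLS regression line of the reference values on the source
    values over matched exons; applying it to the source turns that
    regression line into y = x.
    """

    variable: str
    slope: float
    intercept: float
    n: int

    def apply(self, values: pd.Series) -> pd.Series:
        return self.intercept + self.slope * values


def fit_affine_normalizer(
    source: pd.Series, reference: pd.Series, variable: str | None = None
) -> AffineMap:
    """Fit the affine map sending source values onto the reference scale.

    ``source`` and ``reference`` are matched by index; at least 3 matched
    rows and a non-constant source are required.
    """
    common = source.index.intersection(reference.index)
    if len(common) < 3:
        raise ValueError(f"need >= 3 matched rows, got {len(common)}")
    x = source.loc[common].to_numpy(dtype=float)
    y = reference.loc[common].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant source values; affine map undefined")
    res = stats.linregress(x, y)
    return AffineMap(
        variable=variable or (source.name or "variable"),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=len(common),
    )


def fold_change_filter(expr_a: pd.Series, expr_b: pd.Series, fold: float) -> list[str]:
    """Ids whose log2 expression differs by at least log2(fold) between cells.

    Inclusive at the boundary and symmetric in the two cells; unmatched ids
    are skipped with a warning.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    common = expr_a.index.intersection(expr_b.index)
    unmatched = len(expr_a.index.symmetric_difference(expr_b.index))
    if unmatched:
        logger.warning("%d unmatched ids skipped in fold-change filter", unmatched)
    delta = (expr_a.loc[common] - expr_b.loc[common]).abs()
    return sorted(common[delta >= math.log2(fold)])


@dataclass(slots=True)
class CrossCellResult:
    """Transfer-prediction outcome across cell types."""

    affine_maps: dict[str, AffineMap]
    fit: FitResult
    r_all: float
    p_all: float
    r_by_fold: dict[float, float | None]
    n_by_fold: dict[float, int]


def cross_cell_pipeline(
    train_signals: pd.DataFrame,
    train_expr: pd.Series,
    test_signals: pd.DataFrame,
    test_expr: pd.Series,
    shared_features: list[str] | None = None,
    folds: tuple[float, ...] = (2.0, 5.0, 10.0),
) -> CrossCellResult:
    """Normalize, train on one cell type, predict exon expression in the other.

    The training cell's variables (signals and expression) are affine-
    normalized onto the test (reference) cell's scale over matched exons;
    the expression model is fit on the normalized training cell and applied
    to the reference cell.  Pearson r is reported over all matched exons
    and within each fold-change-filtered subset (None when a subset is
    empty or too small to correlate).
    """
    if shared_features is None:
        shared_features = sorted(set(train_signals.columns) & set(test_signals.columns))
    if not shared_features:
        raise ValueError("no shared features between the two cell types")

    maps: dict[str, AffineMap] = {}
    norm_signals = pd.DataFrame(index=train_signals.index)
    for feat in shared_features:
        amap = fit_affine_normalizer(train_signals[feat], test_signals[feat], feat)
        maps[feat] = amap
        norm_signals[feat] = amap.apply(train_signals[feat])
    expr_map = fit_affine_normalizer(train_expr, test_expr, "expression")
    maps["expression"] = expr_map
    norm_expr = expr_map.apply(train_expr)

    fit = fit_linear(norm_signals[shared_features], norm_expr)

    common = test_signals.index.intersection(norm_signals.index)
    X_test = test_signals.loc[common, shared_features]
    y_test = test_expr.loc[common]
    r_all, p_all = transfer_predict(fit, X_test, y_test)

    r_by_fold: dict[float, float | None] = {}
    n_by_fold: dict[float, int] = {}
    for fold in folds:
        ids = fold_change_filter(y_test, norm_expr.loc[common], fold)
        n_by_fold[fold] = len(ids)
        if len(ids) < 3:
            logger.warning("fold %g filter kept %d exons; correlation reported as NA", fold, len(ids))
            r_by_fold[fold] = None
            continue
        r, _ = transfer_predict(fit, X_test.loc[ids], y_test.loc[ids])
        r_by_fold[fold] = r
    return CrossCellResult(
        affine_maps=maps,
        fit=fit,
        r_all=r_all,
        p_all=p_all,
        r_by_fold=r_by_fold,
        n_by_fold=n_by_fold,
    )
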