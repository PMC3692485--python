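"""Linear and interaction regression of expression on chromatin features.

The workhorse model relates a response (gene or exon expression, both log2
densities) to N chromatin-feature signals::

    e = b + sum_i a_i * h_i                       (main-effects, "singleton")
    e = b + sum_i a_i h_i + sum_{i<j} a_ij h_i h_j   (pairwise interactions)

Coefficients are tested with two-sided t-tests and Benjamini-Hochberg
adjusted across the coefficient family.  Predictive power is measured as
the mean Pearson r between held-out measured and predicted values over
seeded ten-fold cross-validation.  Features are not standardized, so
coefficients live on the raw log2-signal scale.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FitResult",
    "CVResult",
    "ModelComparison",
    "interaction_design",
    "fit_linear",
    "predict",
    "cross_validate",
    "shuffle_control",
    "improvement_ratio",
    "enumerate_combination_models",
    "transfer_predict",
    "bic_of_fit",
    "derangement",
]


@dataclass(slots=True)
class FitResult:
    """An ordinary-least-squares fit with coefficient inference.

    ``params`` is indexed by regressor name with ``"intercept"`` first;
    interaction regressors are named ``"A:B"``.  ``pvalues_adj`` holds
    Benjamini-Hochberg adjusted p-values over the non-intercept family.
    ``d`` counts regressors including the intercept.
    """

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    pvalues_adj: pd.Series
    rss: float
    m: int
    d: int
    feature_names: list[str]
    interactions: bool

    @property
    def intercept(self) -> float:
        return float(self.params["intercept"])

    def significant(self, alpha: float = 0.001) -> pd.Index:
        """Regressors whose BH-adjusted p-value falls below ``alpha``."""
        return self.pvalues_adj.index[self.pvalues_adj < alpha]

    def coefficient_table(self) -> pd.DataFrame:
        """Coefficient, SE, t, raw and adjusted p — one row per regressor."""
        return pd.DataFrame(
            {
                "coefficient": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
                "p_adj": self.pvalues_adj.reindex(self.params.index),
            }
        )


@dataclass(slots=True)
class CVResult:
    """Cross-validation outcome: seeded fold assignment and per-fold Pearson r."""

    fold_of_row: np.ndarray
    fold_r: list[float]
    k: int
    seed: int

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.fold_r))


@dataclass(slots=True)
class ModelComparison:
    """Singleton vs interaction model, compared by cross-validated Pearson r."""

    response: str
    features: list[str]
    p_singleton: float
    p_interaction: float

    @property
    def improvement_ratio(self) -> float:
        return improvement_ratio(self.p_singleton, self.p_interaction)


def interaction_design(X: pd.DataFrame) -> pd.DataFrame:
    """Append all C(N,2) pairwise products to the main-effect columns."""
    cols = {}
    names = list(X.columns)
    for a, b in itertools.combinations(names, 2):
        cols[f"{a}:{b}"] = X[a].to_numpy() * X[b].to_numpy()
    if not cols:
        return X.copy()
    return pd.concat([X, pd.DataFrame(cols, index=X.index)], axis=1)


def _check_rank(design: pd.DataFrame) -> None:
    arr = design.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # Identify offending columns via QR pivoting on the correlation structure.
        _, r = np.linalg.qr(arr)
        bad = [design.columns[i] for i in range(arr.shape[1]) if abs(r[i, i]) < 1e-8]
        raise ValueError(f"rank-deficient design; collinear columns: {bad or 'unidentified'}")


def fit_linear(X: pd.DataFrame, y: pd.Series | np.ndarray, interactions: bool = False) -> FitResult:
    """OLS of ``y`` on the features of ``X`` (optionally with pairwise products).

    Requires more rows than regressors and a full-rank design; coefficient
    p-values are BH-adjusted across the non-intercept family.
    """
    design = interaction_design(X) if interactions else X
    m, n_reg = design.shape
    d = n_reg + 1
    if m <= d:
        raise ValueError(f"need more rows than regressors: m={m}, d={d}")
    if design.isna().any().any():
        raise ValueError("design contains missing values")
    _check_rank(design)

    exog = sm.add_constant(design.to_numpy(), has_constant="add")
    res = sm.OLS(np.asarray(y, dtype=float), exog).fit()
    names = ["intercept"] + list(design.columns)
    params = pd.Series(res.params, index=names)
    pvals = pd.Series(res.pvalues, index=names)
    family = pvals.drop("intercept")
    if len(family):
        adj = pd.Series(
            multipletests(family.to_numpy(), method="fdr_bh")[1], index=family.index
        )
    else:
        adj = family
    return FitResult(
        params=params,
        bse=pd.Series(res.bse, index=names),
        tvalues=pd.Series(res.tvalues, index=names),
        pvalues=pvals,
        pvalues_adj=adj,
        rss=float(res.ssr),
        m=m,
        d=d,
        feature_names=list(X.columns),
        interactions=interactions,
    )


def predict(fit: FitResult, X: pd.DataFrame) -> np.ndarray:
    """Apply a fitted model to new feature data (columns matched by name)."""
    missing = [f for f in fit.feature_names if f not in X.columns]
    if missing:
        raise KeyError(f"missing features: {missing}")
    design = X[fit.feature_names]
    if fit.interactions:
        design = interaction_design(design)
    yhat = np.full(len(design), fit.intercept, dtype=float)
    for name, coef in fit.params.drop("intercept").items():
        yhat += coef * design[name].to_numpy()
    return yhat


def _make_folds(m: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random fold labels 0..k-1 covering all rows, sizes differing by <= 1."""
    base = np.repeat(np.arange(k), m // k)
    extra = rng.permutation(k)[: m % k]
    labels = np.concatenate([base, extra])
    return labels[rng.permutation(m)]


def cross_validate(
    X: pd.DataFrame,
    y: pd.Series,
    k: int = 10,
    seed: int = 0,
    interactions: bool = False,
    _derange_test_columns: np.ndarray | None = None,
) -> CVResult:
    """Seeded k-fold CV; score = mean Pearson r(measured, predicted) over folds.

    ``_derange_test_columns`` is the shuffle-control hook: a permutation
    applied to the held-out rows' feature columns before prediction, so the
    trained coefficients meet the wrong inputs.
    """
    m = len(X)
    if m < 2 * k:
        raise ValueError(f"need at least 2 rows per fold: m={m}, k={k}")
    rng = np.random.default_rng(seed)
    folds = _make_folds(m, k, rng)
    yarr = np.asarray(y, dtype=float)
    fold_r = []
    for f in range(k):
        test = folds == f
        fit = fit_linear(X.loc[~test], yarr[~test], interactions=interactions)
        X_test = X.loc[test]
        if _derange_test_columns is not None:
            X_test = pd.DataFrame(
                X_test.to_numpy()[:, _derange_test_columns],
                index=X_test.index,
                columns=X_test.columns,
            )
        yhat = predict(fit, X_test)
        y_test = yarr[test]
        if np.ptp(y_test) == 0 or np.ptp(yhat) == 0:
            raise ValueError(
                f"fold {f}: constant response or prediction; Pearson r undefined "
                "(use larger folds or more variable data)"
            )
        fold_r.append(float(stats.pearsonr(y_test, yhat)[0]))
    return CVResult(fold_of_row=folds, fold_r=fold_r, k=k, seed=seed)


def derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """A uniform fixed-point-free permutation of ``range(n)`` by rejection."""
    if n < 2:
        raise ValueError("no derangement exists for n < 2")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def shuffle_control(X: pd.DataFrame, y: pd.Series, k: int = 10, seed: int = 0) -> CVResult:
    """Cross-validate with deranged inputs at prediction time.

    Models are trained on correctly-ordered feature columns; the held-out
    rows then have their columns reassigned by a seeded derangement, so no
    feature reaches the coefficient estimated for it.  A model that truly
    reads its inputs collapses toward chance under this control.
    """
    n = X.shape[1]
    rng = np.random.default_rng(seed)
    perm = derangement(n, rng)
    return cross_validate(X, y, k=k, seed=seed, _derange_test_columns=perm)


def improvement_ratio(p_singleton: float, p_interaction: float) -> float:
    """(P_singleton - P_interaction) / P_singleton.

    Positive when the singleton (main-effects) model predicts better;
    negative when interaction terms genuinely help.
    """
    if p_singleton == 0:
        raise ZeroDivisionError("singleton correlation is zero; ratio undefined")
    return (p_singleton - p_interaction) / p_singleton


def enumerate_combination_models(
    X: pd.DataFrame,
    y: pd.Series,
    sizes: tuple[int, ...] = (1, 2),
    k: int = 10,
    seed: int = 0,
) -> tuple[list[tuple[tuple[str, ...], float]], float]:
    """CV score for every feature combination of the given sizes.

    Returns (sorted ascending list of ((features...), mean r), full-model r)
    — the full-model r is the reference line the per-combination scores are
    read against.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least two features to enumerate combinations")
    results = []
    for size in sizes:
        for combo in itertools.combinations(X.columns, size):
            cv = cross_validate(X[list(combo)], y, k=k, seed=seed)
            results.append((combo, cv.mean_r))
    results.sort(key=lambda t: (t[1], t[0]))
    full_r = cross_validate(X, y, k=k, seed=seed).mean_r
    return results, full_r


def transfer_predict(fit: FitResult, X_new: pd.DataFrame, y_new: pd.Series) -> tuple[float, float]:
    """Apply a trained model to new data; Pearson r and its t-test p-value."""
    yhat = predict(fit, X_new)
    r, _ = stats.pearsonr(np.asarray(y_new, dtype=float), yhat)
    m = len(y_new)
    if 1 - r * r <= 0:
        return float(r), 0.0
    t = r * math.sqrt(m - 2) / math.sqrt(1 - r * r)
    p = 2 * stats.t.sf(abs(t), df=m - 2)
    return float(r), float(p)


def bic_of_fit(fit: FitResult) -> float:
    """Bayesian information criterion of an OLS fit.

    Gaussian likelihood at the MLE variance RSS/m gives
    BIC = m*(ln(2*pi*RSS/m) + 1) + d*ln(m), with d counting the intercept.
    A numerically zero RSS (perfectly interpolated response) is rejected:
    the Gaussian likelihood is degenerate there.
    """
    if fit.rss <= 1e-8 * fit.m:
        raise ValueError("RSS is (numerically) zero; Gaussian likelihood degenerate")
    m = fit.m
    return m * (math.log(2 * math.pi * fit.rss / m) + 1) + fit.d * math.log(m)
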