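"""Exponential regression modelling and statistical evaluation.

The biomass models are simple (one predictor) and multiple exponential
regressions of the form

    Y = a * exp(b_1 x_1 + ... + b_k x_k),   a > 0,

fitted by ordinary least squares on the log-transformed response
(``ln Y = ln a + sum b_j x_j``), i.e. a multiplicative error model.  Model
quality is reported as the fold-averaged RMSE of k-fold cross-validation,
the sample standard deviation of the fold RMSEs, and the Pearson r between
predictions and measurements on a held-out test set.  Predictor pairs are
screened for collinearity before entering a multiple model (|r| below an
admissibility threshold, default 0.69).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.model_selection import KFold

__all__ = [
    "ExponentialModel",
    "EvalResult",
    "CorrelationMatrix",
    "TTestResult",
    "UndefinedCorrelationError",
    "rmse",
    "std",
    "pearson_r",
    "fit_exponential",
    "predict",
    "train_test_split",
    "kfold_cv",
    "correlation_matrix",
    "admissible_predictor_sets",
    "treatment_ttest",
    "correlate_vi_with_lab",
    "evaluate_on_test",
]


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined (a constant vector)."""


@dataclass(frozen=True)
class ExponentialModel:
    """Y = a * exp(sum_j b_j x_j) with positive multiplicative coefficient."""

    response: str
    predictors: tuple[str, ...]
    a: float
    b: np.ndarray
    method: str = "log_ols"

    def __post_init__(self) -> None:
        object.__setattr__(self, "b", np.atleast_1d(np.asarray(self.b, dtype=float)))
        if len(self.predictors) < 1 or len(self.predictors) != len(self.b):
            raise ValueError("need one rate coefficient per predictor")
        if not self.a > 0:
            raise ValueError("multiplicative coefficient a must be > 0")

    def formula(self) -> str:
        terms = " + ".join(
            f"{bj:.4g} x {name}" for bj, name in zip(self.b, self.predictors)
        )
        return f"Y = {self.a:.4g} x e^({terms})"


@dataclass
class EvalResult:
    """RMSE / fold-spread / Pearson r summary of a model or trait pair."""

    rmse: float
    std: float | None = None
    r: float | None = None
    p_value: float | None = None
    n: int = 0
    fold_rmses: list[float] = field(default_factory=list)


@dataclass
class CorrelationMatrix:
    matrix: pd.DataFrame
    threshold: float = 0.69

    @property
    def names(self) -> list[str]:
        return list(self.matrix.columns)


@dataclass
class TTestResult:
    t: float
    p_value: float
    group_means: tuple[float, float]
    group_sizes: tuple[int, int]


def rmse(predicted, measured) -> float:
    """Root mean square error sqrt(mean((P_i - M_i)^2))."""
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.shape != m.shape or p.ndim != 1 or p.size < 1:
        raise ValueError("predicted and measured must be equal-length 1-d vectors")
    return float(np.sqrt(np.mean((p - m) ** 2)))


def std(values) -> float:
    """Sample standard deviation with the n-1 denominator."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need at least two values")
    return float(np.std(x, ddof=1))


def pearson_r(measured, predicted) -> tuple[float, float]:
    """Pearson product-moment correlation and its two-sided p-value.

    The p-value comes from the t transform with n-2 degrees of freedom.
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape or m.ndim != 1 or m.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(m) == 0 or np.ptp(p) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    res = stats.pearsonr(m, p)
    return float(res.statistic), float(res.pvalue)


def _design(X, predictors: Sequence[str] | None):
    if isinstance(X, pd.DataFrame):
        if predictors is None:
            predictors = list(X.columns)
        mat = X.loc[:, list(predictors)].to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        if predictors is None:
            predictors = [f"x{j + 1}" for j in range(mat.shape[1])]
    return mat, tuple(predictors)


def fit_exponential(
    X, y, predictors: Sequence[str] | None = None, response: str = "y",
    method: str = "log_ols",
) -> ExponentialModel:
    """Fit Y = a*exp(sum b_j x_j) to strictly positive responses.

    ``log_ols`` (default) performs ordinary least squares on ln(y)
    (multiplicative error); ``nls`` refines the log-OLS solution by
    nonlinear least squares on the original scale (additive error),
    offered for sensitivity analysis.
    """
    mat, names = _design(X, predictors)
    yv = np.asarray(y, dtype=float)
    if yv.ndim != 1 or yv.size != mat.shape[0]:
        raise ValueError("y must be a vector matching X's rows")
    if np.any(yv <= 0):
        raise ValueError("response must be strictly positive for an exponential fit")
    n, k = mat.shape
    if n <= k + 1:
        raise ValueError(f"need more than k+1={k + 1} samples, got {n}")
    A = np.column_stack([np.ones(n), mat])
    if np.linalg.matrix_rank(A) < k + 1:
        raise np.linalg.LinAlgError("predictor matrix is collinear")
    coef, *_ = np.linalg.lstsq(A, np.log(yv), rcond=None)
    a, b = math.exp(coef[0]), coef[1:]
    if method == "nls":
        def resid(theta):
            return theta[0] * np.exp(mat @ theta[1:]) - yv

        sol = optimize.least_squares(resid, x0=np.concatenate([[a], b]))
        a, b = float(sol.x[0]), sol.x[1:]
    elif method != "log_ols":
        raise ValueError(f"unknown method {method!r}")
    return ExponentialModel(response=response, predictors=names, a=float(a), b=b,
                            method=method)


def predict(model: ExponentialModel, X) -> np.ndarray:
    """Evaluate Y = a*exp(sum b_j x_j) row-wise."""
    if isinstance(X, pd.DataFrame):
        missing = [p for p in model.predictors if p not in X.columns]
        if missing:
            raise ValueError(f"X lacks predictor column(s) {missing}")
        mat = X.loc[:, list(model.predictors)].to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        if mat.shape[1] != len(model.predictors):
            raise ValueError(
                f"X has {mat.shape[1]} columns, model expects {len(model.predictors)}"
            )
    return model.a * np.exp(mat @ model.b)


def train_test_split(n: int, test_fraction: float = 0.2, seed: int | None = None):
    """Seeded random split into train/test index arrays (default 4:1)."""
    if n < 5:
        raise ValueError("need n >= 5 for a train/test split")
    n_test = int(round(n * test_fraction))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test = np.sort(perm[:n_test])
    train = np.sort(perm[n_test:])
    return train, test


def kfold_cv(
    X, y, k: int = 10, seed: int | None = None,
    predictors: Sequence[str] | None = None, response: str = "y",
) -> EvalResult:
    """k-fold cross-validation of the exponential model.

    Folds are a seeded random partition into k near-equal parts; the
    reported RMSE is the mean of the k held-out-fold RMSEs and ``std`` their
    sample standard deviation.
    """
    mat, names = _design(X, predictors)
    yv = np.asarray(y, dtype=float)
    n = yv.size
    if k < 2 or n < k:
        raise ValueError("need n >= k >= 2")
    kf = KFold(n_splits=k, shuffle=True, random_state=None if seed is None else int(seed))
    fold_rmses = []
    for tr, te in kf.split(mat):
        model = fit_exponential(mat[tr], yv[tr], predictors=names, response=response)
        fold_rmses.append(rmse(predict(model, mat[te]), yv[te]))
    return EvalResult(
        rmse=float(np.mean(fold_rmses)),
        std=std(fold_rmses) if len(fold_rmses) >= 2 else 0.0,
        n=n,
        fold_rmses=fold_rmses,
    )


def correlation_matrix(
    table: pd.DataFrame, columns: Sequence[str] | None = None, threshold: float = 0.69
) -> CorrelationMatrix:
    """Pairwise Pearson correlations over complete rows."""
    cols = list(columns) if columns is not None else list(table.columns)
    sub = table.loc[:, cols].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 complete rows")
    for c in cols:
        if np.ptp(sub[c].to_numpy(dtype=float)) == 0:
            raise UndefinedCorrelationError(f"column {c!r} is constant")
    mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, j in itertools.combinations(range(len(cols)), 2):
        r, _ = pearson_r(sub[cols[i]], sub[cols[j]])
        mat.iloc[i, j] = mat.iloc[j, i] = r
    return CorrelationMatrix(mat, threshold=threshold)


def admissible_predictor_sets(
    corr: CorrelationMatrix | pd.DataFrame,
    threshold: float = 0.69,
    extra_sets: Iterable[Sequence[str]] = (),
) -> tuple[list[tuple[str, ...]], list[tuple[tuple[str, ...], str]]]:
    """Predictor sets whose every internal pair satisfies |r| < threshold.

    Returns all admissible unordered pairs in matrix column order, followed
    by any caller-supplied larger sets that pass the same pairwise screen,
    plus a list of (set, reason) rejections.
    """
    mat = corr.matrix if isinstance(corr, CorrelationMatrix) else corr
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    names = list(mat.columns)
    sets: list[tuple[str, ...]] = []
    rejected: list[tuple[tuple[str, ...], str]] = []
    for i, j in itertools.combinations(range(len(names)), 2):
        if abs(mat.iloc[i, j]) < threshold:
            sets.append((names[i], names[j]))
    for extra in extra_sets:
        extra = tuple(extra)
        unknown = [p for p in extra if p not in names]
        if unknown:
            raise ValueError(f"unknown trait(s) in extra set: {unknown}")
        bad = [
            (p, q, mat.loc[p, q])
            for p, q in itertools.combinations(extra, 2)
            if abs(mat.loc[p, q]) >= threshold
        ]
        if bad:
            p, q, r = bad[0]
            rejected.append((extra, f"|r({p},{q})| = {abs(r):.2f} >= {threshold}"))
        else:
            sets.append(extra)
    return sets, rejected


def treatment_ttest(values, groups, equal_var: bool = True) -> TTestResult:
    """Two-sample Student's t-test (pooled variance; Welch via flag)."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError(f"need exactly two groups, got {levels.size}")
    x1, x2 = v[g == levels[0]], v[g == levels[1]]
    if min(x1.size, x2.size) < 2:
        raise ValueError("each group needs at least two observations")
    res = stats.ttest_ind(x1, x2, equal_var=equal_var)
    return TTestResult(
        t=float(res.statistic),
        p_value=float(res.pvalue),
        group_means=(float(x1.mean()), float(x2.mean())),
        group_sizes=(int(x1.size), int(x2.size)),
    )


def correlate_vi_with_lab(
    traits: pd.DataFrame,
    lab: pd.DataFrame,
    vi_columns: Sequence[str],
    lab_columns: Sequence[str],
    on: Sequence[str] = ("plot_id",),
) -> pd.DataFrame:
    """Pearson r between plot-mean VIs and lab-measured leaf traits.

    Records are matched on ``on`` (plot id, optionally also a date column)
    and pooled across dates before correlating.  Pairs with fewer than three
    matched records are flagged (``r`` NaN) rather than computed; the count
    of unmatched records is reported in the ``n_unmatched`` column.
    """
    on = list(on)
    merged = traits.merge(lab, on=on, how="inner", suffixes=("", "_lab"))
    n_unmatched = len(lab) - len(merged)
    rows = []
    for vi in vi_columns:
        for trait in lab_columns:
            sub = merged[[vi, trait]].dropna()
            if len(sub) < 3:
                rows.append(
                    {"vi": vi, "lab_trait": trait, "r": np.nan, "p_value": np.nan,
                     "n": len(sub), "n_unmatched": n_unmatched, "flagged": True}
                )
                continue
            r, p = pearson_r(sub[vi], sub[trait])
            rows.append(
                {"vi": vi, "lab_trait": trait, "r": r, "p_value": p,
                 "n": len(sub), "n_unmatched": n_unmatched, "flagged": False}
            )
    return pd.DataFrame(rows)


def evaluate_on_test(model: ExponentialModel, X_test, y_test) -> EvalResult:
    """RMSE and Pearson r of model predictions on a held-out test set.

    If the predictions are constant the correlation is undefined; RMSE is
    still reported and ``r`` is left as NaN.
    """
    pred = predict(model, X_test)
    yv = np.asarray(y_test, dtype=float)
    err = rmse(pred, yv)
    if yv.size < 3:
        r, p = float("nan"), float("nan")
    else:
        try:
            r, p = pearson_r(yv, pred)
        except UndefinedCorrelationError:
            r, p = float("nan"), float("nan")
    return EvalResult(rmse=err, r=r, p_value=p, n=yv.size)
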