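"""Population statistics over a cohort table.

Descriptive parameter tables, stratified scatter regressions, the pairwise
Spearman correlation matrix, analysis of covariance via explicit nested
linear models, and gradient-boosted-tree predictor importances for the
alignment parameters.  All routines consume the cohort DataFrame produced
by :mod:`spinemetrics.cohort`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DescriptiveRow",
    "FitResult",
    "AncovaResult",
    "descriptive_table",
    "fit_by_stratum",
    "spearman_matrix",
    "ancova",
    "gb_importance",
    "DEFAULT_GB_PARAMS",
    "IMPORTANCE_TARGETS",
    "IMPORTANCE_PREDICTORS",
]


# ---------------------------------------------------------------------------
# Descriptive table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DescriptiveRow:
    parameter: str
    unit: str
    min: float
    max: float
    mean: float
    median: float


_UNITS = {"sva": "cm"}


def descriptive_table(cohort: pd.DataFrame,
                      parameters: list[str]) -> list[DescriptiveRow]:
    """Range, mean and median of each parameter column.

    The median of an even-length column is the mid-mean of the two central
    order statistics.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rows = []
    for p in parameters:
        col = cohort[p].to_numpy(dtype=float)
        rows.append(
            DescriptiveRow(
                parameter=p,
                unit=_UNITS.get(p, "degrees"),
                min=float(col.min()),
                max=float(col.max()),
                mean=float(col.mean()),
                median=float(np.median(col)),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Stratified regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    stratum: str
    slope: float
    intercept: float
    r: float
    n: int
    ok: bool = True
    note: str = ""


def fit_by_stratum(
    cohort: pd.DataFrame,
    x: str,
    y: str,
    stratum_var: str | None = None,
    filter: pd.Series | None = None,
) -> list[FitResult]:
    """Ordinary least squares of ``y`` on ``x`` within each stratum level.

    ``filter`` (a boolean mask, e.g. ``~cohort.deformity``) is applied
    first.  A stratum with constant ``x`` yields a flagged result rather
    than an exception.
    """
    df = cohort if filter is None else cohort.loc[np.asarray(filter, bool)]
    groups = (
        [("all", df)] if stratum_var is None
        else [(str(k), g) for k, g in df.groupby(stratum_var, observed=True)]
    )
    results = []
    for label, g in groups:
        xv = g[x].to_numpy(dtype=float)
        yv = g[y].to_numpy(dtype=float)
        if len(xv) < 2:
            results.append(FitResult(label, np.nan, np.nan, np.nan, len(xv),
                                     ok=False, note="fewer than 2 points"))
            continue
        if np.ptp(xv) == 0:
            results.append(FitResult(label, np.nan, float(np.mean(yv)), np.nan,
                                     len(xv), ok=False, note="constant x"))
            continue
        res = sps.linregress(xv, yv)
        results.append(FitResult(label, float(res.slope), float(res.intercept),
                                 float(res.rvalue), len(xv)))
    return results


# ---------------------------------------------------------------------------
# Spearman matrix
# ---------------------------------------------------------------------------

def spearman_matrix(cohort: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Pairwise Spearman rank correlations (average ranks for ties).

    Symmetric with unit diagonal; entries involving a constant variable are
    reported as NaN.
    """
    data = cohort[variables].dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 complete cases")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns -> NaN, reported
        rho = sps.spearmanr(data.to_numpy(dtype=float)).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-variable case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    np.fill_diagonal(rho, 1.0)
    for j, v in enumerate(variables):
        if data[v].nunique() <= 1:
            rho[j, :] = np.nan
            rho[:, j] = np.nan
    return pd.DataFrame(rho, index=variables, columns=variables)


# ---------------------------------------------------------------------------
# ANCOVA via explicit nested linear models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AncovaResult:
    response: str
    factor: str
    covariates: tuple
    F: float
    df_between: int
    df_residual: int
    p: float


def _design(df: pd.DataFrame, covariates: list[str],
            factor: str | None) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for c in covariates:
        cols.append(df[c].to_numpy(dtype=float))
        names.append(c)
    if factor is not None:
        levels = sorted(df[factor].astype(str).unique())
        for lv in levels[1:]:  # treatment coding, first level as reference
            cols.append((df[factor].astype(str) == lv).to_numpy(dtype=float))
            names.append(f"{factor}[{lv}]")
    return np.column_stack(cols), names


def _sse(X: np.ndarray, y: np.ndarray, names: list[str]) -> tuple[float, int]:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by rank-revealing QR on the column order
        aliased = []
        kept = np.empty((X.shape[0], 0))
        for j, name in enumerate(names):
            cand = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(cand) > kept.shape[1]:
                kept = cand
            else:
                aliased.append(name)
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), X.shape[1]


def ancova(cohort: pd.DataFrame, response: str, factor: str,
           covariates: list[str]) -> AncovaResult:
    """F-test of the factor given the covariates (nested linear models).

    Full model: covariates + factor dummies; reduced model: covariates
    only.  F = [(SSE_r − SSE_f)/Δdf] / [SSE_f/df_f], p from the F
    distribution.  Affine rescaling of the response or any covariate leaves
    F unchanged.
    """
    df = cohort.dropna(subset=[response, factor, *covariates])
    levels = df[factor].astype(str).nunique()
    if levels < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels")
    y = df[response].to_numpy(dtype=float)
    X_full, names_full = _design(df, covariates, factor)
    X_red, names_red = _design(df, covariates, None)
    sse_f, p_full = _sse(X_full, y, names_full)
    sse_r, p_red = _sse(X_red, y, names_red)
    df_between = p_full - p_red
    df_residual = len(df) - p_full
    if df_residual <= 0:
        raise ValueError("not enough observations for the full model")
    num = (sse_r - sse_f) / df_between
    den = sse_f / df_residual
    F = max(num / den, 0.0) if den > 0 else np.inf
    p = float(sps.f.sf(F, df_between, df_residual))
    return AncovaResult(response=response, factor=factor,
                        covariates=tuple(covariates), F=float(F),
                        df_between=df_between, df_residual=df_residual, p=p)


# ---------------------------------------------------------------------------
# Boosted-tree predictor importance
# ---------------------------------------------------------------------------

IMPORTANCE_TARGETS = ("ll_l1l5", "tk_t4t12", "sva", "pi_ll", "tpa",
                      "cobb_angle", "rot_angle")
IMPORTANCE_PREDICTORS = ("age", "sex", "pi", "ss", "ll_l1l5", "tk_t4t12",
                         "sva", "cobb_angle", "rot_angle")

#: fixed hyperparameters: small trees, moderate shrinkage, deterministic
DEFAULT_GB_PARAMS = {
    "n_estimators": 200,
    "max_depth": 3,
    "learning_rate": 0.1,
    "subsample": 1.0,
    "random_state": 0,
    "n_jobs": 1,
}

#: targets that are linear combinations of specific predictors; the
#: component predictors are withheld along with the target itself
_ALIASES = {"pi_ll": ("pi", "ll_l1l5")}


def gb_importance(
    cohort: pd.DataFrame,
    group_split_age: float = 19.0,
    targets: tuple = IMPORTANCE_TARGETS,
    predictors: tuple = IMPORTANCE_PREDICTORS,
    backend: str = "gain",
    gb_params: dict | None = None,
    min_group_size: int = 50,
) -> dict[str, pd.DataFrame]:
    """Per-group predictor-importance matrices for the alignment parameters.

    The cohort is split into adolescents (age < ``group_split_age``) and
    adults.  For each target a gradient-boosted regression-tree model is
    fit on all predictors except the target itself (and any predictor the
    target is defined from); importances are gain-based (``backend="gain"``)
    or permutation-based (``backend="permutation"``), normalized to sum to
    1 per row.  Groups smaller than ``min_group_size`` yield a warning and
    an all-NaN matrix.
    """
    from xgboost import XGBRegressor

    params = {**DEFAULT_GB_PARAMS, **(gb_params or {})}
    out = {}
    groups = {
        "adolescent": cohort[cohort["age"] < group_split_age],
        "adult": cohort[cohort["age"] >= group_split_age],
    }
    for label, g in groups.items():
        mat = pd.DataFrame(0.0, index=list(targets), columns=list(predictors))
        if len(g) < min_group_size:
            warnings.warn(
                f"group {label!r} has {len(g)} < {min_group_size} subjects; "
                "importances omitted"
            )
            out[label] = mat.replace(0.0, np.nan)
            continue
        X_all = g[list(predictors)].copy()
        if "sex" in X_all:
            X_all["sex"] = (X_all["sex"].astype(str) == "F").astype(float)
        for target in targets:
            cols = [p for p in predictors
                    if p != target and p not in _ALIASES.get(target, ())]
            X = X_all[cols].to_numpy(dtype=float)
            y = g[target].to_numpy(dtype=float)
            model = XGBRegressor(**params)
            model.fit(X, y)
            if backend == "gain":
                booster = model.get_booster()
                gain = booster.get_score(importance_type="gain")
                imp = np.array([gain.get(f"f{j}", 0.0) for j in range(len(cols))])
            elif backend == "permutation":
                from sklearn.inspection import permutation_importance

                r = permutation_importance(
                    model, X, y, n_repeats=5,
                    random_state=params.get("random_state", 0),
                )
                imp = np.clip(r.importances_mean, 0.0, None)
            else:
                raise ValueError(f"unknown backend {backend!r}")
            total = imp.sum()
            if total > 0:
                imp = imp / total
            mat.loc[target, cols] = imp
        out[label] = mat
    return out
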