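"""Grids of standardized single-predictor linear models.

Each model regresses one (z-scored) outcome on one (z-scored) predictor, so
the fitted slope is a standardized coefficient: for plain OLS it equals the
Pearson correlation.  Three variants are supported:

* plain least squares (no weights, no clustering),
* weighted least squares with positive sampling weights,
* a cluster random-intercept model (REML), optionally row-weighted.

Weighted moments use the sum of weights with the reliability-weight
bias correction ``V1 - V2/V1`` as the variance denominator, which reduces to
``n - 1`` for unit weights and is invariant to rescaling all weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InsufficientDataError, ZeroVarianceError

logger = logging.getLogger(__name__)

_DEGENERATE_TOL = 1e-12

FIT_TABLE_COLUMNS = [
    "predictor",
    "outcome",
    "beta",
    "se",
    "t",
    "p",
    "ci_lower",
    "ci_upper",
    "n_obs",
    "degenerate",
    "error",
]


@dataclass(frozen=True)
class ModelSpec:
    """Names the columns and options of one single-predictor model."""

    outcome_name: str
    predictor_name: str
    weight_name: Optional[str] = None
    cluster_name: Optional[str] = None
    conf_level: float = 0.95

    def __post_init__(self) -> None:
        if self.outcome_name == self.predictor_name:
            raise ValueError("outcome and predictor must name different columns")
        if not 0.0 < self.conf_level < 1.0:
            raise ValueError(f"conf_level must be in (0, 1), got {self.conf_level}")


@dataclass(frozen=True)
class FitResult:
    """One fitted model: standardized slope with Wald inference."""

    spec: ModelSpec
    beta: float
    se: float
    t_stat: float
    p_value: float
    ci_lower: float
    ci_upper: float
    n_obs: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.ci_lower <= self.beta <= self.ci_upper:
            raise ValueError("CI must bracket the point estimate")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")
        if self.se < 0:
            raise ValueError("negative standard error")
        if self.n_obs < 3:
            raise ValueError("n_obs must be at least 3")


def weighted_mean_sd(values: np.ndarray, weights: Optional[np.ndarray] = None) -> tuple[float, float]:
    """Weighted mean and bias-corrected weighted SD of a 1-d array.

    With unit weights this is the ordinary mean and the ``ddof=1`` SD.  The
    variance denominator is ``V1 - V2/V1`` (V1 = sum of weights, V2 = sum of
    squared weights), making the result invariant to a rescaling of all
    weights by a positive constant.
    """
    values = np.asarray(values, dtype=float)
    if weights is None:
        return float(values.mean()), float(values.std(ddof=1))
    weights = np.asarray(weights, dtype=float)
    v1 = weights.sum()
    v2 = (weights**2).sum()
    mean = float((weights * values).sum() / v1)
    denom = v1 - v2 / v1
    var = float((weights * (values - mean) ** 2).sum() / denom)
    return mean, float(np.sqrt(var))


def standardize_columns(
    data: pd.DataFrame,
    columns: Sequence[str],
    weights: Optional[str] = None,
) -> pd.DataFrame:
    """Replace the named columns with their (weighted) z-scores.

    Parameters
    ----------
    data
        Input table; not mutated.
    columns
        Labels of the numeric columns to standardize.
    weights
        Optional label of a positive weight column used for the moments.

    Raises
    ------
    ZeroVarianceError
        If any named column is constant.
    ValueError
        If any weight is not strictly positive.
    """
    out = data.copy()
    w = None
    if weights is not None:
        w = np.asarray(data[weights], dtype=float)
        if np.any(w <= 0):
            raise ValueError(f"weights in column {weights!r} must be strictly positive")
    for col in columns:
        values = np.asarray(data[col], dtype=float)
        mean, sd = weighted_mean_sd(values, w)
        if not np.isfinite(sd) or sd <= 0:
            raise ZeroVarianceError(col)
        out[col] = (values - mean) / sd
    return out


def _wls_slope_se(y: np.ndarray, x: np.ndarray, w: Optional[np.ndarray]) -> tuple[float, float, int]:
    """Slope and SE of (weighted) least squares of y on [1, x]; df = n - 2."""
    n = len(y)
    if w is None:
        w = np.ones(n)
    v1 = w.sum()
    xm = (w * x).sum() / v1
    ym = (w * y).sum() / v1
    xc = x - xm
    yc = y - ym
    sxx = (w * xc * xc).sum()
    beta = (w * xc * yc).sum() / sxx
    resid = yc - beta * xc
    rss = (w * resid * resid).sum()
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    return float(beta), float(se), n - 2


def _cluster_stats(y: np.ndarray, x: np.ndarray, w: np.ndarray, codes: np.ndarray, n_groups: int):
    """Per-cluster weighted cross-products of [1, x, y] for the REML profile."""
    sw = np.bincount(codes, weights=w, minlength=n_groups)
    swx = np.bincount(codes, weights=w * x, minlength=n_groups)
    swy = np.bincount(codes, weights=w * y, minlength=n_groups)
    swxx = np.bincount(codes, weights=w * x * x, minlength=n_groups)
    swxy = np.bincount(codes, weights=w * x * y, minlength=n_groups)
    swyy = np.bincount(codes, weights=w * y * y, minlength=n_groups)
    return sw, swx, swy, swxx, swxy, swyy


def fit_random_intercept(
    y: np.ndarray,
    x: np.ndarray,
    groups: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> tuple[float, float]:
    """REML fit of ``y = b0 + beta*x + u_group + e`` with optional row weights.

    The model has ``Var(u) = tau^2`` per cluster and ``Var(e_i) = sigma^2 / w_i``.
    The variance-ratio ``lambda = tau^2 / sigma^2`` is profiled out of the REML
    criterion, which for a scalar random intercept reduces (via the
    Sherman-Morrison identity applied per cluster) to sums over per-cluster
    weighted cross-products, so each criterion evaluation is O(#clusters).

    Returns
    -------
    (beta, se)
        GLS slope at the REML variance estimate and its standard error.
    """
    n = len(y)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    codes, _ = pd.factorize(groups, use_na_sentinel=False)
    n_groups = int(codes.max()) + 1
    sw, swx, swy, swxx, swxy, swyy = _cluster_stats(y, x, w, codes, n_groups)

    s_tot = np.array(
        [
            [sw.sum(), swx.sum(), swy.sum()],
            [swx.sum(), swxx.sum(), swxy.sum()],
            [swy.sum(), swxy.sum(), swyy.sum()],
        ]
    )
    a = np.stack([sw, swx, swy], axis=1)  # (n_groups, 3): per-cluster D'w

    def profile(lam: float):
        k = lam / (1.0 + lam * sw)
        m = s_tot - (a.T * k) @ a
        amat = m[:2, :2]
        b = m[:2, 2]
        c = m[2, 2]
        coef = np.linalg.solve(amat, b)
        rss = c - b @ coef
        return amat, coef, rss, k

    def neg_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        amat, _, rss, _ = profile(lam)
        if rss <= 0:
            return np.inf
        sign, logdet_a = np.linalg.slogdet(amat)
        if sign <= 0:
            return np.inf
        return (n - 2) * np.log(rss) + np.log1p(lam * sw).sum() + logdet_a

    res = optimize.minimize_scalar(neg_reml, bounds=(-25.0, 25.0), method="bounded")
    lam_hat = float(np.exp(res.x))
    # the profile is flat toward lambda -> 0 when clustering is absent
    if neg_reml(-40.0) < res.fun:
        lam_hat = 0.0
    amat, coef, rss, _ = profile(lam_hat)
    sigma2 = rss / (n - 2)
    cov = sigma2 * np.linalg.inv(amat)
    return float(coef[1]), float(np.sqrt(cov[1, 1]))


def _complete_rows(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    cols = [spec.outcome_name, spec.predictor_name]
    if spec.weight_name:
        cols.append(spec.weight_name)
    if spec.cluster_name:
        cols.append(spec.cluster_name)
    return data[cols].dropna()


def fit_single_model(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit one standardized single-predictor model.

    Rows incomplete in any involved column are dropped (listwise deletion).
    Outcome and predictor are z-scored with the spec's weights before
    fitting.  The CI uses the t quantile with ``df = n_obs - 2`` (also for
    clustered fits, as a Wald approximation).

    Raises
    ------
    InsufficientDataError
        Fewer than 3 complete rows.
    ZeroVarianceError
        Constant outcome or predictor.
    """
    sub = _complete_rows(data, spec)
    n = len(sub)
    if n < 3:
        raise InsufficientDataError(
            f"insufficient data: {n} complete rows for "
            f"{spec.outcome_name!r} ~ {spec.predictor_name!r} (need >= 3)"
        )
    std = standardize_columns(sub, [spec.outcome_name, spec.predictor_name], spec.weight_name)
    y = np.asarray(std[spec.outcome_name], dtype=float)
    x = np.asarray(std[spec.predictor_name], dtype=float)
    w = None
    if spec.weight_name:
        w = np.asarray(std[spec.weight_name], dtype=float)

    cluster = None
    if spec.cluster_name:
        cluster = sub[spec.cluster_name].to_numpy()
        if len(pd.unique(cluster)) < 2:
            logger.warning(
                "cluster column %r has a single level; falling back to a non-clustered fit",
                spec.cluster_name,
            )
            cluster = None

    if cluster is not None:
        beta, se = fit_random_intercept(y, x, cluster, w)
        df = n - 2
    else:
        beta, se, df = _wls_slope_se(y, x, w)

    degenerate = bool(se < _DEGENERATE_TOL or not np.isfinite(se))
    if degenerate:
        se = 0.0
        t_stat = np.inf if beta != 0 else 0.0
        p = 0.0 if beta != 0 else 1.0
        lo = hi = beta
    else:
        t_stat = beta / se
        p = 2.0 * stats.t.sf(abs(t_stat), df)
        tq = stats.t.ppf(0.5 + spec.conf_level / 2.0, df)
        lo, hi = beta - tq * se, beta + tq * se
    return FitResult(
        spec=spec,
        beta=beta,
        se=se,
        t_stat=float(t_stat),
        p_value=float(p),
        ci_lower=float(lo),
        ci_upper=float(hi),
        n_obs=n,
        degenerate=degenerate,
    )


def fit_result_to_row(fit: FitResult) -> dict:
    """Flatten a FitResult into one row of the fit-table schema."""
    return {
        "predictor": fit.spec.predictor_name,
        "outcome": fit.spec.outcome_name,
        "beta": fit.beta,
        "se": fit.se,
        "t": fit.t_stat,
        "p": fit.p_value,
        "ci_lower": fit.ci_lower,
        "ci_upper": fit.ci_upper,
        "n_obs": fit.n_obs,
        "degenerate": fit.degenerate,
        "error": "",
    }


def fit_model_grid(
    data: pd.DataFrame,
    outcomes: Sequence[str],
    predictors: Sequence[str],
    weight_name: Optional[str] = None,
    cluster_name: Optional[str] = None,
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Fit every (outcome x predictor) pair and return the stacked fit table.

    Rows are ordered with predictors as the outer loop and outcomes as the
    inner loop.  A failing cell produces a row whose ``error`` column holds
    the diagnostic instead of aborting the grid.
    """
    if len(outcomes) == 0 or len(predictors) == 0:
        raise ValueError("outcomes and predictors must be non-empty")
    overlap = set(outcomes) & set(predictors)
    if overlap:
        raise ValueError(f"outcomes and predictors overlap: {sorted(overlap)}")
    rows = []
    for pred in predictors:
        for out in outcomes:
            spec = ModelSpec(out, pred, weight_name, cluster_name, conf_level)
            try:
                rows.append(fit_result_to_row(fit_single_model(data, spec)))
            except Exception as exc:  # error note, keep the grid going
                rows.append(
                    {
                        "predictor": pred,
                        "outcome": out,
                        "beta": np.nan,
                        "se": np.nan,
                        "t": np.nan,
                        "p": np.nan,
                        "ci_lower": np.nan,
                        "ci_upper": np.nan,
                        "n_obs": 0,
                        "degenerate": False,
                        "error": str(exc),
                    }
                )
    return pd.DataFrame(rows, columns=FIT_TABLE_COLUMNS)
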