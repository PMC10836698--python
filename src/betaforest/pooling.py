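"""Rubin's-rules combination of per-plausible-value fits.

For m estimates q_i with squared standard errors se_i^2 the pooled quantities
are

    q_bar     = mean(q_i)
    w_within  = mean(se_i^2)
    b_between = var(q_i, ddof=1)
    t_total   = w_within + (1 + 1/m) * b_between
    df        = (m - 1) * (1 + w_within / ((1 + 1/m) * b_between))^2

with the 95% CI ``q_bar +/- t_{0.975, df} * sqrt(t_total)``.  When
b_between is exactly zero the df is infinite and the normal quantile is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PoolingError
from .regression import FitResult

POOLED_TABLE_COLUMNS = [
    "domain",
    "predictor",
    "m",
    "beta_pooled",
    "se_pooled",
    "df_rubin",
    "ci_lower",
    "ci_upper",
]


@dataclass(frozen=True)
class PooledResult:
    domain: str
    predictor: str
    m: int
    q_bar: float
    w_within: float
    b_between: float
    t_total: float
    se_pooled: float
    df_rubin: float
    ci_lower: float
    ci_upper: float


def _pool_arrays(betas: np.ndarray, ses: np.ndarray, domain: str, predictor: str) -> PooledResult:
    m = len(betas)
    q_bar = float(betas.mean())
    w_within = float((ses**2).mean())
    # identical estimates must give exactly B = 0 (and hence infinite df)
    b_between = 0.0 if np.ptp(betas) == 0.0 else float(betas.var(ddof=1))
    t_total = w_within + (1.0 + 1.0 / m) * b_between
    if b_between == 0.0:
        df = float("inf")
        quantile = stats.norm.ppf(0.975)
    else:
        df = (m - 1) * (1.0 + w_within / ((1.0 + 1.0 / m) * b_between)) ** 2
        quantile = stats.t.ppf(0.975, df)
    se_pooled = float(np.sqrt(t_total))
    return PooledResult(
        domain=domain,
        predictor=predictor,
        m=m,
        q_bar=q_bar,
        w_within=w_within,
        b_between=b_between,
        t_total=float(t_total),
        se_pooled=se_pooled,
        df_rubin=float(df),
        ci_lower=q_bar - quantile * se_pooled,
        ci_upper=q_bar + quantile * se_pooled,
    )


def pool_estimates(
    fits: Sequence[Union[FitResult, Mapping]],
    labels: tuple[str, str],
) -> PooledResult:
    """Pool m >= 2 fits that share a predictor into one Rubin estimate.

    ``fits`` may be FitResult objects or fit-table row mappings; ``labels``
    is the (domain, predictor) pair naming the cell.
    """
    domain, predictor = labels
    if len(fits) < 2:
        raise PoolingError(f"cell ({domain}, {predictor}): need m >= 2 fits, got {len(fits)}")
    betas, ses, preds = [], [], []
    for f in fits:
        if isinstance(f, FitResult):
            betas.append(f.beta)
            ses.append(f.se)
            preds.append(f.spec.predictor_name)
        else:
            err = f.get("error", "")
            if not (err is None or pd.isna(err) or str(err) == ""):
                raise PoolingError(
                    f"cell ({domain}, {predictor}): cannot pool errored fit "
                    f"for outcome {f.get('outcome')!r}: {err}"
                )
            betas.append(float(f["beta"]))
            ses.append(float(f["se"]))
            preds.append(f["predictor"])
    if len(set(preds)) > 1:
        raise PoolingError(f"cell ({domain}, {predictor}): fits mix predictors {sorted(set(preds))}")
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if not (np.isfinite(betas).all() and np.isfinite(ses).all()):
        raise PoolingError(f"cell ({domain}, {predictor}): non-finite estimates in input fits")
    return _pool_arrays(betas, ses, domain, predictor)


def pool_table(fit_table: pd.DataFrame, domain_of: Mapping[str, str]) -> pd.DataFrame:
    """Pool a whole fit table into one row per (domain, predictor) cell.

    ``domain_of`` maps every outcome name to its domain label.  Cells are
    emitted in order of first appearance in the input.
    """
    outcomes = fit_table["outcome"].unique()
    unmapped = [o for o in outcomes if o not in domain_of]
    if unmapped:
        raise PoolingError(f"outcomes missing from the domain mapping: {unmapped}")
    domains = fit_table["outcome"].map(domain_of)
    keyed = fit_table.assign(_domain=domains)
    rows = []
    for (domain, predictor), cell in keyed.groupby(["_domain", "predictor"], sort=False):
        pooled = pool_estimates(list(cell.to_dict("records")), (domain, predictor))
        rows.append(
            {
                "domain": pooled.domain,
                "predictor": pooled.predictor,
                "m": pooled.m,
                "beta_pooled": pooled.q_bar,
                "se_pooled": pooled.se_pooled,
                "df_rubin": pooled.df_rubin,
                "ci_lower": pooled.ci_lower,
                "ci_upper": pooled.ci_upper,
            }
        )
    return pd.DataFrame(rows, columns=POOLED_TABLE_COLUMNS)
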