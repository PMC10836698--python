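"""Case-bootstrap distributions of standardized regression coefficients.

Each replicate resamples rows with replacement, re-standardizes outcome and
predictor within the resample, and records the fitted slope (for the
plain/weighted engine this is the weighted Pearson correlation).  Replicates
are generated per (predictor, outcome) cell from a seed derived by a stable
hash of the cell labels, so a cell's draws do not depend on which other
cells share the grid.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import BootstrapError
from .regression import ModelSpec, _complete_rows, standardize_columns

DRAW_TABLE_COLUMNS = ["beta", "predictor", "outcome", "replicate"]


@dataclass(frozen=True)
class BootstrapDraw:
    beta: float
    predictor: str
    outcome: str
    replicate: int


def cell_seed_sequence(seed: int, predictor: str, outcome: str) -> np.random.SeedSequence:
    """Seed material for one grid cell: base seed + SHA-256 of the labels.

    The digest depends only on the cell's own labels, so reordering or
    extending the grid never changes a cell's stream.
    """
    digest = hashlib.sha256(f"{predictor}\x1f{outcome}".encode("utf-8")).digest()
    words = [int.from_bytes(digest[i : i + 4], "big") for i in range(0, 16, 4)]
    return np.random.SeedSequence([int(seed) & 0xFFFFFFFF, *words])


def _weighted_corr(y: np.ndarray, x: np.ndarray, w: Optional[np.ndarray]) -> float:
    if w is None:
        xc = x - x.mean()
        yc = y - y.mean()
    else:
        v1 = w.sum()
        xc = x - (w * x).sum() / v1
        yc = y - (w * y).sum() / v1
        xc = xc * np.sqrt(w)
        yc = yc * np.sqrt(w)
    sxx = (xc * xc).sum()
    syy = (yc * yc).sum()
    if sxx <= 0 or syy <= 0:
        return np.nan
    return float((xc * yc).sum() / np.sqrt(sxx * syy))


def bootstrap_betas(
    data: pd.DataFrame,
    spec: ModelSpec,
    n_reps: int,
    seed: int,
) -> list[BootstrapDraw]:
    """Draw ``n_reps`` case-bootstrap standardized slopes for one model.

    Degenerate resamples (zero variance in outcome or predictor) are
    discarded and redrawn so the cell always yields exactly ``n_reps``
    draws; more than ``100 * n_reps`` consecutive degenerate resamples
    aborts with an error.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    sub = _complete_rows(data, spec)
    n = len(sub)
    if n < 3:
        raise BootstrapError(
            f"insufficient data for bootstrap of {spec.outcome_name!r} ~ {spec.predictor_name!r}"
        )
    # validate the full sample once (raises on constant columns / bad weights)
    standardize_columns(sub, [spec.outcome_name, spec.predictor_name], spec.weight_name)
    y = np.asarray(sub[spec.outcome_name], dtype=float)
    x = np.asarray(sub[spec.predictor_name], dtype=float)
    w = None
    if spec.weight_name:
        w = np.asarray(sub[spec.weight_name], dtype=float)

    rng = np.random.default_rng(cell_seed_sequence(seed, spec.predictor_name, spec.outcome_name))
    draws: list[BootstrapDraw] = []
    consecutive_failures = 0
    limit = 100 * n_reps
    while len(draws) < n_reps:
        idx = rng.integers(0, n, size=n)
        beta = _weighted_corr(y[idx], x[idx], None if w is None else w[idx])
        if np.isnan(beta):
            consecutive_failures += 1
            if consecutive_failures > limit:
                raise BootstrapError("bootstrap failed: degenerate data")
            continue
        consecutive_failures = 0
        draws.append(
            BootstrapDraw(
                beta=beta,
                predictor=spec.predictor_name,
                outcome=spec.outcome_name,
                replicate=len(draws) + 1,
            )
        )
    return draws


def bootstrap_grid(
    data: pd.DataFrame,
    outcomes: Sequence[str],
    predictors: Sequence[str],
    n_reps: int,
    seed: int,
    weight_name: Optional[str] = None,
) -> pd.DataFrame:
    """Bootstrap every (outcome x predictor) cell; one row per draw.

    Row count is ``len(outcomes) * len(predictors) * n_reps``; cells are
    laid out predictor-outer / outcome-inner, replicates 1..n_reps within
    each cell.
    """
    if len(outcomes) == 0 or len(predictors) == 0:
        raise ValueError("outcomes and predictors must be non-empty")
    overlap = set(outcomes) & set(predictors)
    if overlap:
        raise ValueError(f"outcomes and predictors overlap: {sorted(overlap)}")
    frames = []
    errors = []
    for pred in predictors:
        for out in outcomes:
            spec = ModelSpec(out, pred, weight_name=weight_name)
            try:
                draws = bootstrap_betas(data, spec, n_reps, seed)
            except BootstrapError as exc:
                errors.append(f"({pred}, {out}): {exc}")
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "beta": [d.beta for d in draws],
                        "predictor": pred,
                        "outcome": out,
                        "replicate": np.arange(1, n_reps + 1),
                    }
                )
            )
    if errors:
        raise BootstrapError("bootstrap failed for cells: " + "; ".join(errors))
    return pd.concat(frames, ignore_index=True)[DRAW_TABLE_COLUMNS]
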