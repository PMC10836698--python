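"""Beta-range summaries: extremes of per-PV estimates and outer CI limits."""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from .errors import PoolingError

RANGE_TABLE_COLUMNS = [
    "domain",
    "predictor",
    "beta_pooled",
    "est_min",
    "est_max",
    "ci_outer_lower",
    "ci_outer_upper",
]

#: Default display labels for the assessment-score domain codes.
DOMAIN_LABELS = {
    "BSMALG": "Algebra",
    "BSMDAT": "Data and Probability",
    "BSMGEO": "Geometry",
    "BSMMAT": "Mathematics",
    "BSMNUM": "Number",
    "BSSBIO": "Biology",
    "BSSCHE": "Chemistry",
    "BSSEAR": "Earth Science",
    "BSSPHY": "Physics",
    "BSSSCI": "Science",
}

_TRAILING_INDEX = re.compile(r"^(?P<stem>.+?)(?:0[1-9]|[1-9][0-9])$")


@dataclass(frozen=True)
class BetaRangeRow:
    domain: str
    predictor: str
    beta_pooled: float
    est_min: float
    est_max: float
    ci_outer_lower: float
    ci_outer_upper: float

    def __post_init__(self) -> None:
        ok = (
            self.ci_outer_lower
            <= self.est_min
            <= self.beta_pooled
            <= self.est_max
            <= self.ci_outer_upper
        )
        if not ok:
            raise ValueError(
                f"range ordering violated for cell ({self.domain}, {self.predictor})"
            )


def map_pv_to_domain(outcome_name: str, mapping: Optional[Mapping[str, str]] = None) -> str:
    """Collapse a plausible-value column name to its domain label.

    The default rule strips a trailing two-digit index 01-99 (``"BSMMAT01"``
    -> ``"BSMMAT"``); names without such an index are returned unchanged.  An
    explicit ``mapping`` takes precedence over the rule.
    """
    if not outcome_name:
        raise ValueError("outcome name must be non-empty")
    if mapping is not None and outcome_name in mapping:
        return mapping[outcome_name]
    match = _TRAILING_INDEX.match(outcome_name)
    if match:
        return match.group("stem")
    return outcome_name


def domain_mapping_for(outcomes, mapping: Optional[Mapping[str, str]] = None) -> dict:
    """Build an outcome -> domain dict for a list of outcome names."""
    return {o: map_pv_to_domain(o, mapping) for o in outcomes}


def summarize_ranges(
    fit_table: pd.DataFrame,
    pooled_table: pd.DataFrame,
    domain_of: Mapping[str, str],
) -> pd.DataFrame:
    """Collapse each (domain, predictor) cell to one beta-range row.

    Per cell: ``est_min``/``est_max`` are the extremes of the member betas,
    ``ci_outer_lower``/``ci_outer_upper`` the outermost of the member CI
    limits, and ``beta_pooled`` is joined in from ``pooled_table``.  Rows are
    ordered by first appearance of the domain, then of the predictor within
    the domain.
    """
    outcomes = fit_table["outcome"].unique()
    unmapped = [o for o in outcomes if o not in domain_of]
    if unmapped:
        raise PoolingError(f"outcomes missing from the domain mapping: {unmapped}")
    keyed = fit_table.assign(_domain=fit_table["outcome"].map(domain_of))
    pooled_lookup = {
        (r.domain, r.predictor): r.beta_pooled for r in pooled_table.itertuples()
    }
    rows = []
    for domain in keyed["_domain"].unique():
        block = keyed[keyed["_domain"] == domain]
        for predictor in block["predictor"].unique():
            cell = block[block["predictor"] == predictor]
            if (domain, predictor) in pooled_lookup:
                beta_pooled = pooled_lookup[(domain, predictor)]
            else:
                raise PoolingError(
                    f"cell ({domain}, {predictor}) missing from the pooled table"
                )
            row = BetaRangeRow(
                domain=domain,
                predictor=predictor,
                beta_pooled=float(beta_pooled),
                est_min=float(cell["beta"].min()),
                est_max=float(cell["beta"].max()),
                ci_outer_lower=float(cell["ci_lower"].min()),
                ci_outer_upper=float(cell["ci_upper"].max()),
            )
            rows.append(row.__dict__)
    return pd.DataFrame(rows, columns=RANGE_TABLE_COLUMNS)
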