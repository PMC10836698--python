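"""Synthetic demonstration datasets.

Two generators:

* ``simulate_decathlon`` — 10 correlated event results plus 7 correlated
  hematological indices per athlete, drawn from a truncated multivariate
  normal with a block correlation structure.
* ``simulate_timss_like`` — hierarchical achievement data: students nested
  in schools nested in countries, 10 domains x 5 plausible-value columns,
  country-level macroeconomic predictors, lognormal sampling weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SimulationError

EVENT_NAMES = [
    "100 m",
    "Long jump",
    "Shot put",
    "High jump",
    "400 m",
    "110 m hurdles",
    "Discus throw",
    "Pole vault",
    "Javelin throw",
    "1500 m",
]
#: Events scored by time: lower is better, so their cross-block correlation
#: with the blood markers is sign-flipped.
TIMED_EVENTS = {"100 m", "400 m", "110 m hurdles", "1500 m"}

MARKER_NAMES = [
    "Ferritin",
    "Haptoglobin",
    "Hematocrit",
    "Hemoglobin",
    "Iron",
    "Red blood cell count",
    "Transferrin",
]

#: Marginal (mean, SD) targets for the decathlon generator.
DECATHLON_MARGINALS = {
    "100 m": (10.78, 0.29),
    "Long jump": (7.43, 0.44),
    "Shot put": (13.66, 0.46),
    "High jump": (1.95, 0.03),
    "400 m": (48.02, 1.64),
    "110 m hurdles": (14.79, 0.71),
    "Discus throw": (44.20, 2.79),
    "Pole vault": (4.90, 0.17),
    "Javelin throw": (57.17, 3.52),
    "1500 m": (4.60, 0.23),
    "Ferritin": (68.29, 8.90),
    "Haptoglobin": (65.70, 9.30),
    "Hematocrit": (46.78, 2.68),
    "Hemoglobin": (15.92, 1.08),
    "Iron": (122.37, 10.46),
    "Red blood cell count": (5.24, 0.53),
    "Transferrin": (320.77, 41.41),
}

#: Country-level macroeconomic predictors: (mean, SD).
PREDICTOR_MARGINALS = {
    "GDP": (28910.56, 21805.43),
    "GPI": (1.00, 0.03),
    "Gini": (36.82, 10.70),
    "GeS": (19.80, 7.55),
    "GeT": (4.58, 1.42),
}

MATH_DOMAINS = ["BSMALG", "BSMDAT", "BSMGEO", "BSMMAT", "BSMNUM"]
SCIENCE_DOMAINS = ["BSSBIO", "BSSCHE", "BSSEAR", "BSSPHY", "BSSSCI"]
ASSESSMENT_DOMAINS = MATH_DOMAINS + SCIENCE_DOMAINS
N_PLAUSIBLE_VALUES = 5


def nearest_positive_definite_correlation(matrix: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Repair a symmetric matrix to a positive-definite correlation matrix.

    Eigenvalues are floored at ``floor`` and the result rescaled to unit
    diagonal.  A matrix that is already positive definite is returned
    unchanged (up to symmetrization).
    """
    sym = (matrix + matrix.T) / 2.0
    eigval, eigvec = np.linalg.eigh(sym)
    if eigval.min() > floor:
        return sym
    eigval = np.maximum(eigval, floor)
    repaired = (eigvec * eigval) @ eigvec.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2.0


@dataclass
class SimulationConfig:
    """Marginals, correlation and truncation bounds for a truncated MVN draw."""

    n_units: int
    variable_names: Sequence[str]
    means: np.ndarray
    sds: np.ndarray
    correlation: np.ndarray
    bounds: Optional[np.ndarray] = None  # (k, 2) lower/upper per variable
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.variable_names)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.bounds is None:
            self.bounds = np.column_stack([np.full(k, -np.inf), np.full(k, np.inf)])
        self.bounds = np.asarray(self.bounds, dtype=float)
        if self.means.shape != (k,) or self.sds.shape != (k,):
            raise SimulationError("means and sds must match variable_names in length")
        if np.any(self.sds <= 0):
            raise SimulationError("all sds must be strictly positive")
        if self.correlation.shape != (k, k):
            raise SimulationError("correlation matrix shape mismatch")
        if not np.allclose(np.diag(self.correlation), 1.0, atol=1e-8):
            raise SimulationError("correlation matrix must have unit diagonal")
        if not np.allclose(self.correlation, self.correlation.T, atol=1e-8):
            raise SimulationError("correlation matrix must be symmetric")
        if self.bounds.shape != (k, 2):
            raise SimulationError("bounds must be a (k, 2) array")
        inside = (self.bounds[:, 0] <= self.means) & (self.means <= self.bounds[:, 1])
        if not inside.all():
            bad = [self.variable_names[i] for i in np.flatnonzero(~inside)]
            raise SimulationError(f"bounds do not contain the mean for: {bad}")


def sample_truncated_mvn(config: SimulationConfig) -> pd.DataFrame:
    """Draw ``n_units`` rows of a truncated multivariate normal.

    Rows with any value outside its bounds are rejected and redrawn, up to
    1,000 rounds; any still-offending values are then clipped with a
    warning.  The correlation matrix is repaired to the nearest positive
    definite one if needed.
    """
    corr = nearest_positive_definite_correlation(config.correlation)
    cov = corr * np.outer(config.sds, config.sds)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise SimulationError("correlation matrix not positive definite after repair") from exc
    rng = np.random.default_rng(config.seed)
    k = len(config.variable_names)
    lower, upper = config.bounds[:, 0], config.bounds[:, 1]

    def draw(n: int) -> np.ndarray:
        return config.means + rng.standard_normal((n, k)) @ chol.T

    values = draw(config.n_units)
    bad = np.flatnonzero(((values < lower) | (values > upper)).any(axis=1))
    attempts = 0
    while bad.size and attempts < 1000:
        redrawn = draw(bad.size)
        values[bad] = redrawn
        still = ((redrawn < lower) | (redrawn > upper)).any(axis=1)
        bad = bad[still]
        attempts += 1
    if bad.size:
        warnings.warn(
            f"{bad.size} rows still out of bounds after 1000 rejection rounds; clipping",
            stacklevel=2,
        )
        values[bad] = np.clip(values[bad], lower, upper)
    return pd.DataFrame(values, columns=list(config.variable_names))


def decathlon_correlation(
    rho_within_events: float = 0.6,
    rho_within_markers: float = 0.5,
    rho_cross: float = 0.4,
) -> np.ndarray:
    """Assemble the 17x17 block correlation for the decathlon generator.

    Events correlate ``rho_within_events`` among themselves, markers
    ``rho_within_markers``; the event-marker cross block is ``rho_cross``
    with the sign flipped for timed events (lower time = better
    performance).  The result is repaired to positive definiteness.
    """
    for rho in (rho_within_events, rho_within_markers, rho_cross):
        if not -1.0 < rho < 1.0:
            raise SimulationError("block correlations must lie in (-1, 1)")
    n_e, n_m = len(EVENT_NAMES), len(MARKER_NAMES)
    k = n_e + n_m
    corr = np.eye(k)
    corr[:n_e, :n_e] = rho_within_events
    corr[n_e:, n_e:] = rho_within_markers
    signs = np.array([-1.0 if e in TIMED_EVENTS else 1.0 for e in EVENT_NAMES])
    cross = rho_cross * signs[:, None] * np.ones((n_e, n_m))
    corr[:n_e, n_e:] = cross
    corr[n_e:, :n_e] = cross.T
    np.fill_diagonal(corr, 1.0)
    return nearest_positive_definite_correlation(corr)


def decathlon_config(
    n_units: int = 10_000,
    seed: int = 0,
    rho_within_events: float = 0.6,
    rho_within_markers: float = 0.5,
    rho_cross: float = 0.4,
    bound_sds: float = 4.0,
) -> SimulationConfig:
    """Default decathlon simulation configuration (bounds at mean +/- 4 SD)."""
    names = EVENT_NAMES + MARKER_NAMES
    means = np.array([DECATHLON_MARGINALS[v][0] for v in names])
    sds = np.array([DECATHLON_MARGINALS[v][1] for v in names])
    bounds = np.column_stack([means - bound_sds * sds, means + bound_sds * sds])
    return SimulationConfig(
        n_units=n_units,
        variable_names=names,
        means=means,
        sds=sds,
        correlation=decathlon_correlation(rho_within_events, rho_within_markers, rho_cross),
        bounds=bounds,
        seed=seed,
    )


def simulate_decathlon(config: Optional[SimulationConfig] = None, **overrides) -> pd.DataFrame:
    """Simulate the decathlon table: 10 events + 7 blood markers per athlete."""
    if config is None:
        config = decathlon_config(**overrides)
    return sample_truncated_mvn(config)


@dataclass
class HierarchyConfig:
    """Sizes, effects and noise levels for the hierarchical assessment generator."""

    n_countries: int = 38
    schools_per_country: int = 150
    students_per_school: int = 15
    true_slopes: Mapping[str, float] = field(
        default_factory=lambda: {"GDP": 0.25, "GPI": 0.01, "Gini": -0.12, "GeS": 0.17, "GeT": -0.12}
    )
    icc_school: float = 0.2
    pv_noise_sd: float = 10.0
    achievement_mean: float = 490.0
    achievement_sd: float = 110.0
    weight_dispersion: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_countries, self.schools_per_country, self.students_per_school) < 1:
            raise SimulationError("all hierarchy counts must be >= 1")
        if not 0.0 <= self.icc_school < 1.0:
            raise SimulationError("icc_school must lie in [0, 1)")
        if self.pv_noise_sd < 0:
            raise SimulationError("pv_noise_sd must be non-negative")
        unknown = set(self.true_slopes) - set(PREDICTOR_MARGINALS)
        if unknown:
            raise SimulationError(f"true_slopes name unknown predictors: {sorted(unknown)}")
        if sum(s**2 for s in self.true_slopes.values()) >= 1.0:
            raise SimulationError("sum of squared true slopes must be < 1")


def simulate_timss_like(config: Optional[HierarchyConfig] = None, **overrides) -> pd.DataFrame:
    """Simulate a hierarchical assessment table.

    Latent achievement (unit variance before scaling) is

        sum_p slope_p * z(pred_country) + u_school + eps_student

    where the country predictor draws are z-scored across the realized
    countries, Var(u)/Var(u + eps) = ``icc_school``, and
    Var(u) + Var(eps) = 1 - sum(slope^2).  Each domain's five PV columns add
    independent N(0, pv_noise_sd) noise on the reporting scale.  Sampling
    weights are lognormal with mean 1.
    """
    if config is None:
        config = HierarchyConfig(**overrides)
    rng = np.random.default_rng(config.seed)
    n_c, n_s, n_st = config.n_countries, config.schools_per_country, config.students_per_school
    n_schools = n_c * n_s
    n = n_schools * n_st

    predictors = list(config.true_slopes.keys())
    slopes = np.array([config.true_slopes[p] for p in predictors])
    # z-scored country draws: exact mean 0 / SD 1 across countries so the
    # configured slopes are the standardized effects in the realized sample
    z = rng.standard_normal((n_c, len(predictors)))
    if n_c > 1:
        z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=0)
    else:
        z = np.zeros_like(z)

    resid_var = 1.0 - float(slopes @ slopes)
    tau2 = config.icc_school * resid_var
    eps_var = (1.0 - config.icc_school) * resid_var

    country_of_school = np.repeat(np.arange(n_c), n_s)
    country = np.repeat(country_of_school, n_st)
    school = np.repeat(np.arange(n_schools), n_st)

    u_school = rng.normal(0.0, np.sqrt(tau2), size=n_schools)
    eps = rng.normal(0.0, np.sqrt(eps_var), size=n)
    latent_core = (z @ slopes)[country] + u_school[school] + eps
    latent = config.achievement_mean + config.achievement_sd * latent_core

    data = {
        "country_id": country + 1,
        "school_id": school + 1,
    }
    for j, pred in enumerate(predictors):
        mean, sd = PREDICTOR_MARGINALS[pred]
        data[pred] = (mean + sd * z[:, j])[country]
    sigma = config.weight_dispersion
    data["weight"] = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n)) if sigma > 0 else np.ones(n)
    for domain in ASSESSMENT_DOMAINS:
        for pv in range(1, N_PLAUSIBLE_VALUES + 1):
            noise = rng.normal(0.0, config.pv_noise_sd, size=n) if config.pv_noise_sd > 0 else 0.0
            data[f"{domain}{pv:02d}"] = latent + noise
    return pd.DataFrame(data)


def pv_column_names() -> list[str]:
    """The 50 plausible-value column names (10 domains x 5 PVs)."""
    return [f"{d}{pv:02d}" for d in ASSESSMENT_DOMAINS for pv in range(1, N_PLAUSIBLE_VALUES + 1)]
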