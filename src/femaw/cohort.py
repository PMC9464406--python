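"""Synthetic cohorts of (sex, group, AW, FA, NSA) hip records.

The generative model mirrors the structure the statistical analysis
assumes: the AW angle is normal within sex, FA follows the linear model

    FA = b0 + b_aw * AW + b_sex * [male] + N(0, residual_sd)

with sex coded 0 = female / 1 = male, and NSA is drawn independently of FA
(the two are uncorrelated in the study population).  Default parameters are
the study's printed sex-specific AW marginals and regression coefficients.

Repeated-observer measurements are generated with an explicit variance
decomposition (subject + observer bias + session noise) whose components
are chosen in closed form so the population intra- and inter-observer
intraclass correlations equal the requested targets.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "CohortParams",
    "ObserverReplicates",
    "derive_residual_sd",
    "simulate_cohort",
    "simulate_observers",
    "systematic_fa_variance",
    "population_r_squared",
    "residual_sd_for_r_squared",
]


def derive_residual_sd(total_sd: float, r_squared: float) -> float:
    """Residual SD implied by a total SD and a coefficient of determination.

    ``total_sd * sqrt(1 - r_squared)``: the share of the outcome's spread
    the linear model leaves unexplained.
    """
    if not 0.0 <= r_squared < 1.0:
        raise ValueError("r_squared must lie in [0, 1)")
    if total_sd <= 0:
        raise ValueError("total_sd must be positive")
    return float(total_sd * np.sqrt(1.0 - r_squared))


@dataclass(frozen=True)
class CohortParams:
    """Generative parameters; defaults reproduce the study's printed marginals.

    AW means/SDs are per sex (male, female) in degrees; the FA coefficients
    are (intercept, AW slope, male-indicator effect).  ``residual_sd``
    defaults to the value implied by the pooled FA SD (10.8) and the
    reported fit (R^2 = 0.507).
    """

    n_hips: int = 100
    male_fraction: float = 0.53
    aw_mean_by_sex: tuple[float, float] = (14.6, 20.8)
    aw_sd_by_sex: tuple[float, float] = (6.6, 8.2)
    coef_const: float = 4.330
    coef_aw: float = 0.744
    coef_sex: float = -4.998
    residual_sd: float = derive_residual_sd(10.8, 0.507)
    nsa_mean: float = 127.3
    nsa_sd: float = 5.4
    onfh_fraction: float = 0.67
    seed: int = 0

    def __post_init__(self):
        if self.n_hips < 1:
            raise ValueError("n_hips must be positive")
        for frac in (self.male_fraction, self.onfh_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        for sd in (*self.aw_sd_by_sex, self.residual_sd, self.nsa_sd):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")

    def calibrated_to_r_squared(self, r_squared: float = 0.507) -> "CohortParams":
        """Copy with ``residual_sd`` set so the population R^2 equals ``r_squared``."""
        return replace(self, residual_sd=residual_sd_for_r_squared(self, r_squared))


def systematic_fa_variance(params: CohortParams) -> float:
    """Closed-form variance of the FA component explained by (AW, sex)."""
    p = params.male_fraction
    q = 1.0 - p
    mu_m, mu_f = params.aw_mean_by_sex
    sd_m, sd_f = params.aw_sd_by_sex
    var_aw = p * sd_m**2 + q * sd_f**2 + p * q * (mu_m - mu_f) ** 2
    cov_aw_sex = p * q * (mu_m - mu_f)
    return (params.coef_aw**2 * var_aw
            + params.coef_sex**2 * p * q
            + 2.0 * params.coef_aw * params.coef_sex * cov_aw_sex)


def population_r_squared(params: CohortParams) -> float:
    v_sys = systematic_fa_variance(params)
    return v_sys / (v_sys + params.residual_sd**2)


def residual_sd_for_r_squared(params: CohortParams, r_squared: float) -> float:
    """Residual SD making the population R^2 of the model equal ``r_squared``."""
    if not 0.0 < r_squared < 1.0:
        raise ValueError("r_squared must lie in (0, 1)")
    v_sys = systematic_fa_variance(params)
    return float(np.sqrt(v_sys * (1.0 - r_squared) / r_squared))


def simulate_cohort(params: CohortParams, seed: int | None = None) -> pd.DataFrame:
    """Draw one cohort as a DataFrame of per-hip records.

    Columns: ``hip_id, sex, sex_code (0=female, 1=male), group, aw, fa, nsa``.
    Reproducible for a fixed ``params.seed`` (or the ``seed`` override).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_hips
    male = rng.random(n) < params.male_fraction
    mu = np.where(male, *params.aw_mean_by_sex)
    sd = np.where(male, *params.aw_sd_by_sex)
    aw = rng.normal(mu, sd)
    fa = (params.coef_const + params.coef_aw * aw + params.coef_sex * male
          + rng.normal(0.0, params.residual_sd, size=n))
    nsa = rng.normal(params.nsa_mean, params.nsa_sd, size=n)
    onfh = rng.random(n) < params.onfh_fraction
    return pd.DataFrame({
        "hip_id": np.arange(1, n + 1),
        "sex": np.where(male, "male", "female"),
        "sex_code": male.astype(int),
        "group": np.where(onfh, "ONFH", "normal"),
        "aw": aw,
        "fa": fa,
        "nsa": nsa,
    })


@dataclass(frozen=True)
class ObserverReplicates:
    """Measurements of shape (n_hips, n_observers, n_sessions) plus targets."""

    values: np.ndarray
    target_icc_intra: float
    target_icc_inter: float

    def session_matrix(self, observer: int = 0) -> np.ndarray:
        """(n, sessions) matrix for one observer: intra-observer reliability."""
        return self.values[:, observer, :]

    def observer_means(self) -> np.ndarray:
        """(n, observers) matrix of session-averaged values: inter-observer."""
        return self.values.mean(axis=2)


def simulate_observers(true_values, target_icc_intra: float, target_icc_inter: float,
                       seed: int = 0, n_observers: int = 2,
                       n_sessions: int = 2) -> ObserverReplicates:
    """Repeated measurements by several observers over several sessions.

    ``true_values`` may be a 1-D array or a cohort DataFrame column.  Session
    noise variance is set from the intra-observer ICC target,
    ``sigma_e^2 = sigma_T^2 (1 - rho) / rho``; observer biases are placed
    deterministically (symmetric around zero) with the spread that makes the
    large-n ICC(2,1) of session-averaged observer scores equal the
    inter-observer target.  Targets must satisfy
    ``0 < target_icc_inter <= intra-implied bound < 1``.
    """
    t = np.asarray(true_values, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("true_values must be a 1-D array of at least 2 hips")
    for name, v in (("target_icc_intra", target_icc_intra),
                    ("target_icc_inter", target_icc_inter)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must lie strictly inside (0, 1)")
    var_t = float(np.var(t, ddof=1))
    if var_t <= 0:
        raise ValueError("true values are constant; ICC undefined")
    var_e = var_t * (1.0 - target_icc_intra) / target_icc_intra
    # inter target: rho2 = var_t / (var_t + var_b + var_e / n_sessions)
    var_b = var_t * (1.0 / target_icc_inter - 1.0) - var_e / n_sessions
    if var_b < 0:
        raise ValueError(
            "target_icc_inter is unreachable given target_icc_intra "
            "(session noise alone already exceeds the inter-observer spread)"
        )
    # deterministic, zero-mean observer biases with population variance var_b
    # (sum b^2 / (k-1) = k/2 * delta^2 ... for the symmetric +-delta layout)
    k = n_observers
    offsets = np.arange(k) - (k - 1) / 2.0
    offsets = offsets / np.sqrt(np.sum(offsets**2) / (k - 1)) if k > 1 else offsets
    biases = offsets * np.sqrt(var_b)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, np.sqrt(var_e), size=(len(t), k, n_sessions))
    values = t[:, None, None] + biases[None, :, None] + noise
    return ObserverReplicates(values=values, target_icc_intra=target_icc_intra,
                              target_icc_inter=target_icc_inter)
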