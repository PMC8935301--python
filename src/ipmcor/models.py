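"""Vital-rate functions: survival, reproduction, growth, offspring size.

Every function is vectorized over log body mass ``m`` and returns
probabilities/densities on the natural scale; log-scale variants carry a
``log_`` prefix and are the ones the likelihood code uses.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
from scipy.special import expit, log_expit

from .params import (
    ConfigurationError,
    IndividualEffects,
    ModelSpec,
    VitalRateParams,
    YearDraw,
    require_effects,
)

ArrayLike = Union[float, np.ndarray]

_LOG_2PI = np.log(2.0 * np.pi)


def _check_finite(m: ArrayLike, name: str = "m") -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError(f"{name} must be finite")
    return m


def log_normal_pdf(x: ArrayLike, mean: ArrayLike, var: float) -> np.ndarray:
    """Gaussian log-density; kept explicit because it sits in hot loops."""
    x = np.asarray(x, dtype=float)
    return -0.5 * (_LOG_2PI + np.log(var) + (x - mean) ** 2 / var)


def survival_prob(m: ArrayLike, params: VitalRateParams) -> np.ndarray:
    """Pr(alive at t+1 | log mass m): inverse-logit of a linear predictor.

    Survival is independent of the heterogeneity structure in every model
    variant, so no effects argument exists.
    """
    m = _check_finite(m)
    return expit(params.beta_s0 + params.beta_sm * m)


def _repro_linpred(
    m: np.ndarray,
    params: VitalRateParams,
    model: ModelSpec,
    year: Optional[YearDraw],
    indiv: Optional[IndividualEffects],
) -> np.ndarray:
    eta = params.beta_b0 + params.beta_bm * m
    mid = model.model_id
    if mid in ("I2", "D2b"):
        year = require_effects(model, year)
        eta = eta + year.u_b
    elif mid == "D2a":
        year = require_effects(model, year)
        eta = eta + params.beta_bq * year.q
    elif mid in ("I3", "D3"):
        if indiv is None:
            raise ConfigurationError(f"model {mid} requires individual effects")
        eta = eta + indiv.v_b
    return eta


def _growth_mean(
    m: np.ndarray,
    params: VitalRateParams,
    model: ModelSpec,
    year: Optional[YearDraw],
    indiv: Optional[IndividualEffects],
) -> np.ndarray:
    mu = params.beta_g0 + params.beta_gm * m
    mid = model.model_id
    if mid in ("I2", "D2b"):
        year = require_effects(model, year)
        mu = mu + year.u_g
    elif mid == "D2a":
        year = require_effects(model, year)
        mu = mu + params.beta_gq * year.q
    elif mid in ("I3", "D3"):
        if indiv is None:
            raise ConfigurationError(f"model {mid} requires individual effects")
        mu = mu + indiv.v_g
    return mu


def reproduction_prob(
    m: ArrayLike,
    params: VitalRateParams,
    model: ModelSpec = ModelSpec("I1"),
    year: Optional[YearDraw] = None,
    indiv: Optional[IndividualEffects] = None,
) -> np.ndarray:
    """Pr(reproduces at t+1 | m, effects) under any model variant."""
    m = _check_finite(m)
    return expit(_repro_linpred(m, params, model, year, indiv))


def log_reproduction_prob(m, params, model=ModelSpec("I1"), year=None, indiv=None):
    return log_expit(_repro_linpred(_check_finite(m), params, model, year, indiv))


def growth_density(
    m_next: ArrayLike,
    m: ArrayLike,
    params: VitalRateParams,
    model: ModelSpec = ModelSpec("I1"),
    year: Optional[YearDraw] = None,
    indiv: Optional[IndividualEffects] = None,
) -> np.ndarray:
    """Gaussian transition density g(m' | m) of log mass, given effects."""
    return np.exp(log_growth_density(m_next, m, params, model, year, indiv))


def log_growth_density(m_next, m, params, model=ModelSpec("I1"), year=None, indiv=None):
    m = _check_finite(m)
    m_next = np.asarray(m_next, dtype=float)
    mu = _growth_mean(m, params, model, year, indiv)
    return log_normal_pdf(m_next, mu, params.sigma2_g)


def offspring_density(c_next: ArrayLike, m: ArrayLike, params: VitalRateParams) -> np.ndarray:
    """Offspring-size density h(c' | m): Gaussian, linear in parent log mass."""
    return np.exp(log_offspring_density(c_next, m, params))


def log_offspring_density(c_next, m, params):
    m = _check_finite(m)
    c_next = np.asarray(c_next, dtype=float)
    mu = params.beta_h0 + params.beta_hm * m
    return log_normal_pdf(c_next, mu, params.sigma2_h)


def growth_density_marginal_D1a(
    m_next: ArrayLike, m: ArrayLike, params: VitalRateParams
) -> np.ndarray:
    """Marginal growth density of the reproduction-conditional model.

    Integrating the binary breeding status out of the conditional growth
    model yields a two-component Gaussian mixture weighted by the
    reproduction probability b(m):

        g(m'|m) = b(m) phi(m'; mu + beta_g_given_r, sigma_g^2)
                + (1 - b(m)) phi(m'; mu, sigma_g^2)

    which induces cov(m', r') = beta_g_given_r * b(m)(1 - b(m)).
    """
    m = _check_finite(m)
    m_next = np.asarray(m_next, dtype=float)
    b = reproduction_prob(m, params)
    mu = params.beta_g0 + params.beta_gm * m
    f1 = np.exp(log_normal_pdf(m_next, mu + params.beta_g_given_r, params.sigma2_g))
    f0 = np.exp(log_normal_pdf(m_next, mu, params.sigma2_g))
    return b * f1 + (1.0 - b) * f0
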