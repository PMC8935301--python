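"""Gaussian copula joining a Gaussian growth margin and a Bernoulli
reproduction margin via continuity augmentation.

The Bernoulli response Y2 (reproduced or not) is augmented with an
independent uniform X to Y3 = Y2 + X, whose CDF F3 is piecewise linear on
[0, 2] with a slope break at 1 (the break carries Pr(Y2 = 0) = q).  A
bivariate Gaussian copula with correlation matrix
D = [[1, alpha], [alpha, 1]] then couples Y1 (growth) and Y3, giving the
joint density

    f(y1, y3) = phi_D((y1 - mu)/sigma, PhiInv(F3(y3)))
                * f3(y3) / (sigma * phi(PhiInv(F3(y3))))

Because a copula never changes its margins, the induced projection kernel
is identical to the independent ("vanilla") kernel; the dependence shows up
only in the joint law of growth and reproduction, not in the population
projection.
"""

from __future__ import annotations

from typing import Union

import numpy as np
from scipy.special import ndtr, ndtri

from .models import log_normal_pdf
from .params import CopulaSpec, InvalidParameterError, VitalRateParams

ArrayLike = Union[float, np.ndarray]

# Phi^-1(F3(y3)) is clamped to Phi^-1 of [CLAMP, 1-CLAMP]: the joint density
# is undefined where the margin CDF hits exactly 0 or 1, a measure-zero set.
_CLAMP = 1e-12


def copula_margin_cdf_F3(y3: ArrayLike, q_fail: float) -> np.ndarray:
    """Piecewise-linear CDF of the augmented Bernoulli response Y3 = Y2 + X."""
    if not 0.0 <= q_fail <= 1.0:
        raise InvalidParameterError("q_fail must lie in [0, 1]")
    y3 = np.asarray(y3, dtype=float)
    out = np.where(
        y3 < 1.0, q_fail * y3, q_fail + (1.0 - q_fail) * (y3 - 1.0)
    )
    return np.clip(out, 0.0, 1.0)


def copula_margin_pdf_f3(y3: ArrayLike, q_fail: float) -> np.ndarray:
    """Density of Y3: q on [0, 1), 1 - q on [1, 2], zero elsewhere."""
    y3 = np.asarray(y3, dtype=float)
    out = np.where(y3 < 1.0, q_fail, 1.0 - q_fail)
    return np.where((y3 < 0.0) | (y3 > 2.0), 0.0, out)


def copula_margin_quantile_F3(p: ArrayLike, q_fail: float) -> np.ndarray:
    """Inverse of F3 (used to sample Y3 from a Gaussian copula draw)."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lo = p / q_fail
        hi = 1.0 + (p - q_fail) / (1.0 - q_fail)
    out = np.where(p < q_fail, lo, hi)
    return np.clip(out, 0.0, 2.0)


def _std_bivariate_log_pdf(z1: np.ndarray, z2: np.ndarray, alpha: float) -> np.ndarray:
    """log phi_D at (z1, z2) for unit variances and correlation alpha."""
    om = 1.0 - alpha * alpha
    quad = (z1 * z1 - 2.0 * alpha * z1 * z2 + z2 * z2) / om
    return -np.log(2.0 * np.pi) - 0.5 * np.log(om) - 0.5 * quad


def copula_joint_log_density(
    y1: ArrayLike, y3: ArrayLike, spec: CopulaSpec
) -> np.ndarray:
    """log f(y1, y3) of the augmented joint; margins are preserved exactly."""
    y1 = np.asarray(y1, dtype=float)
    y3 = np.asarray(y3, dtype=float)
    sigma = np.sqrt(spec.sigma2)
    z1 = (y1 - spec.mu) / sigma
    u = np.clip(copula_margin_cdf_F3(y3, spec.q_fail), _CLAMP, 1.0 - _CLAMP)
    z2 = ndtri(u)
    log_f3 = np.log(np.maximum(copula_margin_pdf_f3(y3, spec.q_fail), 1e-300))
    log_phi_z2 = -0.5 * (np.log(2.0 * np.pi) + z2 * z2)
    return (
        _std_bivariate_log_pdf(z1, z2, spec.alpha)
        + log_f3
        - np.log(sigma)
        - log_phi_z2
    )


def copula_joint_density(y1: ArrayLike, y3: ArrayLike, spec: CopulaSpec) -> np.ndarray:
    out = np.exp(copula_joint_log_density(y1, y3, spec))
    return np.where(
        (np.asarray(y3, dtype=float) < 0.0) | (np.asarray(y3, dtype=float) > 2.0),
        0.0,
        out,
    )


def copula_loglik_record(
    m_next: ArrayLike,
    r_next: ArrayLike,
    m: ArrayLike,
    x_aux: ArrayLike,
    params: VitalRateParams,
) -> np.ndarray:
    """Copula log-density of one augmented growth/reproduction observation.

    The growth model supplies the Gaussian margin (mu = beta_g0 +
    beta_gm * m) and the reproduction model the Bernoulli margin
    (q_fail = 1 - b(m)); the observed pair enters as y1 = m_next,
    y3 = r_next + x_aux with the auxiliary x_aux in [0, 1].
    """
    m = np.asarray(m, dtype=float)
    m_next = np.asarray(m_next, dtype=float)
    r_next = np.asarray(r_next, dtype=float)
    x_aux = np.asarray(x_aux, dtype=float)
    if np.any((x_aux < 0.0) | (x_aux > 1.0)):
        raise ValueError("auxiliary x_aux must lie in [0, 1]")
    if not np.all((r_next == 0.0) | (r_next == 1.0)):
        raise ValueError("r_next must be binary")

    from scipy.special import expit

    sigma = np.sqrt(params.sigma2_g)
    mu = params.beta_g0 + params.beta_gm * m
    q_fail = 1.0 - expit(params.beta_b0 + params.beta_bm * m)
    y3 = r_next + x_aux

    z1 = (m_next - mu) / sigma
    # F3 evaluated segment-wise to stay vectorized over per-record q_fail
    u = np.where(y3 < 1.0, q_fail * y3, q_fail + (1.0 - q_fail) * (y3 - 1.0))
    u = np.clip(u, _CLAMP, 1.0 - _CLAMP)
    z2 = ndtri(u)
    f3 = np.where(y3 < 1.0, q_fail, 1.0 - q_fail)
    log_f3 = np.log(np.maximum(f3, 1e-300))
    log_phi_z2 = -0.5 * (np.log(2.0 * np.pi) + z2 * z2)
    return (
        _std_bivariate_log_pdf(z1, z2, params.alpha)
        + log_f3
        - np.log(sigma)
        - log_phi_z2
    )


def copula_growth_margin(
    y1: ArrayLike, spec: CopulaSpec, n_nodes: int = 80
) -> np.ndarray:
    """Marginal density of Y1 by numerical integration of the joint over y3.

    Substituting u = PhiInv(F3(y3)) turns the y3-integral into an integral
    of phi(u) * N(y1; mu + sigma*alpha*u, sigma^2(1 - alpha^2)) over the
    whole real line, evaluated here with a Gauss-Hermite rule.  Used to
    build the copula kernel so that its agreement with the independent
    kernel is a numerical result rather than an identity by construction.
    """
    y1 = np.atleast_1d(np.asarray(y1, dtype=float))
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    # hermite_e: integral of f(u) exp(-u^2/2), so phi(u) du -> weights/sqrt(2*pi)
    w = weights / np.sqrt(2.0 * np.pi)
    sigma = np.sqrt(spec.sigma2)
    cond_var = spec.sigma2 * (1.0 - spec.alpha**2)
    mu_cond = spec.mu + sigma * spec.alpha * nodes  # (n_nodes,)
    dens = np.exp(log_normal_pdf(y1[:, None], mu_cond[None, :], cond_var))
    out = dens @ w
    return out if np.ndim(y1) else float(out[0])


def sample_copula_pair(
    rng: np.random.Generator,
    mu: np.ndarray,
    sigma2: float,
    q_fail: np.ndarray,
    alpha: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (y1, r) pairs from the copula joint, vectorized over records."""
    mu = np.asarray(mu, dtype=float)
    n = mu.shape[0] if mu.ndim else 1
    z = rng.standard_normal((2, n))
    z2 = alpha * z[0] + np.sqrt(1.0 - alpha * alpha) * z[1]
    y1 = mu + np.sqrt(sigma2) * np.asarray(z[0])
    y3 = copula_margin_quantile_F3(ndtr(z2), np.asarray(q_fail, dtype=float))
    r = (y3 >= 1.0).astype(int)
    return y1, r
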