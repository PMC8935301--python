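"""Parameter and state containers shared by every model variant.

The eight vital-rate model variants share one fixed-effect skeleton
(logistic survival and reproduction, Gaussian growth and offspring size,
all linear in log body mass) and differ only in which heterogeneity
arguments enter the growth/reproduction linear predictors:

========  ===========================================================
model id  extra structure
========  ===========================================================
I1        none ("vanilla")
I2        independent random year effects (u_b, u_g)
I3        independent random individual effects (v_b, v_g)
D1a       current breeding status shifts growth mean by beta_g_given_r
D1b       Gaussian copula joins growth and reproduction (correlation alpha)
D2a       observed shared driver q with coefficients beta_bq, beta_gq
D2b       correlated year effects, corr(u_b, u_g) = rho
D3        correlated individual effects, corr(v_b, v_g) = psi
========  ===========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

MODEL_IDS = ("I1", "I2", "I3", "D1a", "D1b", "D2a", "D2b", "D3")

#: models with latent year effects in the growth/reproduction block
TEMPORAL_LATENT = ("I2", "D2b")
#: models whose kernel varies from year to year
TEMPORAL = ("I2", "D2a", "D2b")
#: models with persistent individual effects (extended (x, z) state)
INDIVIDUAL = ("I3", "D3")


class InvalidParameterError(ValueError):
    """A parameter violates its support (negative variance, |corr| >= 1...)."""


class ConfigurationError(ValueError):
    """Model id and supplied effects/arguments are inconsistent."""


@dataclass
class VitalRateParams:
    """All fixed-effect, variance and dependence parameters in one container.

    Intercepts/slopes are on the logit scale for survival (``beta_s*``) and
    reproduction (``beta_b*``) and on the log-mass scale for growth
    (``beta_g*``) and offspring size (``beta_h*``).  Parameters a model
    variant does not use are simply never read by its evaluation.
    """

    beta_s0: float = 0.0
    beta_sm: float = 0.0
    beta_b0: float = 0.0
    beta_bm: float = 0.0
    beta_g0: float = 0.0
    beta_gm: float = 0.0
    beta_h0: float = 0.0
    beta_hm: float = 0.0
    sigma2_g: float = 1.0
    sigma2_h: float = 1.0
    # D1a: shift of the growth mean when the individual reproduces
    beta_g_given_r: float = 0.0
    # D1b: off-diagonal of the 2x2 copula correlation matrix D
    alpha: float = 0.0
    # D2a: shared-driver coefficients
    beta_bq: float = 0.0
    beta_gq: float = 0.0
    # I2/D2b: year-effect variances and correlation (rho = 0 recovers I2)
    nu2_b: float = 0.0
    nu2_g: float = 0.0
    rho: float = 0.0
    # I3/D3: individual-effect variances and correlation (psi = 0 recovers I3)
    theta2_b: float = 0.0
    theta2_g: float = 0.0
    psi: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma2_g", "sigma2_h"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        for name in ("nu2_b", "nu2_g", "theta2_b", "theta2_g"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be nonnegative")
        for name in ("rho", "psi", "alpha"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise InvalidParameterError(f"{name} must lie in (-1, 1), got {v}")

    def replace(self, **changes) -> "VitalRateParams":
        return replace(self, **changes)

    def year_effect_cov(self) -> np.ndarray:
        """2x2 covariance of (u_b, u_g) for the temporal random-effect models."""
        sb, sg = np.sqrt(self.nu2_b), np.sqrt(self.nu2_g)
        off = self.rho * sb * sg
        return np.array([[self.nu2_b, off], [off, self.nu2_g]])

    def individual_effect_cov(self) -> np.ndarray:
        """2x2 covariance of (v_b, v_g) for the persistent-heterogeneity models."""
        sb, sg = np.sqrt(self.theta2_b), np.sqrt(self.theta2_g)
        off = self.psi * sb * sg
        return np.array([[self.theta2_b, off], [off, self.theta2_g]])


@dataclass
class ModelSpec:
    """Which variant to evaluate, plus the case-study refinement flags.

    ``newborn_only`` restricts the D1a breeding-status growth shift to
    records flagged as first-year individuals.  ``lag_previous_breeding``
    conditions growth on breeding status at t instead of t+1 (off by
    default; the current-status convention is the primary one).
    """

    model_id: str
    newborn_only: bool = False
    lag_previous_breeding: bool = False

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ConfigurationError(
                f"unknown model id {self.model_id!r}; expected one of {MODEL_IDS}"
            )

    @property
    def temporal(self) -> bool:
        return self.model_id in TEMPORAL

    @property
    def individual(self) -> bool:
        return self.model_id in INDIVIDUAL


@dataclass
class YearDraw:
    """Time-specific conditions for one projection year.

    Latent effects (u_b, u_g) for I2/D2b; an observed driver value q for
    D2a.  Exactly the pieces the model id needs must be present.
    """

    u_b: Optional[float] = None
    u_g: Optional[float] = None
    q: Optional[float] = None
    year: Optional[int] = None

    @staticmethod
    def none() -> "YearDraw":
        return YearDraw()


@dataclass
class IndividualEffects:
    """Persistent individual effects (v_b, v_g) for models I3/D3."""

    v_b: float = 0.0
    v_g: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.v_b) and np.isfinite(self.v_g)):
            raise InvalidParameterError("individual effects must be finite")


@dataclass
class CopulaSpec:
    """Gaussian-copula joint of a Gaussian margin Y1 and a Bernoulli margin Y2.

    The Bernoulli variable is made continuous by adding an independent
    uniform: Y3 = Y2 + X, X ~ U[0, 1], so a bivariate Gaussian copula with
    correlation ``alpha`` can couple Y1 and Y3.  ``q_fail`` = Pr(Y2 = 0).
    """

    mu: float
    sigma2: float
    q_fail: float
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma2 > 0:
            raise InvalidParameterError("sigma2 must be strictly positive")
        if not 0.0 <= self.q_fail <= 1.0:
            raise InvalidParameterError("q_fail must lie in [0, 1]")
        if not -1.0 < self.alpha < 1.0:
            raise InvalidParameterError("alpha must lie in (-1, 1)")


def require_effects(model: ModelSpec, year: Optional[YearDraw]) -> YearDraw:
    """Validate that ``year`` carries what ``model`` needs; fill neutral values."""
    year = year if year is not None else YearDraw.none()
    mid = model.model_id
    if mid in TEMPORAL_LATENT:
        if year.u_b is None or year.u_g is None:
            raise ConfigurationError(f"model {mid} requires year effects (u_b, u_g)")
    elif mid == "D2a":
        if year.q is None:
            raise ConfigurationError("model D2a requires a driver value q")
    return year
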