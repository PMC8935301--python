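"""Bayesian estimation of the vital-rate models from individual panel data.

The data unit is one individual-year record: log mass m at t, survival
indicator to t+1, reproduction indicator at t+1 (given survival, possibly
missing), log mass at t+1 (given survival, possibly missing) and offspring
log mass (given reproduction, possibly missing).  The likelihood is a sum
of Bernoulli terms (survival, reproduction), Gaussian terms (growth,
offspring size) and, for the copula model, the joint augmented density of
(growth, reproduction).  Missing binary responses are marginalized
analytically; missing Gaussian responses simply drop their term.

Sampling uses adaptive random-walk Metropolis within Gibbs.  Random
effects (year or individual) and the copula auxiliaries are treated as
unobserved parameters and refreshed every iteration with vectorized
blockwise accept/reject (records aggregate to their year/individual via
bincount, so a full sweep costs a handful of array passes regardless of
the number of effects).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

from .copula import copula_loglik_record
from .models import log_normal_pdf
from .params import ConfigurationError, ModelSpec, VitalRateParams

REQUIRED_COLUMNS = ("id", "year", "mass", "surv", "repro", "mass_next", "off_mass")


class ValidationError(ValueError):
    """A record violates the panel invariants."""


@dataclass
class MCMCConfig:
    n_iter: int = 10_000
    n_burnin: int = 4_000
    n_chains: int = 3
    seed: int = 0
    thin: int = 1

    def __post_init__(self) -> None:
        if not self.n_burnin < self.n_iter:
            raise ConfigurationError("n_burnin must be < n_iter")
        if self.n_chains < 1 or self.thin < 1:
            raise ConfigurationError("n_chains and thin must be >= 1")


@dataclass
class PriorConfig:
    """Weakly informative defaults keeping every posterior proper.

    Normal(0, coef_scale^2) on regression coefficients, half-Normal(0,
    sd_scale^2) on residual/effect SDs, Uniform(-1, 1) on correlations.
    """

    coef_scale: float = 10.0
    sd_scale: float = 5.0


# --------------------------------------------------------------------------
# record validation and preparation


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"records table lacks columns {missing}")
    df = records.reset_index(drop=True)
    m = pd.to_numeric(df["mass"], errors="coerce")
    bad = df.index[~np.isfinite(m)]
    if len(bad):
        raise ValidationError(
            f"records {list(bad[:5])} have missing/non-finite mass (the "
            "predictor m must be observed; only responses may be missing)"
        )
    for col in ("surv", "repro"):
        vals = df[col].dropna()
        if not vals.isin([0, 1, 0.0, 1.0, True, False]).all():
            bad = df.index[~df[col].isna() & ~df[col].isin([0, 1])]
            raise ValidationError(f"non-binary {col} indicator at records {list(bad[:5])}")
    both = df["off_mass"].notna() & (df["repro"] != 1)
    if both.any():
        raise ValidationError(
            f"records {list(df.index[both][:5])} have offspring mass without repro = 1"
        )
    dup = df.duplicated(subset=["id", "year"])
    if dup.any():
        raise ValidationError(f"duplicate (id, year) pairs at records {list(df.index[dup][:5])}")
    return df


@dataclass
class _Prepared:
    m: np.ndarray
    surv: np.ndarray
    surv_mask: np.ndarray
    r: np.ndarray
    r_mask: np.ndarray
    mn: np.ndarray
    mn_mask: np.ndarray
    c: np.ndarray
    c_mask: np.ndarray
    year_code: np.ndarray
    years: np.ndarray
    indiv_code: np.ndarray
    indivs: np.ndarray
    newborn: np.ndarray
    alive_mask: np.ndarray  # records eligible for growth/repro terms

    @property
    def n(self) -> int:
        return self.m.size

    @property
    def n_years(self) -> int:
        return self.years.size

    @property
    def n_indiv(self) -> int:
        return self.indivs.size


def prepare_records(records: pd.DataFrame) -> _Prepared:
    df = validate_records(records)
    n = len(df)
    m = df["mass"].to_numpy(float)
    surv = df["surv"].to_numpy(float)
    surv_mask = np.isfinite(surv)
    r = df["repro"].to_numpy(float)
    r_mask = np.isfinite(r)
    mn = df["mass_next"].to_numpy(float)
    mn_mask = np.isfinite(mn)
    c = df["off_mass"].to_numpy(float)
    c_mask = np.isfinite(c)
    year_code, years = pd.factorize(df["year"], sort=True)
    indiv_code, indivs = pd.factorize(df["id"], sort=True)
    if "newborn" in df.columns:
        newborn = df["newborn"].fillna(False).to_numpy(bool)
    else:
        newborn = np.zeros(n, dtype=bool)
    alive = np.where(surv_mask, surv == 1, True)
    return _Prepared(
        m, np.nan_to_num(surv), surv_mask, np.nan_to_num(r), r_mask,
        np.nan_to_num(mn), mn_mask, np.nan_to_num(c), c_mask,
        year_code.astype(np.int64), np.asarray(years),
        indiv_code.astype(np.int64), np.asarray(indivs), newborn, alive,
    )


# --------------------------------------------------------------------------
# likelihood terms


def _bern_logit_ll(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    return y * log_expit(eta) + (1.0 - y) * log_expit(-eta)


def _effect_shifts(
    model: ModelSpec, params: VitalRateParams, prep: _Prepared, effects: Dict
) -> tuple[np.ndarray, np.ndarray]:
    """Per-record shifts (db on the reproduction logit, dg on the growth mean)."""
    mid = model.model_id
    zeros = 0.0
    if mid in ("I2", "D2b"):
        for k in ("u_b", "u_g"):
            if k not in effects:
                raise ConfigurationError(f"model {mid} requires effects[{k!r}] per year")
        return effects["u_b"][prep.year_code], effects["u_g"][prep.year_code]
    if mid == "D2a":
        if "q" not in effects:
            raise ConfigurationError("model D2a requires effects['q'] per year")
        q = effects["q"][prep.year_code]
        return params.beta_bq * q, params.beta_gq * q
    if mid in ("I3", "D3"):
        for k in ("v_b", "v_g"):
            if k not in effects:
                raise ConfigurationError(f"model {mid} requires effects[{k!r}] per individual")
        return effects["v_b"][prep.indiv_code], effects["v_g"][prep.indiv_code]
    return zeros, zeros


def _gr_loglik_terms(
    model: ModelSpec,
    params: VitalRateParams,
    prep: _Prepared,
    effects: Dict,
) -> np.ndarray:
    """Per-record growth + reproduction log-contribution (zeros where absent)."""
    mid = model.model_id
    db, dg = _effect_shifts(model, params, prep, effects)
    eta_b = params.beta_b0 + params.beta_bm * prep.m + db
    mu_g = params.beta_g0 + params.beta_gm * prep.m + dg
    out = np.zeros(prep.n)
    r_obs = prep.r_mask
    g_obs = prep.mn_mask

    if mid == "D1a":
        applies = prep.newborn if model.newborn_only else np.ones(prep.n, bool)
        shift = params.beta_g_given_r * applies
        both = r_obs & g_obs
        out[both] = (
            _bern_logit_ll(prep.r[both], eta_b[both])
            + log_normal_pdf(
                prep.mn[both], mu_g[both] + shift[both] * prep.r[both], params.sigma2_g
            )
        )
        only_r = r_obs & ~g_obs
        out[only_r] = _bern_logit_ll(prep.r[only_r], eta_b[only_r])
        only_g = ~r_obs & g_obs
        if only_g.any():
            # marginalize the missing breeding status out of the growth term
            b = expit(eta_b[only_g])
            f1 = np.exp(
                log_normal_pdf(prep.mn[only_g], mu_g[only_g] + shift[only_g], params.sigma2_g)
            )
            f0 = np.exp(log_normal_pdf(prep.mn[only_g], mu_g[only_g], params.sigma2_g))
            out[only_g] = np.log(b * f1 + (1.0 - b) * f0)
        return out

    if mid == "D1b":
        x_aux = effects.get("x_aux")
        both = r_obs & g_obs
        if both.any():
            if x_aux is None:
                raise ConfigurationError("model D1b requires effects['x_aux'] per record")
            out[both] = copula_loglik_record(
                prep.mn[both], prep.r[both], prep.m[both], x_aux[both], params
            )
        only_r = r_obs & ~g_obs
        out[only_r] = _bern_logit_ll(prep.r[only_r], eta_b[only_r])
        only_g = ~r_obs & g_obs
        # copula margins are untouched: the marginal growth term is Gaussian
        out[only_g] = log_normal_pdf(prep.mn[only_g], mu_g[only_g], params.sigma2_g)
        return out

    out[r_obs] = _bern_logit_ll(prep.r[r_obs], eta_b[r_obs])
    out[g_obs] += log_normal_pdf(prep.mn[g_obs], mu_g[g_obs], params.sigma2_g)
    return out


def _surv_loglik(params: VitalRateParams, prep: _Prepared) -> float:
    msk = prep.surv_mask
    eta = params.beta_s0 + params.beta_sm * prep.m[msk]
    return float(_bern_logit_ll(prep.surv[msk], eta).sum())


def _off_loglik(params: VitalRateParams, prep: _Prepared) -> float:
    msk = prep.c_mask
    mu = params.beta_h0 + params.beta_hm * prep.m[msk]
    return float(log_normal_pdf(prep.c[msk], mu, params.sigma2_h).sum())


def log_likelihood(
    model: ModelSpec,
    params: VitalRateParams,
    records: pd.DataFrame,
    effects: Optional[Dict] = None,
) -> float:
    """Total data log-likelihood under one model variant.

    ``effects`` carries whatever latent structure the model conditions on:
    per-year arrays ``u_b``/``u_g`` (I2, D2b), a per-year driver ``q``
    (D2a), per-individual ``v_b``/``v_g`` (I3, D3), or per-record copula
    auxiliaries ``x_aux`` (D1b).  The random-effect distribution itself is
    not included here (see :func:`log_effects_prior`).
    """
    if len(records) == 0:
        return 0.0
    prep = prepare_records(records)
    effects = effects or {}
    return (
        _surv_loglik(params, prep)
        + _off_loglik(params, prep)
        + float(_gr_loglik_terms(model, params, prep, effects).sum())
    )


def log_effects_prior(model: ModelSpec, params: VitalRateParams, effects: Dict) -> float:
    """Log-density of the latent effects under their model distribution."""
    mid = model.model_id
    if mid in ("I2", "D2b"):
        return float(_bvn_logpdf(effects["u_b"], effects["u_g"], params.year_effect_cov()).sum())
    if mid in ("I3", "D3"):
        return float(
            _bvn_logpdf(effects["v_b"], effects["v_g"], params.individual_effect_cov()).sum()
        )
    return 0.0


def _bvn_logpdf(a: np.ndarray, b: np.ndarray, cov: np.ndarray) -> np.ndarray:
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
    if det <= 0 or cov[0, 0] <= 0 or cov[1, 1] <= 0:
        return np.full(np.shape(a), -np.inf)
    inv00, inv11 = cov[1, 1] / det, cov[0, 0] / det
    inv01 = -cov[0, 1] / det
    quad = inv00 * a * a + 2.0 * inv01 * a * b + inv11 * b * b
    return -np.log(2.0 * np.pi) - 0.5 * np.log(det) - 0.5 * quad


# --------------------------------------------------------------------------
# posterior container and diagnostics


@dataclass
class PosteriorSamples:
    """Post-burn-in MCMC draws, one array of shape (n_chains, n_kept) per
    monitored parameter."""

    draws: Dict[str, np.ndarray]
    model_id: str
    n_burnin: int = 0
    rhat: Dict[str, float] = field(default_factory=dict)

    @property
    def parameters(self) -> list[str]:
        return list(self.draws)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def param_draws(self):
        """Yield one VitalRateParams per retained draw (chains concatenated)."""
        names = [n for n in self.draws if n in _PARAM_FIELDS or n in _SD_FIELDS]
        flat = {n: self.stacked(n) for n in names}
        n_total = self.n_chains * self.n_draws
        for i in range(n_total):
            kwargs = {}
            for n, v in flat.items():
                if n in _SD_FIELDS:
                    kwargs[_SD_FIELDS[n]] = float(v[i]) ** 2
                else:
                    kwargs[n] = float(v[i])
            yield VitalRateParams(**kwargs)

    def to_frame(self) -> pd.DataFrame:
        rows = {"chain": np.repeat(np.arange(self.n_chains), self.n_draws)}
        for name, arr in self.draws.items():
            rows[name] = arr.reshape(-1)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, model_id: str) -> "PosteriorSamples":
        df = pd.read_csv(path)
        chains = np.sort(df["chain"].unique())
        draws = {}
        for name in df.columns:
            if name == "chain":
                continue
            draws[name] = np.stack(
                [df.loc[df["chain"] == c, name].to_numpy() for c in chains]
            )
        return cls(draws, model_id)


#: sampled SD names -> variance field on VitalRateParams
_SD_FIELDS = {
    "sigma_g": "sigma2_g",
    "sigma_h": "sigma2_h",
    "nu_b": "nu2_b",
    "nu_g": "nu2_g",
    "theta_b": "theta2_b",
    "theta_g": "theta2_g",
}
_PARAM_FIELDS = {
    "beta_s0", "beta_sm", "beta_b0", "beta_bm", "beta_g0", "beta_gm",
    "beta_h0", "beta_hm", "beta_g_given_r", "alpha", "beta_bq", "beta_gq",
    "rho", "psi",
}


def gelman_rubin(samples: PosteriorSamples | Dict[str, np.ndarray], threshold: float = 1.05):
    """Potential scale reduction factor per monitored parameter.

    The classic Brooks–Gelman–Rubin statistic: with M chains of length N,
    W the mean within-chain variance and B/N the variance of chain means,
    PSRF = sqrt(((N-1)/N * W + B/N * (1 + 1/M)) / W).  Chains below the
    threshold (default 1.05) are flagged converged.
    """
    draws = samples.draws if isinstance(samples, PosteriorSamples) else samples
    out = {}
    for name, arr in draws.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError("gelman_rubin requires >= 2 chains")
        m_chains, n = arr.shape
        w = arr.var(axis=1, ddof=1).mean()
        b_over_n = arr.mean(axis=1).var(ddof=1)
        if w == 0:
            out[name] = 1.0 if b_over_n == 0 else np.inf
            continue
        v_hat = (n - 1) / n * w + b_over_n * (1.0 + 1.0 / m_chains)
        # values below 1 are a finite-sample artifact; floor at 1
        out[name] = max(1.0, float(np.sqrt(v_hat / w)))
    if isinstance(samples, PosteriorSamples):
        samples.rhat = out
    converged = {k: v < threshold for k, v in out.items()}
    return out, converged


def posterior_summary(samples: PosteriorSamples, quantiles=(0.025, 0.5, 0.975)) -> pd.DataFrame:
    """Means, SDs and equal-tailed quantiles per monitored parameter."""
    rows = []
    for name in samples.parameters:
        v = samples.stacked(name)
        row = {"parameter": name, "mean": v.mean(), "sd": v.std(ddof=1) if v.size > 1 else 0.0}
        for q in quantiles:
            row[f"q{100 * q:g}"] = np.quantile(v, q)
        if samples.rhat:
            row["rhat"] = samples.rhat.get(name, np.nan)
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")


# --------------------------------------------------------------------------
# the sampler


def _logistic_init(y: np.ndarray, m: np.ndarray) -> tuple[float, float]:
    """A few Newton steps of logistic regression for chain initialization."""
    X = np.column_stack([np.ones_like(m), m])
    beta = np.zeros(2)
    for _ in range(8):
        p = expit(X @ beta)
        wgt = np.maximum(p * (1 - p), 1e-6)
        try:
            step = np.linalg.solve((X * wgt[:, None]).T @ X, X.T @ (y - p))
        except np.linalg.LinAlgError:
            break
        beta += step
        if np.max(np.abs(step)) < 1e-8:
            break
    if not np.all(np.isfinite(beta)):
        beta = np.array([np.log(max(y.mean(), 1e-3) / max(1 - y.mean(), 1e-3)), 0.0])
    return float(beta[0]), float(beta[1])


def _ols_init(y: np.ndarray, m: np.ndarray) -> tuple[float, float, float]:
    X = np.column_stack([np.ones_like(m), m])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sd = float(resid.std(ddof=2)) if y.size > 2 else 1.0
    return float(coef[0]), float(coef[1]), max(sd, 1e-3)


class _Chain:
    """One MCMC chain: state, adapted proposal scales, update sweeps.

    Observation subsets (reproduction observed, growth observed, both
    observed, exactly one observed) are materialized once so every update
    touches only the arrays its likelihood half needs.
    """

    def __init__(self, model, prep, priors, rng, q_by_year=None, jitter=0.0):
        self.model = model
        self.mid = model.model_id
        self.prep = prep
        self.priors = priors
        self.rng = rng
        self.q = q_by_year
        self.m_bar = float(prep.m.mean())

        # --- observation subsets
        r_idx = np.flatnonzero(prep.r_mask)
        g_idx = np.flatnonzero(prep.mn_mask)
        self.m_r, self.r_v = prep.m[r_idx], prep.r[r_idx]
        self.yr_r, self.iv_r = prep.year_code[r_idx], prep.indiv_code[r_idx]
        self.m_g, self.mn_v = prep.m[g_idx], prep.mn[g_idx]
        self.yr_g, self.iv_g = prep.year_code[g_idx], prep.indiv_code[g_idx]
        self.nb_r, self.nb_g = prep.newborn[r_idx], prep.newborn[g_idx]
        both = prep.r_mask & prep.mn_mask
        only_r = prep.r_mask & ~prep.mn_mask
        only_g = ~prep.r_mask & prep.mn_mask
        b_idx = np.flatnonzero(both)
        self.m_b, self.r_b, self.mn_b = prep.m[b_idx], prep.r[b_idx], prep.mn[b_idx]
        self.nb_b = prep.newborn[b_idx]
        o_r = np.flatnonzero(only_r)
        self.m_or, self.r_or = prep.m[o_r], prep.r[o_r]
        o_g = np.flatnonzero(only_g)
        self.m_og, self.mn_og, self.nb_og = prep.m[o_g], prep.mn[o_g], prep.newborn[o_g]
        sm = np.flatnonzero(prep.surv_mask)
        self.m_s, self.s_v = prep.m[sm], prep.surv[sm]
        cm = np.flatnonzero(prep.c_mask)
        self.m_c, self.c_v = prep.m[cm], prep.c[cm]

        # --- moment-based initialization, jittered per chain
        st: Dict[str, float] = {}
        sm = prep.surv_mask
        st["beta_s0"], st["beta_sm"] = _logistic_init(prep.surv[sm], prep.m[sm])
        rm = prep.r_mask
        if rm.sum() > 10:
            st["beta_b0"], st["beta_bm"] = _logistic_init(prep.r[rm], prep.m[rm])
        else:
            st["beta_b0"], st["beta_bm"] = 0.0, 0.0
        gm = prep.mn_mask
        st["beta_g0"], st["beta_gm"], st["sigma_g"] = _ols_init(prep.mn[gm], prep.m[gm])
        cm = prep.c_mask
        if cm.sum() > 10:
            st["beta_h0"], st["beta_hm"], st["sigma_h"] = _ols_init(prep.c[cm], prep.m[cm])
        else:
            st["beta_h0"], st["beta_hm"], st["sigma_h"] = 0.0, 0.0, 1.0
        st["beta_g_given_r"] = 0.0
        st["alpha"] = 0.0
        st["beta_bq"] = 0.0
        st["beta_gq"] = 0.0
        st["nu_b"], st["nu_g"], st["rho"] = 0.3, 0.05, 0.0
        st["theta_b"], st["theta_g"], st["psi"] = 0.3, 0.05, 0.0
        for k in st:
            if k not in ("sigma_g", "sigma_h", "nu_b", "nu_g", "theta_b", "theta_g"):
                st[k] += jitter * rng.standard_normal()
        self.state = st

        self.scalar_blocks = self._scalar_blocks()
        self.scales = {name: 0.1 for name, _ in self.scalar_blocks}
        self.acc = {name: [0, 0] for name, _ in self.scalar_blocks}

        self.effects: Dict[str, np.ndarray] = {}
        if self.mid in ("I2", "D2b"):
            self.effects["u_b"] = np.zeros(prep.n_years)
            self.effects["u_g"] = np.zeros(prep.n_years)
        if self.mid in ("I3", "D3"):
            self.effects["v_b"] = np.zeros(prep.n_indiv)
            self.effects["v_g"] = np.zeros(prep.n_indiv)
        if self.mid == "D2a":
            self.effects["q"] = np.asarray(q_by_year, dtype=float)
        if self.mid == "D1b":
            # auxiliaries only exist where the copula term applies
            self.x_aux = rng.uniform(size=self.m_b.size)
        self.vec_scales = {"u_b": 0.3, "u_g": 0.05, "v_b": 0.3, "v_g": 0.05}
        self.vec_acc = {k: [0, 0] for k in self.vec_scales}

        self._gr_ll = self._gr_loglik(self.params())
        self._surv_ll = self._surv_loglik(self.params())
        self._off_ll = self._off_loglik(self.params())

    # -- state <-> params ---------------------------------------------------
    def params(self, **over) -> VitalRateParams:
        st = {**self.state, **over}
        return VitalRateParams(
            beta_s0=st["beta_s0"], beta_sm=st["beta_sm"],
            beta_b0=st["beta_b0"], beta_bm=st["beta_bm"],
            beta_g0=st["beta_g0"], beta_gm=st["beta_gm"],
            beta_h0=st["beta_h0"], beta_hm=st["beta_hm"],
            sigma2_g=st["sigma_g"] ** 2, sigma2_h=st["sigma_h"] ** 2,
            beta_g_given_r=st["beta_g_given_r"], alpha=st["alpha"],
            beta_bq=st["beta_bq"], beta_gq=st["beta_gq"],
            nu2_b=st["nu_b"] ** 2, nu2_g=st["nu_g"] ** 2, rho=st["rho"],
            theta2_b=st["theta_b"] ** 2, theta2_g=st["theta_g"] ** 2, psi=st["psi"],
        )

    def _scalar_blocks(self):
        """(name, which-likelihood) pairs sampled for this model."""
        blocks = [
            ("beta_s0", "surv"), ("beta_sm", "surv"),
            ("beta_h0", "off"), ("beta_hm", "off"), ("sigma_h", "off"),
            ("beta_b0", "gr"), ("beta_bm", "gr"),
            ("beta_g0", "gr"), ("beta_gm", "gr"), ("sigma_g", "gr"),
        ]
        if self.mid == "D1a":
            blocks.append(("beta_g_given_r", "gr"))
        if self.mid == "D1b":
            blocks.append(("alpha", "gr"))
        if self.mid == "D2a":
            blocks += [("beta_bq", "gr"), ("beta_gq", "gr")]
        if self.mid in ("I2", "D2b"):
            blocks += [("nu_b", "hyper"), ("nu_g", "hyper")]
        if self.mid == "D2b":
            blocks.append(("rho", "hyper"))
        if self.mid in ("I3", "D3"):
            blocks += [("theta_b", "hyper"), ("theta_g", "hyper")]
        if self.mid == "D3":
            blocks.append(("psi", "hyper"))
        return blocks

    # -- log-densities ------------------------------------------------------
    def _surv_loglik(self, params) -> float:
        eta = params.beta_s0 + params.beta_sm * self.m_s
        return float(_bern_logit_ll(self.s_v, eta).sum())

    def _off_loglik(self, params) -> float:
        mu = params.beta_h0 + params.beta_hm * self.m_c
        return float(log_normal_pdf(self.c_v, mu, params.sigma2_h).sum())

    def _shift_r(self, params):
        """Reproduction-logit shift on the reproduction-observed subset."""
        if self.mid in ("I2", "D2b"):
            return self.effects["u_b"][self.yr_r]
        if self.mid == "D2a":
            return params.beta_bq * self.effects["q"][self.yr_r]
        if self.mid in ("I3", "D3"):
            return self.effects["v_b"][self.iv_r]
        return 0.0

    def _shift_g(self, params):
        """Growth-mean shift on the growth-observed subset."""
        if self.mid in ("I2", "D2b"):
            return self.effects["u_g"][self.yr_g]
        if self.mid == "D2a":
            return params.beta_gq * self.effects["q"][self.yr_g]
        if self.mid in ("I3", "D3"):
            return self.effects["v_g"][self.iv_g]
        return 0.0

    def _gr_loglik(self, params) -> float:
        mid = self.mid
        s2 = params.sigma2_g
        if mid == "D1a":
            eta_b = params.beta_b0 + params.beta_bm * self.m_b
            mu_b = params.beta_g0 + params.beta_gm * self.m_b
            shift = params.beta_g_given_r * (self.nb_b if self.model.newborn_only else 1.0)
            ll = float(_bern_logit_ll(self.r_b, eta_b).sum())
            ll += float(log_normal_pdf(self.mn_b, mu_b + shift * self.r_b, s2).sum())
            if self.m_or.size:
                eta = params.beta_b0 + params.beta_bm * self.m_or
                ll += float(_bern_logit_ll(self.r_or, eta).sum())
            if self.m_og.size:
                eta = params.beta_b0 + params.beta_bm * self.m_og
                mu = params.beta_g0 + params.beta_gm * self.m_og
                sh = params.beta_g_given_r * (self.nb_og if self.model.newborn_only else 1.0)
                b = expit(eta)
                f1 = np.exp(log_normal_pdf(self.mn_og, mu + sh, s2))
                f0 = np.exp(log_normal_pdf(self.mn_og, mu, s2))
                ll += float(np.log(b * f1 + (1.0 - b) * f0).sum())
            return ll
        if mid == "D1b":
            ll = float(
                copula_loglik_record(self.mn_b, self.r_b, self.m_b, self.x_aux, params).sum()
            )
            if self.m_or.size:
                eta = params.beta_b0 + params.beta_bm * self.m_or
                ll += float(_bern_logit_ll(self.r_or, eta).sum())
            if self.m_og.size:
                mu = params.beta_g0 + params.beta_gm * self.m_og
                ll += float(log_normal_pdf(self.mn_og, mu, s2).sum())
            return ll
        eta = params.beta_b0 + params.beta_bm * self.m_r + self._shift_r(params)
        mu = params.beta_g0 + params.beta_gm * self.m_g + self._shift_g(params)
        return float(_bern_logit_ll(self.r_v, eta).sum()) + float(
            log_normal_pdf(self.mn_v, mu, s2).sum()
        )

    def _log_prior_scalar(self, name: str, value: float) -> float:
        if name in ("sigma_g", "sigma_h", "nu_b", "nu_g", "theta_b", "theta_g"):
            if value <= 0:
                return -np.inf
            return -0.5 * value**2 / self.priors.sd_scale**2
        if name in ("rho", "psi", "alpha"):
            return 0.0 if -1.0 < value < 1.0 else -np.inf
        return -0.5 * value**2 / self.priors.coef_scale**2

    def _effects_hyper_ll(self, params) -> float:
        return log_effects_prior(self.model, params, self.effects)

    # -- scalar updates -----------------------------------------------------
    def _update_scalar(self, name: str, which: str, adapt: bool) -> None:
        cur = self.state[name]
        prop = cur + self.scales[name] * self.rng.standard_normal()
        lp_prop = self._log_prior_scalar(name, prop)
        accepted = False
        if np.isfinite(lp_prop):
            lp_cur = self._log_prior_scalar(name, cur)
            # slope updates carry a compensating intercept shift so the
            # predictor stays centred (removes the slope/intercept ridge)
            shift_pair = {
                "beta_sm": "beta_s0", "beta_bm": "beta_b0",
                "beta_gm": "beta_g0", "beta_hm": "beta_h0",
            }
            over = {name: prop}
            if name in shift_pair:
                icpt = shift_pair[name]
                over[icpt] = self.state[icpt] - (prop - cur) * self.m_bar
                lp_prop += self._log_prior_scalar(icpt, over[icpt])
                lp_cur += self._log_prior_scalar(icpt, self.state[icpt])
            p_prop = self.params(**over)
            if which == "surv":
                ll_prop, ll_cur = self._surv_loglik(p_prop), self._surv_ll
            elif which == "off":
                ll_prop, ll_cur = self._off_loglik(p_prop), self._off_ll
            elif which == "gr":
                ll_prop, ll_cur = self._gr_loglik(p_prop), self._gr_ll
            else:  # hyper: only the random-effect distribution moves
                ll_prop = self._effects_hyper_ll(p_prop)
                ll_cur = self._effects_hyper_ll(self.params())
            if np.log(self.rng.uniform()) < (ll_prop + lp_prop) - (ll_cur + lp_cur):
                self.state.update({k: float(v) for k, v in over.items()})
                if which == "surv":
                    self._surv_ll = ll_prop
                elif which == "off":
                    self._off_ll = ll_prop
                elif which == "gr":
                    self._gr_ll = ll_prop
                accepted = True
        a = self.acc[name]
        a[0] += accepted
        a[1] += 1
        if adapt and a[1] % 25 == 0:
            rate = a[0] / a[1]
            self.scales[name] *= float(np.exp(np.clip(rate - 0.44, -1, 1) * 0.33))

    # -- vectorized random-effect updates -----------------------------------
    def _update_effect_vector(self, key: str, adapt: bool) -> None:
        """Blockwise RW update of one effect vector (all groups at once).

        Groups (years or individuals) are conditionally independent given
        the parameters, so proposals for every group are accepted or
        rejected in parallel; per-record likelihood deltas aggregate to
        their group via bincount and the cached total is updated
        incrementally.
        """
        params = self.params()
        temporal = key.startswith("u")
        n_groups = self.prep.n_years if temporal else self.prep.n_indiv
        cur = self.effects[key]
        prop = cur + self.vec_scales[key] * self.rng.standard_normal(n_groups)
        if key in ("u_b", "v_b"):
            code = self.yr_r if temporal else self.iv_r
            eta0 = params.beta_b0 + params.beta_bm * self.m_r
            t_cur = _bern_logit_ll(self.r_v, eta0 + cur[code])
            t_prop = _bern_logit_ll(self.r_v, eta0 + prop[code])
        else:
            code = self.yr_g if temporal else self.iv_g
            mu0 = params.beta_g0 + params.beta_gm * self.m_g
            t_cur = log_normal_pdf(self.mn_v, mu0 + cur[code], params.sigma2_g)
            t_prop = log_normal_pdf(self.mn_v, mu0 + prop[code], params.sigma2_g)
        delta = np.bincount(code, weights=t_prop - t_cur, minlength=n_groups)
        other = self.effects[{"u_b": "u_g", "u_g": "u_b", "v_b": "v_g", "v_g": "v_b"}[key]]
        cov = params.year_effect_cov() if temporal else params.individual_effect_cov()
        if key in ("u_b", "v_b"):
            prior_delta = _bvn_logpdf(prop, other, cov) - _bvn_logpdf(cur, other, cov)
        else:
            prior_delta = _bvn_logpdf(other, prop, cov) - _bvn_logpdf(other, cur, cov)
        accept = np.log(self.rng.uniform(size=n_groups)) < delta + prior_delta
        self.effects[key] = np.where(accept, prop, cur)
        self._gr_ll += float(delta[accept].sum())
        a = self.vec_acc[key]
        a[0] += int(accept.sum())
        a[1] += n_groups
        if adapt and a[1] % (25 * n_groups) == 0:
            rate = a[0] / a[1]
            self.vec_scales[key] *= float(np.exp(np.clip(rate - 0.44, -1, 1) * 0.33))

    _NC_MAP = {"nu_b": "u_b", "nu_g": "u_g", "theta_b": "v_b", "theta_g": "v_g"}

    def _update_sd_noncentered(self, name: str, adapt: bool) -> None:
        """Joint scale move on an effect SD and its effect vector.

        The centered SD update mixes poorly when the data constrain the
        effects weakly (the classic funnel), so the SD is also updated
        holding the standardized effects fixed: theta' = theta * c with
        c log-normal, v' = c * v.  The effect-prior ratio cancels the
        transform Jacobian, leaving the likelihood delta plus the
        half-Normal prior ratio on the log-theta scale.
        """
        key = self._NC_MAP[name]
        cur = self.state[name]
        sc_name = name + "_nc"
        c = float(np.exp(self.scales.get(sc_name, 0.1) * self.rng.standard_normal()))
        prop = cur * c
        v_cur = self.effects[key]
        v_prop = v_cur * c
        params = self.params()
        if key in ("u_b", "v_b"):
            code = self.yr_r if key == "u_b" else self.iv_r
            eta0 = params.beta_b0 + params.beta_bm * self.m_r
            d_lik = float(
                (_bern_logit_ll(self.r_v, eta0 + v_prop[code])
                 - _bern_logit_ll(self.r_v, eta0 + v_cur[code])).sum()
            )
        else:
            code = self.yr_g if key == "u_g" else self.iv_g
            mu0 = params.beta_g0 + params.beta_gm * self.m_g
            d_lik = float(
                (log_normal_pdf(self.mn_v, mu0 + v_prop[code], params.sigma2_g)
                 - log_normal_pdf(self.mn_v, mu0 + v_cur[code], params.sigma2_g)).sum()
            )
        s2 = self.priors.sd_scale**2
        d_prior = (-0.5 * prop**2 / s2 + np.log(prop)) - (-0.5 * cur**2 / s2 + np.log(cur))
        accepted = np.log(self.rng.uniform()) < d_lik + d_prior
        if accepted:
            self.state[name] = prop
            self.effects[key] = v_prop
            self._gr_ll += d_lik
        a = self.acc.setdefault(sc_name, [0, 0])
        a[0] += accepted
        a[1] += 1
        if sc_name not in self.scales:
            self.scales[sc_name] = 0.1
        if adapt and a[1] % 25 == 0:
            rate = a[0] / a[1]
            self.scales[sc_name] *= float(np.exp(np.clip(rate - 0.44, -1, 1) * 0.33))

    def _update_x_aux(self) -> None:
        """Independence refresh of the copula auxiliaries (per record)."""
        if self.x_aux.size == 0:
            return
        params = self.params()
        prop = self.rng.uniform(size=self.x_aux.size)
        ll_cur = copula_loglik_record(self.mn_b, self.r_b, self.m_b, self.x_aux, params)
        ll_prop = copula_loglik_record(self.mn_b, self.r_b, self.m_b, prop, params)
        accept = np.log(self.rng.uniform(size=self.x_aux.size)) < ll_prop - ll_cur
        self.x_aux = np.where(accept, prop, self.x_aux)
        self._gr_ll += float((ll_prop - ll_cur)[accept].sum())

    # -- one sweep ----------------------------------------------------------
    _sweep_count = 0

    def sweep(self, adapt: bool) -> None:
        self._sweep_count += 1
        if self._sweep_count % 200 == 0:
            # guard against drift from incremental likelihood updates
            self._gr_ll = self._gr_loglik(self.params())
        for name, which in self.scalar_blocks:
            self._update_scalar(name, which, adapt)
        if self.mid in ("I2", "D2b"):
            self._update_effect_vector("u_b", adapt)
            self._update_effect_vector("u_g", adapt)
            self._update_sd_noncentered("nu_b", adapt)
            self._update_sd_noncentered("nu_g", adapt)
        if self.mid in ("I3", "D3"):
            self._update_effect_vector("v_b", adapt)
            self._update_effect_vector("v_g", adapt)
            self._update_sd_noncentered("theta_b", adapt)
            self._update_sd_noncentered("theta_g", adapt)
        if self.mid == "D1b":
            self._update_x_aux()
        if not np.isfinite(self._gr_ll):
            raise RuntimeError(
                f"divergent chain: non-finite log-posterior at state {self.state}"
            )


def _monitored(model: ModelSpec) -> list[str]:
    mid = model.model_id
    names = [
        "beta_s0", "beta_sm", "beta_b0", "beta_bm", "beta_g0", "beta_gm",
        "beta_h0", "beta_hm", "sigma_g", "sigma_h",
    ]
    if mid == "D1a":
        names.append("beta_g_given_r")
    if mid == "D1b":
        names.append("alpha")
    if mid == "D2a":
        names += ["beta_bq", "beta_gq"]
    if mid in ("I2", "D2b"):
        names += ["nu_b", "nu_g"]
    if mid == "D2b":
        names.append("rho")
    if mid in ("I3", "D3"):
        names += ["theta_b", "theta_g"]
    if mid == "D3":
        names.append("psi")
    return names


def fit(
    model: ModelSpec,
    records: pd.DataFrame,
    mcmc: MCMCConfig = MCMCConfig(),
    priors: PriorConfig = PriorConfig(),
    driver: Optional[Dict] = None,
) -> PosteriorSamples:
    """Fit one vital-rate model variant by adaptive Metropolis-within-Gibbs.

    ``driver`` maps year -> covariate value and is required for D2a.
    Proposal scales adapt during burn-in only; chains are seeded
    independently from ``mcmc.seed``.
    """
    if len(records) == 0:
        raise ValidationError("records table is empty")
    prep = prepare_records(records)
    q_by_year = None
    if model.model_id == "D2a":
        if driver is None:
            raise ConfigurationError("model D2a requires a driver mapping year -> q")
        try:
            q_by_year = np.array([float(driver[y]) for y in prep.years])
        except KeyError as exc:
            raise ConfigurationError(f"driver value missing for year {exc}") from exc

    names = _monitored(model)
    n_kept = (mcmc.n_iter - mcmc.n_burnin) // mcmc.thin
    draws = {n: np.empty((mcmc.n_chains, n_kept)) for n in names}
    root = np.random.SeedSequence(mcmc.seed)
    for c, ss in enumerate(root.spawn(mcmc.n_chains)):
        rng = np.random.default_rng(ss)
        chain = _Chain(model, prep, priors, rng, q_by_year, jitter=0.02 * c)
        kept = 0
        for it in range(mcmc.n_iter):
            chain.sweep(adapt=it < mcmc.n_burnin)
            if it >= mcmc.n_burnin and (it - mcmc.n_burnin) % mcmc.thin == 0 and kept < n_kept:
                for n in names:
                    draws[n][c, kept] = chain.state[n]
                kept += 1
    samples = PosteriorSamples(draws, model.model_id, n_burnin=mcmc.n_burnin)
    if mcmc.n_chains >= 2:
        gelman_rubin(samples)
    return samples
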