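"""Individual-based simulator and the model-comparison simulation study.

The simulator forward-iterates a population of individuals under any of
the eight model variants, emitting the same individual-year panel the
fitting code consumes (log mass, survival, reproduction, next mass,
offspring mass, newborn flag), so parameter-recovery and round-trip checks
never need external data.  The study driver draws vital-rate parameters
from their calibration distributions, evaluates every requested model on
the same parameter set and records the growth-rate and elasticity
contrasts against the vanilla model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .copula import sample_copula_pair
from .growth_rate import (
    NAO_MEAN,
    NAO_SD,
    eigen_log_lambda,
    log_lambda,
)
from .kernel import build_kernel, mesh_from_params
from .params import ModelSpec, VitalRateParams
from .perturbation import elasticity

#: calibration distributions of the regression coefficients (mean, sd)
COEFFICIENT_DISTRIBUTIONS: Dict[str, tuple[float, float]] = {
    "beta_s0": (-4.25, 0.05),
    "beta_sm": (1.92, 0.01),
    "beta_b0": (-1.47, 0.05),
    "beta_bm": (0.50, 0.01),
    "beta_g0": (1.20, 0.05),
    "beta_gm": (0.63, 0.01),
    "beta_h0": (0.46, 0.05),
    "beta_hm": (0.57, 0.01),
}

#: fixed variance/driver values used alongside the random coefficients
FIXED_PARAMETERS: Dict[str, float] = {
    "beta_gq": 0.01,
    "sigma2_g": 0.09**2,
    "sigma2_h": 0.2**2,
    "nu2_g": 0.03**2,
    "nu2_b": 0.45**2,
    "theta2_g": 0.03**2,
    "theta2_b": 0.45**2,
}


@dataclass
class SimulationDesign:
    """Configuration of the model-comparison study.

    ``toggles`` maps a model id to the dependence-parameter values swept for
    it (the parameter swept is rho for D2b, psi for D3, beta_bq for D2a;
    I2/I3 carry no toggle).  Elasticity contrasts (of beta_g0, the growth
    intercept) are optional because each one costs two extra stochastic
    growth-rate evaluations per model per replicate.
    """

    models: Sequence[str] = ("I2", "D2b", "I3", "D3", "D2a")
    n_replicates: int = 100
    toggles: Dict[str, Sequence[float]] = field(
        default_factory=lambda: {
            "D2b": (0.45, 0.9),
            "D3": (0.45, 0.9),
            "D2a": (0.1, 0.2),
        }
    )
    L: int = 10_000
    L0: int = 1_000
    seed: int = 0
    n_mesh: int = 50
    n_z: int = 7
    compute_elasticities: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for mid in self.models:
            ModelSpec(mid)  # validates


def draw_parameters(
    seed: int | np.random.Generator = 0,
    fixed_overrides: Optional[Dict[str, float]] = None,
) -> VitalRateParams:
    """One parameter set: coefficients from their calibration normals,
    variances at their fixed values."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kwargs = {
        name: rng.normal(mu, sd) for name, (mu, sd) in COEFFICIENT_DISTRIBUTIONS.items()
    }
    kwargs.update(FIXED_PARAMETERS)
    if fixed_overrides:
        kwargs.update(fixed_overrides)
    return VitalRateParams(**kwargs)


def stationary_size_distribution(params: VitalRateParams, n_mesh: int = 100):
    """(mean, sd) of the stable size distribution of the vanilla kernel."""
    mesh = mesh_from_params(params, n_points=n_mesh)
    K = build_kernel(ModelSpec("I1"), params, mesh, warn_eviction=False)
    vals, vecs = np.linalg.eig(K.matrix)
    lead = np.argmax(vals.real)
    w = np.abs(vecs[:, lead].real)
    w = w / w.sum()
    mean = float(w @ mesh.x_nodes)
    sd = float(np.sqrt(w @ (mesh.x_nodes - mean) ** 2))
    return mean, max(sd, 1e-3)


def simulate_population(
    model: ModelSpec,
    params: VitalRateParams,
    n0: int = 200,
    T: int = 20,
    seed: int | np.random.Generator = 0,
    missing_rate_r: float = 0.0,
    init_mass: Optional[tuple[float, float]] = None,
    driver_mean: float = NAO_MEAN,
    driver_sd: float = NAO_SD,
    max_individuals: int = 2_000_000,
) -> pd.DataFrame:
    """Forward-simulate an individual-level demographic panel.

    Founders draw log mass from the vanilla kernel's stable size
    distribution (Gaussian fit) unless ``init_mass`` = (mean, sd) is given.
    Year effects are drawn once per year (bivariate with correlation rho
    for D2b, a shared driver for D2a), individual effects once per
    individual at birth (bivariate with psi for D3, independent of the
    parent's).  Births are singletons.  ``missing_rate_r`` masks that
    fraction of reproduction records, emulating incomplete breeding
    surveys.  Returns one row per individual-year with the canonical panel
    columns.
    """
    if n0 < 1 or T < 1:
        raise ValueError("n0 and T must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mid = model.model_id
    if init_mass is None:
        init_mass = stationary_size_distribution(params)

    mass = rng.normal(init_mass[0], init_mass[1], size=n0)
    ids = np.arange(n0)
    age = np.ones(n0, dtype=int)  # founders treated as established (not newborn)
    next_id = n0

    def draw_indiv_effects(k: int) -> np.ndarray:
        if mid not in ("I3", "D3") or k == 0:
            return np.zeros((k, 2))
        chol = np.linalg.cholesky(params.individual_effect_cov() + 1e-300 * np.eye(2))
        return rng.standard_normal((k, 2)) @ chol.T

    vb_vg = draw_indiv_effects(n0)

    rows = []
    for t in range(T):
        n_alive = ids.size
        if n_alive == 0:
            import warnings

            warnings.warn(f"population extinct at year {t}; panel truncated")
            break
        if n_alive > max_individuals:
            raise RuntimeError("population exceeded max_individuals; lower T or n0")

        if mid in ("I2", "D2b"):
            chol = np.linalg.cholesky(params.year_effect_cov() + 1e-300 * np.eye(2))
            u_b, u_g = (rng.standard_normal(2) @ chol.T).tolist()
            db, dg = u_b, u_g
        elif mid == "D2a":
            q_t = rng.normal(driver_mean, driver_sd)
            db, dg = params.beta_bq * q_t, params.beta_gq * q_t
        else:
            db = dg = 0.0

        eta_s = params.beta_s0 + params.beta_sm * mass
        alive = rng.uniform(size=n_alive) < expit(eta_s)

        eta_b = params.beta_b0 + params.beta_bm * mass + db
        mu_g = params.beta_g0 + params.beta_gm * mass + dg
        if mid in ("I3", "D3"):
            eta_b = eta_b + vb_vg[:, 0]
            mu_g = mu_g + vb_vg[:, 1]

        r = np.zeros(n_alive, dtype=float)
        m_next = np.full(n_alive, np.nan)
        if mid == "D1b":
            y1, rr = sample_copula_pair(
                rng, mu_g, params.sigma2_g, 1.0 - expit(eta_b), params.alpha
            )
            r[:], m_next[:] = rr, y1
        else:
            r[:] = rng.uniform(size=n_alive) < expit(eta_b)
            shift = 0.0
            if mid == "D1a":
                applies = (age == 0) if model.newborn_only else np.ones(n_alive, bool)
                shift = params.beta_g_given_r * r * applies
            m_next[:] = rng.normal(mu_g + shift, np.sqrt(params.sigma2_g))
        r[~alive] = np.nan
        m_next[~alive] = np.nan

        reproduced = alive & (r == 1.0)
        c_next = np.full(n_alive, np.nan)
        n_births = int(reproduced.sum())
        if n_births:
            mu_h = params.beta_h0 + params.beta_hm * mass[reproduced]
            c_next[reproduced] = rng.normal(mu_h, np.sqrt(params.sigma2_h))

        r_rec = r.copy()
        if missing_rate_r > 0:
            mask = alive & (rng.uniform(size=n_alive) < missing_rate_r)
            r_rec[mask] = np.nan
        c_rec = np.where(np.isnan(r_rec), np.nan, c_next)

        rows.append(
            pd.DataFrame(
                {
                    "id": ids,
                    "year": t,
                    "mass": mass,
                    "surv": alive.astype(float),
                    "repro": r_rec,
                    "mass_next": m_next,
                    "off_mass": c_rec,
                    "newborn": (age == 0),
                }
            )
        )

        # assemble next year's population: survivors plus this year's births
        surv_ids = ids[alive]
        surv_mass = m_next[alive]
        surv_eff = vb_vg[alive]
        child_mass = c_next[reproduced]
        child_ids = next_id + np.arange(n_births)
        next_id += n_births
        ids = np.concatenate([surv_ids, child_ids])
        mass = np.concatenate([surv_mass, child_mass])
        vb_vg = np.vstack([surv_eff, draw_indiv_effects(n_births)])
        age = np.concatenate([age[alive] + 1, np.zeros(n_births, dtype=int)])

    if not rows:
        return pd.DataFrame(
            columns=["id", "year", "mass", "surv", "repro", "mass_next", "off_mass", "newborn"]
        )
    return pd.concat(rows, ignore_index=True)


def _toggle_field(mid: str) -> Optional[str]:
    return {"D2b": "rho", "D3": "psi", "D2a": "beta_bq"}.get(mid)


def run_simulation_study(design: SimulationDesign) -> pd.DataFrame:
    """Per-replicate growth-rate and elasticity contrasts across models.

    Each replicate draws one parameter set; every model in the design is
    evaluated on it (eigenanalysis for fixed kernels, including the
    extended-state kernels of the individual-effect models;
    element-selection for the temporal models).  Contrasts are paired
    through the shared parameter draw; each stochastic evaluation gets its
    own environmental sequence.  Output columns:
    replicate, model, dep_value, log_lambda, d_log_lambda (vs the vanilla
    model) and, when requested, elasticity_bg0 and pct_change_elasticity =
    100 (e_model - e_I1)/e_I1.
    """
    root = np.random.SeedSequence(design.seed)
    rows = []
    for rep, ss in enumerate(root.spawn(design.n_replicates)):
        rng = np.random.default_rng(ss)
        params = draw_parameters(rng)
        mesh = mesh_from_params(params, n_points=design.n_mesh)

        ll_i1 = eigen_log_lambda(
            build_kernel(ModelSpec("I1"), params, mesh, warn_eviction=False)
        ).log_lambda
        e_i1 = np.nan
        if design.compute_elasticities:
            e_i1 = elasticity(ModelSpec("I1"), params, "beta_g0", mesh).elasticity
        rows.append(
            dict(replicate=rep, model="I1", dep_value=0.0, log_lambda=ll_i1,
                 d_log_lambda=0.0, elasticity_bg0=e_i1, pct_change_elasticity=0.0)
        )

        for mid in design.models:
            tf = _toggle_field(mid)
            values = design.toggles.get(mid, (0.0,)) if tf else (0.0,)
            for val in values:
                p = params.replace(**{tf: val}) if tf else params
                model = ModelSpec(mid)
                # fresh environmental sequence per evaluation: contrasts are
                # paired through the parameter draw, not the environment
                sim_seed = int(rng.integers(2**31))
                if mid in ("I3", "D3"):
                    zmesh = mesh_from_params(p, n_points=design.n_mesh, n_z_points=design.n_z)
                    ll = eigen_log_lambda(
                        build_kernel(model, p, zmesh, warn_eviction=False)
                    ).log_lambda
                    use_mesh = zmesh
                else:
                    ll = log_lambda(
                        model, p, mesh, L=design.L, L0=design.L0, seed=sim_seed
                    ).log_lambda
                    use_mesh = mesh
                e_val = np.nan
                pct = np.nan
                if design.compute_elasticities:
                    e_val = elasticity(
                        model, p, "beta_g0", use_mesh, L=design.L, L0=design.L0,
                        seed=sim_seed,
                    ).elasticity
                    pct = 100.0 * (e_val - e_i1) / e_i1
                rows.append(
                    dict(replicate=rep, model=mid, dep_value=val, log_lambda=ll,
                         d_log_lambda=ll - ll_i1, elasticity_bg0=e_val,
                         pct_change_elasticity=pct)
                )
    return pd.DataFrame(rows)
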