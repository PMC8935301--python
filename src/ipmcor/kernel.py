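"""Projection-kernel assembly and midpoint-rule discretization.

The kernel k(x', z' | x, z, d_t) = s(x,z,d_t) [ b(x,z,d_t) h(x',z'|x,z,d_t)
+ g(x',z'|x,z,d_t) ] maps the abundance density at time t to t+1.  The
continuous i-state x (log body mass) is discretized with the midpoint rule
on a uniform grid; for the persistent-heterogeneity models the q-state
z = (v_b, v_g) is discretized on uniform Gaussian quantiles, so the state
vector lives on the product grid with growth block-diagonal in z (an
individual's quality never changes: I{v_g' = v_g}) and offspring entering
each z-cell with the independent offspring-effect weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import ndtri

from . import models
from .copula import copula_growth_margin
from .params import (
    ConfigurationError,
    CopulaSpec,
    IndividualEffects,
    ModelSpec,
    VitalRateParams,
    YearDraw,
    require_effects,
)


class EvictionWarning(UserWarning):
    """Probability mass of the discretized kernel falls outside the mesh."""


@dataclass
class Mesh:
    """Midpoint-rule grid over log mass, optionally crossed with a z grid."""

    x_nodes: np.ndarray
    x_width: float
    bounds: tuple[float, float]
    z_nodes: Optional[np.ndarray] = None  # (n_z, 2) values of (v_b, v_g)
    z_weights: Optional[np.ndarray] = None

    @property
    def n_x(self) -> int:
        return self.x_nodes.size

    @property
    def n_z(self) -> int:
        return 1 if self.z_nodes is None else self.z_nodes.shape[0]

    @property
    def n_states(self) -> int:
        return self.n_x * self.n_z


@dataclass
class KernelOperator:
    """A discretized projection kernel: n_{t+1} = matrix @ n_t.

    Rows index target states, columns source states; the midpoint-rule cell
    width is already folded into the entries, so column sums approximate the
    per-capita outflow s(x)(1 + b(x)).
    """

    matrix: np.ndarray
    mesh: Mesh
    model_id: str
    year: Optional[YearDraw] = None

    def expected_outflow(self) -> np.ndarray:
        return self.matrix.sum(axis=0)


@dataclass
class PopulationState:
    """Density vector over mesh states; total abundance N = sum(n) * dx."""

    n: np.ndarray
    mesh: Mesh

    @property
    def total(self) -> float:
        return float(self.n.sum() * self.mesh.x_width)


def make_mesh(
    data_or_bounds: Union[tuple, Sequence, np.ndarray],
    n_points: int = 100,
    n_z_points: int = 0,
    params: Optional[VitalRateParams] = None,
    pad_sd: float = 4.0,
) -> Mesh:
    """Build a midpoint-rule mesh from explicit bounds or observed masses.

    When an array of observed log masses is passed, bounds extend its range
    by ``pad_sd`` residual standard deviations (growth and offspring-size
    residual SDs, whichever is larger) so eviction stays negligible.  The z
    grid uses ``n_z_points`` uniform quantile midpoints per effect, pushed
    through the Cholesky factor of the individual-effect covariance when
    the effects are correlated; cells carry equal weight.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    arr = np.asarray(data_or_bounds, dtype=float)
    if arr.size == 2 and arr.ndim == 1 and np.ndim(data_or_bounds) == 1:
        lo, hi = float(arr[0]), float(arr[1])
    else:
        if params is None:
            raise ValueError("padding observed data requires params")
        pad = pad_sd * max(np.sqrt(params.sigma2_g), np.sqrt(params.sigma2_h))
        lo, hi = float(arr.min()) - pad, float(arr.max()) + pad
    if not hi > lo:
        raise ValueError(f"degenerate bounds ({lo}, {hi})")
    width = (hi - lo) / n_points
    x_nodes = lo + width * (np.arange(n_points) + 0.5)

    z_nodes = z_weights = None
    if n_z_points > 0:
        if params is None:
            raise ValueError("a z grid requires params for the effect covariance")
        p = (np.arange(n_z_points) + 0.5) / n_z_points
        e = ndtri(p)
        e1, e2 = np.meshgrid(e, e, indexing="ij")
        std_pairs = np.column_stack([e1.ravel(), e2.ravel()])
        cov = params.individual_effect_cov()
        # guard zero variances so Cholesky stays defined
        jitter = np.diag(np.full(2, 1e-300))
        chol = np.linalg.cholesky(cov + jitter)
        z_nodes = std_pairs @ chol.T
        z_weights = np.full(z_nodes.shape[0], 1.0 / z_nodes.shape[0])
    return Mesh(x_nodes, width, (lo, hi), z_nodes, z_weights)


def mesh_from_params(
    params: VitalRateParams,
    n_points: int = 100,
    n_z_points: int = 0,
    pad_sd: float = 4.0,
) -> Mesh:
    """Mesh whose bounds cover the sizes the model itself generates.

    Centres on the growth fixed point m* = beta_g0 / (1 - beta_gm) and the
    mean offspring size at m*, padded by ``pad_sd`` stationary/residual SDs
    inflated for any year or individual effects on growth.
    """
    shrink = 1.0 - params.beta_gm
    if shrink <= 0:
        raise ValueError("mesh_from_params requires beta_gm < 1")
    m_star = params.beta_g0 / shrink
    # bounds chosen so one growth step from the boundary keeps pad_sd
    # residual SDs inside the mesh: x_hi(1 - beta_gm) >= beta_g0 + pad*sd
    sd_g = np.sqrt(params.sigma2_g + params.nu2_g + params.theta2_g)
    hi = m_star + pad_sd * sd_g / shrink
    lo_g = m_star - pad_sd * sd_g / shrink
    sd_h = np.sqrt(params.sigma2_h)
    # offspring of boundary parents must also land inside, which at the low
    # end is a fixed-point condition: lo <= beta_h0 + beta_hm*lo - pad*sd_h
    shrink_h = 1.0 - params.beta_hm
    if shrink_h > 0:
        lo_h = (params.beta_h0 - pad_sd * sd_h) / shrink_h
        hi_h = (params.beta_h0 + pad_sd * sd_h) / shrink_h
    else:
        lo_h, hi_h = lo_g, hi
    lo = min(lo_g, lo_h)
    hi = max(hi, hi_h)
    return make_mesh((lo, hi), n_points, n_z_points, params=params)


def _growth_matrix(
    mesh: Mesh, params: VitalRateParams, model: ModelSpec, year: YearDraw
) -> np.ndarray:
    """g(x_i | x_j) on the mesh for the scalar-state models."""
    x = mesh.x_nodes
    mid = model.model_id
    if mid == "D1a":
        return models.growth_density_marginal_D1a(x[:, None], x[None, :], params)
    if mid == "D1b":
        b = models.reproduction_prob(x, params)
        out = np.empty((mesh.n_x, mesh.n_x))
        for j in range(mesh.n_x):
            spec = CopulaSpec(
                mu=params.beta_g0 + params.beta_gm * x[j],
                sigma2=params.sigma2_g,
                q_fail=1.0 - b[j],
                alpha=params.alpha,
            )
            out[:, j] = copula_growth_margin(x, spec)
        return out
    return models.growth_density(x[:, None], x[None, :], params, model, year)


def build_kernel(
    model: ModelSpec,
    params: VitalRateParams,
    mesh: Mesh,
    year: Optional[YearDraw] = None,
    eviction_tol: float = 1e-3,
    warn_eviction: bool = True,
) -> KernelOperator:
    """Discretize the projection kernel for one model and one year-draw."""
    mid = model.model_id
    if (mesh.z_nodes is not None) != (mid in ("I3", "D3")):
        raise ConfigurationError(
            f"mesh z grid present iff model has individual effects (got {mid})"
        )
    year = require_effects(model, year)
    x = mesh.x_nodes
    dx = mesh.x_width
    s = models.survival_prob(x, params)
    h = models.offspring_density(x[:, None], x[None, :], params)

    if mesh.z_nodes is None:
        b = models.reproduction_prob(x, params, model, year)
        g = _growth_matrix(mesh, params, model, year)
        K = dx * s[None, :] * (b[None, :] * h + g)
        expected = s * (1.0 + b)
    else:
        n_x, n_z = mesh.n_x, mesh.n_z
        w = mesh.z_weights
        K = np.zeros((n_x * n_z, n_x * n_z))
        b_all = np.empty((n_z, n_x))
        for k in range(n_z):
            eff = IndividualEffects(*mesh.z_nodes[k])
            b_all[k] = models.reproduction_prob(x, params, model, indiv=eff)
            g_k = models.growth_density(
                x[:, None], x[None, :], params, model, indiv=eff
            )
            sl = slice(k * n_x, (k + 1) * n_x)
            K[sl, sl] += dx * s[None, :] * g_k
        # offspring: parents in any z-cell send newborns into z' with weight w[z']
        fert = dx * s[None, :] * h  # (n_x, n_x) in x only
        for k in range(n_z):
            src = slice(k * n_x, (k + 1) * n_x)
            block = b_all[k][None, :] * fert
            for kp in range(n_z):
                tgt = slice(kp * n_x, (kp + 1) * n_x)
                K[tgt, src] += w[kp] * block
        expected = (s[None, :] * (1.0 + b_all)).ravel()

    if warn_eviction:
        deficit = float(np.max(expected - K.sum(axis=0)))
        if deficit > eviction_tol:
            warnings.warn(
                f"kernel eviction: max outflow deficit {deficit:.2e} exceeds "
                f"tolerance {eviction_tol:.0e}; widen the mesh bounds",
                EvictionWarning,
                stacklevel=2,
            )
    return KernelOperator(K, mesh, mid, year)


def project(state: PopulationState, K: KernelOperator) -> PopulationState:
    """One time step of the discretized projection, n_{t+1} = K n_t."""
    if state.n.shape[0] != K.matrix.shape[1]:
        raise ValueError(
            f"state dimension {state.n.shape[0]} does not match kernel "
            f"{K.matrix.shape[1]}"
        )
    return PopulationState(K.matrix @ state.n, K.mesh)
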