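"""Vital-rate function behaviour: closed forms, normalization, model nesting."""

import numpy as np
import pytest
from scipy.special import expit

from ipmcor import (
    IndividualEffects,
    InvalidParameterError,
    ModelSpec,
    VitalRateParams,
    YearDraw,
    growth_density,
    growth_density_marginal_D1a,
    offspring_density,
    reproduction_prob,
    survival_prob,
)
from ipmcor.params import ConfigurationError


class TestSurvival:
    def test_zero_coefficients_give_half(self):
        p = VitalRateParams(beta_s0=0.0, beta_sm=0.0)
        assert survival_prob(3.1, p) == pytest.approx(0.5)

    def test_closed_form_at_sheep_means(self, sheep_params):
        # logit^-1(-4.25 + 1.92*2.5) = logit^-1(0.55)
        assert survival_prob(2.5, sheep_params) == pytest.approx(expit(0.55), abs=1e-12)
        assert survival_prob(2.5, sheep_params) == pytest.approx(0.634, abs=5e-4)

    def test_monotone_increasing_in_mass(self, sheep_params):
        m = np.linspace(1.0, 4.0, 50)
        s = survival_prob(m, sheep_params)
        assert np.all(np.diff(s) > 0)

    def test_nonfinite_mass_rejected(self, sheep_params):
        with pytest.raises(ValueError):
            survival_prob(np.nan, sheep_params)


class TestReproduction:
    def test_closed_form_at_sheep_means(self, sheep_params):
        assert reproduction_prob(2.5, sheep_params) == pytest.approx(
            expit(-0.22), abs=1e-12
        )

    def test_zero_year_effect_matches_vanilla(self, temporal_params):
        b_i1 = reproduction_prob(2.5, temporal_params)
        b_i2 = reproduction_prob(
            2.5, temporal_params, ModelSpec("I2"), year=YearDraw(u_b=0.0, u_g=0.0)
        )
        assert b_i2 == pytest.approx(b_i1, abs=0)

    def test_zero_driver_matches_vanilla(self, sheep_params):
        p = sheep_params.replace(beta_bq=0.3, beta_gq=0.1)
        b_d2a = reproduction_prob(2.5, p, ModelSpec("D2a"), year=YearDraw(q=0.0))
        assert b_d2a == pytest.approx(reproduction_prob(2.5, sheep_params))

    def test_missing_required_effect_raises(self, temporal_params):
        with pytest.raises(ConfigurationError):
            reproduction_prob(2.5, temporal_params, ModelSpec("I2"))
        with pytest.raises(ConfigurationError):
            reproduction_prob(2.5, temporal_params, ModelSpec("I3"))


class TestDensities:
    @pytest.mark.parametrize("fn", ["growth", "offspring"])
    def test_normalization_on_wide_grid(self, sheep_params, fn):
        grid = np.linspace(-2, 8, 4001)
        dx = grid[1] - grid[0]
        if fn == "growth":
            dens = growth_density(grid, 2.5, sheep_params)
        else:
            dens = offspring_density(grid, 2.5, sheep_params)
        assert np.trapezoid(dens, dx=dx) == pytest.approx(1.0, abs=1e-6)

    def test_growth_mode_is_linear_predictor(self, temporal_params):
        grid = np.linspace(0, 6, 6001)
        d = growth_density(
            grid, 3.0, temporal_params, ModelSpec("D2b"), year=YearDraw(u_b=0, u_g=0.2)
        )
        expected = temporal_params.beta_g0 + temporal_params.beta_gm * 3.0 + 0.2
        assert grid[np.argmax(d)] == pytest.approx(expected, abs=2e-3)

    def test_offspring_mean_linear_in_parent_mass(self, sheep_params):
        grid = np.linspace(-2, 6, 8001)
        means = []
        for m in (2.0, 3.0):
            d = offspring_density(grid, m, sheep_params)
            means.append(np.trapezoid(grid * d, grid))
        slope = (means[1] - means[0]) / 1.0
        assert slope == pytest.approx(sheep_params.beta_hm, abs=1e-6)

    def test_individual_effect_shifts_growth(self, individual_params):
        d0 = growth_density(3.1, 3.0, individual_params, ModelSpec("I3"),
                            indiv=IndividualEffects(0.0, 0.0))
        base = growth_density(3.1, 3.0, individual_params)
        assert d0 == pytest.approx(base)


class TestD1aMixture:
    def test_zero_shift_collapses_to_vanilla(self, sheep_params):
        grid = np.linspace(1, 5, 200)
        assert growth_density_marginal_D1a(grid, 2.5, sheep_params) == pytest.approx(
            growth_density(grid, 2.5, sheep_params)
        )

    def test_certain_reproduction_gives_shifted_gaussian(self):
        p = VitalRateParams(
            beta_b0=50.0, beta_g0=1.2, beta_gm=0.63, sigma2_g=0.09**2,
            beta_g_given_r=-0.3,
        )
        grid = np.linspace(-1, 6, 400)
        shifted = growth_density(grid - (-0.3), 2.5, p)
        assert growth_density_marginal_D1a(grid, 2.5, p) == pytest.approx(
            shifted, abs=1e-10
        )

    def test_mixture_integrates_to_one(self, sheep_params):
        p = sheep_params.replace(beta_g_given_r=-0.3)
        grid = np.linspace(-2, 8, 8001)
        d = growth_density_marginal_D1a(grid, 2.5, p)
        assert np.trapezoid(d, grid) == pytest.approx(1.0, abs=1e-6)

    def test_covariance_identity_by_sampling(self, rng):
        # cov(m', r') = beta_g_given_r * b(1-b), largest in magnitude at b=0.5
        shift = -0.3
        # mass chosen so the reproduction probability is exactly one half
        m_half = 1.47 / 0.5
        p = VitalRateParams(
            beta_b0=-1.47, beta_bm=0.5, beta_g0=1.2, beta_gm=0.63,
            sigma2_g=0.09**2, beta_g_given_r=shift,
        )
        n = 100_000
        from ipmcor import reproduction_prob

        b = float(reproduction_prob(m_half, p))
        assert b == pytest.approx(0.5, abs=1e-12)
        r = (rng.uniform(size=n) < b).astype(float)
        mu = p.beta_g0 + p.beta_gm * m_half
        m_next = rng.normal(mu + shift * r, 0.09)
        cov = np.cov(m_next, r)[0, 1]
        expected = shift * b * (1 - b)
        se = np.sqrt(
            (0.09**2 * b * (1 - b) + shift**2 * b * (1 - b) * (1 - 2 * b * (1 - b))) / n
        )
        assert expected == pytest.approx(-0.075)
        assert abs(cov - expected) < 3 * max(se, 1e-4)

    def test_covariance_magnitude_maximized_at_half(self):
        b = np.linspace(0.01, 0.99, 99)
        mag = np.abs(-0.3 * b * (1 - b))
        assert b[np.argmax(mag)] == pytest.approx(0.5, abs=1e-9)


class TestModelNesting:
    """All eight variants collapse to the vanilla model when every
    dependence/heterogeneity parameter is zero."""

    @pytest.mark.parametrize("mid", ["I1", "I2", "I3", "D1a", "D2a", "D2b", "D3"])
    def test_growth_density_reduces_to_vanilla(self, sheep_params, mid):
        model = ModelSpec(mid)
        kw = {}
        if mid in ("I2", "D2b"):
            kw["year"] = YearDraw(u_b=0.0, u_g=0.0)
        elif mid == "D2a":
            kw["year"] = YearDraw(q=0.0)
        elif mid in ("I3", "D3"):
            kw["indiv"] = IndividualEffects(0.0, 0.0)
        grid = np.linspace(1, 5, 101)
        if mid == "D1a":
            got = growth_density_marginal_D1a(grid, 2.5, sheep_params)
        else:
            got = growth_density(grid, 2.5, sheep_params, model, **kw)
        assert got == pytest.approx(growth_density(grid, 2.5, sheep_params))


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(sigma2_g=0.0), dict(sigma2_h=-1.0), dict(rho=1.0), dict(psi=-1.2),
         dict(alpha=1.5), dict(nu2_b=-0.1)],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            VitalRateParams(**kwargs)

    def test_unknown_model_id_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelSpec("D4")
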