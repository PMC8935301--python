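"""Individual-based simulator and the model-comparison study driver."""

import numpy as np
import pytest

from ipmcor import (
    ModelSpec,
    SimulationDesign,
    VitalRateParams,
    draw_parameters,
    run_simulation_study,
    simulate_population,
)
from ipmcor.synthetic import COEFFICIENT_DISTRIBUTIONS, FIXED_PARAMETERS


class TestDrawParameters:
    def test_fixed_values_are_constants(self):
        p = draw_parameters(0)
        assert p.sigma2_h == pytest.approx(0.04)
        assert p.sigma2_g == pytest.approx(0.09**2)
        assert p.beta_gq == pytest.approx(0.01)
        assert p.nu2_b == pytest.approx(0.45**2)
        assert p.theta2_g == pytest.approx(0.03**2)

    def test_coefficient_means_match_calibration(self):
        rng = np.random.default_rng(1)
        draws = [draw_parameters(rng) for _ in range(10_000)]
        for name, (mu, sd) in COEFFICIENT_DISTRIBUTIONS.items():
            vals = np.array([getattr(d, name) for d in draws])
            assert vals.mean() == pytest.approx(mu, abs=3 * sd / np.sqrt(10_000))
            assert vals.std() == pytest.approx(sd, rel=0.05)

    def test_seeded_determinism(self):
        assert draw_parameters(7) == draw_parameters(7)
        assert draw_parameters(7) != draw_parameters(8)


class TestSimulatePopulation:
    def test_immortal_sterile_population_is_static(self):
        p = VitalRateParams(
            beta_s0=60.0, beta_b0=-60.0, beta_g0=1.2, beta_gm=0.63,
            beta_h0=0.46, beta_hm=0.57, sigma2_g=0.09**2, sigma2_h=0.04,
        )
        panel = simulate_population(ModelSpec("I1"), p, n0=40, T=6, seed=0,
                                    init_mass=(3.0, 0.1))
        assert panel.id.nunique() == 40
        assert (panel.groupby("id").size() == 6).all()
        assert (panel.surv == 1).all()
        assert panel.off_mass.isna().all()

    def test_growth_block_recovered_by_least_squares(self, sheep_params):
        panel = simulate_population(ModelSpec("I1"), sheep_params, n0=400, T=20, seed=5)
        obs = panel.dropna(subset=["mass_next"])
        assert len(obs) > 5_000
        X = np.column_stack([np.ones(len(obs)), obs["mass"]])
        coef, *_ = np.linalg.lstsq(X, obs["mass_next"], rcond=None)
        resid_sd = np.std(obs["mass_next"] - X @ coef)
        n = len(obs)
        se_slope = 0.09 / (np.std(obs["mass"]) * np.sqrt(n))
        assert coef[1] == pytest.approx(sheep_params.beta_gm, abs=3 * se_slope)
        assert resid_sd == pytest.approx(0.09, rel=0.05)

    def test_copula_dependence_matches_quadrature_implied_value(self, sheep_params, rng):
        """Negative copula correlation shows up as negative correlation
        between breeding status and the growth residual, at the strength
        implied by integrating the joint density."""
        from ipmcor.copula import copula_joint_density
        from ipmcor.params import CopulaSpec

        alpha = -0.8
        p = sheep_params.replace(alpha=alpha)
        panel = simulate_population(ModelSpec("D1b"), p, n0=400, T=15, seed=6)
        obs = panel.dropna(subset=["mass_next", "repro"])
        resid = obs["mass_next"] - (p.beta_g0 + p.beta_gm * obs["mass"])
        emp = np.corrcoef(obs["repro"], resid)[0, 1]
        assert emp < -0.3

        # quadrature oracle at the panel's mean reproduction rate
        from scipy.special import expit

        m_ref = float(obs["mass"].mean())
        q_fail = 1.0 - float(expit(p.beta_b0 + p.beta_bm * m_ref))
        spec = CopulaSpec(mu=0.0, sigma2=p.sigma2_g, q_fail=q_fail, alpha=alpha)
        y1 = np.linspace(-0.45, 0.45, 601)
        y3 = np.linspace(1.0, 2.0, 301)
        Y1, Y3 = np.meshgrid(y1, y3, indexing="ij")
        joint = copula_joint_density(Y1, Y3, spec)
        e_y1_r1 = np.trapezoid(np.trapezoid(Y1 * joint, y3, axis=1), y1)
        cov = e_y1_r1  # E[y1] = 0, so cov(y1, r) = E[y1 * 1{r=1}]
        implied = cov / (np.sqrt(p.sigma2_g) * np.sqrt(q_fail * (1 - q_fail)))
        assert emp == pytest.approx(implied, abs=0.06)

    def test_missing_rate_masks_reproduction(self, sheep_params):
        panel = simulate_population(
            ModelSpec("I1"), sheep_params, n0=300, T=10, seed=7, missing_rate_r=0.25
        )
        alive = panel[panel.surv == 1]
        frac = alive.repro.isna().mean()
        assert frac == pytest.approx(0.25, abs=0.02)
        # masking reproduction also hides the offspring record
        assert panel.loc[panel.repro.isna(), "off_mass"].isna().all()

    def test_panel_round_trips_through_io(self, small_panel, tmp_path):
        from ipmcor import read_demography_csv, write_demography_csv

        path = tmp_path / "panel.csv"
        write_demography_csv(small_panel, path)
        table = read_demography_csv(path)
        assert len(table) == len(small_panel)
        assert table.records["mass"].to_numpy() == pytest.approx(
            small_panel["mass"].to_numpy()
        )
        assert int(table.records["repro"].isna().sum()) == int(small_panel["repro"].isna().sum())

    def test_extinction_truncates_with_warning(self):
        p = VitalRateParams(
            beta_s0=-60.0, beta_b0=-60.0, beta_g0=1.2, beta_gm=0.63,
            sigma2_g=0.01, sigma2_h=0.01,
        )
        with pytest.warns(UserWarning, match="extinct"):
            panel = simulate_population(ModelSpec("I1"), p, n0=5, T=10, seed=0,
                                        init_mass=(3.0, 0.1))
        assert panel.year.max() == 0

    def test_invalid_sizes_rejected(self, sheep_params):
        with pytest.raises(ValueError):
            simulate_population(ModelSpec("I1"), sheep_params, n0=0, T=5)


class TestSimulationStudy:
    def test_vanilla_only_design_has_zero_differences(self):
        design = SimulationDesign(models=("I1",), n_replicates=2, toggles={},
                                  L=500, L0=50, n_mesh=45)
        out = run_simulation_study(design)
        assert out["d_log_lambda"].to_numpy() == pytest.approx(0.0, abs=1e-14)

    def test_study_output_shape_and_determinism(self):
        design = SimulationDesign(
            models=("I2", "D2b"), n_replicates=2, toggles={"D2b": (0.5,)},
            L=800, L0=100, n_mesh=30, seed=5,
        )
        a = run_simulation_study(design)
        b = run_simulation_study(design)
        assert len(a) == 2 * 3  # I1 + I2 + D2b(0.5) per replicate
        assert a["log_lambda"].to_numpy() == pytest.approx(b["log_lambda"].to_numpy())

    def test_elasticity_contrast_computed_on_request(self):
        design = SimulationDesign(models=("I3",), n_replicates=1, toggles={},
                                  n_mesh=45, n_z=3, compute_elasticities=True)
        out = run_simulation_study(design)
        i3 = out[out.model == "I3"].iloc[0]
        assert np.isfinite(i3.elasticity_bg0)
        assert np.isfinite(i3.pct_change_elasticity)

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            SimulationDesign(n_replicates=0)
        with pytest.raises(Exception):
            SimulationDesign(models=("I9",))
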