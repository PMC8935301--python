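"""Simulate an individual-level demographic panel and refit it by MCMC.

The simulator produces one row per individual-year (log mass, survival,
reproduction, next mass, offspring mass), here under correlated year
effects (model D2b), with 10% of reproduction records masked to mimic
incomplete breeding surveys.  The fit marginalizes the missing records
analytically and samples year effects alongside the parameters.
"""

from ipmcor import (
    MCMCConfig,
    ModelSpec,
    VitalRateParams,
    fit,
    posterior_summary,
    simulate_population,
)

truth = VitalRateParams(
    beta_s0=-4.25, beta_sm=1.92, beta_b0=-1.47, beta_bm=0.50,
    beta_g0=1.20, beta_gm=0.63, beta_h0=0.46, beta_hm=0.57,
    sigma2_g=0.09**2, sigma2_h=0.2**2,
    nu2_b=0.45**2, nu2_g=0.03**2, rho=0.5,
)
panel = simulate_population(
    ModelSpec("D2b"), truth, n0=200, T=25, seed=3, missing_rate_r=0.1
)
print(f"simulated {len(panel)} records, {panel.id.nunique()} individuals, "
      f"{panel.year.nunique()} years")

samples = fit(
    ModelSpec("D2b"), panel,
    MCMCConfig(n_iter=5000, n_burnin=2000, n_chains=2, seed=4),
)
summary = posterior_summary(samples)
print(summary.round(3)[["mean", "sd", "q2.5", "q97.5", "rhat"]].to_string())
print("\nThe year-effect correlation rho (truth 0.5) is recovered with a wide")
print("interval: 25 years give only 25 effect pairs to learn it from.")
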