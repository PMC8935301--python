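"""Stochastic growth rate under correlated year effects (element selection).

Year effects (u_b, u_g) shift the reproduction logit and the growth mean
each year; their correlation rho couples the two vital rates through the
shared environment.  The stochastic growth rate is estimated by iterating
randomly drawn yearly kernels and averaging log abundance increments
after a burn-in.
"""

from ipmcor import ModelSpec, VitalRateParams, mesh_from_params, stochastic_log_lambda

params = VitalRateParams(
    beta_s0=-4.25, beta_sm=1.92, beta_b0=-1.47, beta_bm=0.50,
    beta_g0=1.20, beta_gm=0.63, beta_h0=0.46, beta_hm=0.57,
    sigma2_g=0.09**2, sigma2_h=0.2**2,
    nu2_b=0.45**2, nu2_g=0.03**2,
)
mesh = mesh_from_params(params, n_points=50)

for rho in (0.0, 0.45, 0.9):
    model = ModelSpec("I2" if rho == 0 else "D2b")
    est = stochastic_log_lambda(
        model, params.replace(rho=rho), mesh, L=10_000, L0=1_000, seed=1
    )
    print(f"rho = {rho:.2f}: log lambda_s = {est.log_lambda:.5f} (se {est.se:.5f})")
print("Environmental variance lowers the stochastic growth rate below the")
print("deterministic value (~0.0263).  The additional effect of rho is of")
print("the same order as the simulation standard error for a single")
print("sequence; averaged over replicates it is a further small decrease")
print("(see examples/05_model_comparison_study.py).")
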