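"""The Gaussian copula couples growth and reproduction without changing
the population projection.

A copula preserves its margins, and the kernel depends on the vital rates
only through their margins, so the copula kernel (built here by numerical
integration of the joint density) matches the independent kernel — and so
do growth rate and elasticities — for any copula correlation alpha.
"""

from ipmcor import VitalRateParams, copula_invariance_check, mesh_from_params

params = VitalRateParams(
    beta_s0=-4.25, beta_sm=1.92, beta_b0=-1.47, beta_bm=0.50,
    beta_g0=1.20, beta_gm=0.63, beta_h0=0.46, beta_hm=0.57,
    sigma2_g=0.09**2, sigma2_h=0.2**2,
)
mesh = mesh_from_params(params, n_points=80)
report = copula_invariance_check(params, mesh, alphas=(-0.7, 0.0, 0.7))

print(f"vanilla log lambda: {report['log_lambda_I1']:.6f}")
for alpha, entry in report["alphas"].items():
    print(
        f"alpha = {alpha:+.1f}: |log lambda gap| = {entry['log_lambda_gap']:.2e}, "
        f"max elasticity gap = {entry['max_elasticity_gap']:.2e}"
    )
print("Gaps at machine precision: the dependence is demographically invisible,")
print("though it changes the joint law of individual growth and breeding.")
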