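"""Mini model-comparison study: how heterogeneity moves the growth rate.

Each replicate draws one set of vital-rate coefficients from the
calibration distributions and evaluates several heterogeneity structures
on it; differences in log lambda_s are paired within replicate.
(The full-scale study uses 100 replicates and L = 10,000 years.)
"""

from ipmcor import SimulationDesign, run_simulation_study

design = SimulationDesign(
    models=("I2", "D2b", "I3", "D3"),
    n_replicates=5,
    toggles={"D2b": (0.9,), "D3": (0.9,)},
    L=4_000, L0=400, seed=7, n_mesh=50, n_z=5,
)
out = run_simulation_study(design)
summary = out.groupby(["model", "dep_value"])["d_log_lambda"].agg(["mean", "std"])
print(summary.round(5).to_string())
print("\nNegative means for the temporal models (I2, D2b): year-to-year")
print("variation lowers the stochastic growth rate, more with correlation.")
print("Positive means for the individual-effect models (I3, D3): persistent")
print("quality differences raise it.")
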