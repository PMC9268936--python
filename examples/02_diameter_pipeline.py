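"""Full diameter-estimation pipeline on synthetic phantom data.

Generates a seeded, noisy ten-step withdrawal experiment (instrument-style
sweeps: |Z| and phase over ten log-spaced frequencies, 1 kHz - 1 MHz),
inverts every sweep to a parallel-RC resistance, applies the Nyboer
parallel-branch inversion to get the arterial cross-section per frequency,
and prints the per-step estimate against the pump reference.
"""
import wristbia as wb
from wristbia.diameter import run_group_experiment
from wristbia.synthetic import NoiseModel, PhantomSpec, generate_group_experiment

spec = PhantomSpec()
bundle = generate_group_experiment(spec, group="B",
                                   noise=NoiseModel(seed=7), mode="nyboer")

res = run_group_experiment(bundle.experiment, bundle.basal_sweep,
                           list(bundle.step_sweeps),
                           l_pu=bundle.l_pu, sigma_b=spec.blood_sigma)

cols = ["step", "dv_mm3", "d_ref_mm", "d_est_mm", "d_sd_mm", "pe_percent"]
print(res.table[cols].round(4).to_string(index=False))
print(f"\nmean percent error: {res.table['pe_percent'].mean():.3f}%")
# d_est tracks d_ref to within a fraction of a percent: the residual error
# is purely the injected 0.3% |Z| / 0.1 deg instrument noise, since the
# inversion is the exact algebraic inverse of the volume-loss model.

# The same data in "area_conserving" mode shows the systematic
# under-estimation seen with real gel phantoms, growing non-linearly:
bundle_ac = generate_group_experiment(spec, group="B",
                                      noise=NoiseModel(0.0, 0.0, 0),
                                      mode="area_conserving")
res_ac = run_group_experiment(bundle_ac.experiment, bundle_ac.basal_sweep,
                              list(bundle_ac.step_sweeps),
                              l_pu=bundle_ac.l_pu, sigma_b=spec.blood_sigma)
print("\narea-conserving mode (withdrawn blood replaced by gel):")
print(res_ac.table[["step", "d_ref_mm", "d_est_mm", "pe_percent"]]
      .round(4).to_string(index=False))
a2 = res_ac.pe_fit_quadratic.coefficients[0]
print(f"quadratic PE-vs-volume curvature: {a2:.3e} (> 0: convex error growth)")
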