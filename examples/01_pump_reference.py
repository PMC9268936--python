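"""Pump-reference calibration: withdrawn volume -> reference diameter.

Builds the ten-step withdrawal protocol of the wrist-phantom experiment
(80.98 mm^3 of blood simulant per constriction, 175 mm artery, 3.98 mm
initial diameter) and prints the reference cross-sectional area change and
absolute diameter after each step.  These are the ground-truth values any
impedance-based estimate is judged against.
"""
import wristbia as wb

exp = wb.PumpExperiment(
    d0=3.98e-3, artery_length=0.175,
    steps=tuple(80.98e-9 * k for k in range(1, 11)),
)

print(f"basal area A0 = {exp.basal_area * 1e6:.2f} mm^2")
print(f"{'step':>4} {'dV (mm^3)':>10} {'dA (mm^2)':>10} {'d_ref (mm)':>10}")
for k, dv in enumerate(exp.steps, start=1):
    da = wb.reference_area_change(dv, exp.artery_length)
    d = wb.reference_diameter(exp, dv)
    print(f"{k:>4} {dv * 1e9:>10.2f} {da * 1e6:>10.4f} {d * 1e3:>10.2f}")

# The single large withdrawal used with every electrode configuration:
dv_a = 647.83e-9
print(f"\nlarge withdrawal {dv_a * 1e9:.2f} mm^3 -> "
      f"dA = {wb.reference_area_change(dv_a, 0.175) * 1e6:.4f} mm^2, "
      f"d_ref = {wb.reference_diameter(exp, dv_a) * 1e3:.2f} mm")
# The diameter falls from 3.98 mm to 3.15 mm over the full protocol; the
# estimator should track exactly this staircase.
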