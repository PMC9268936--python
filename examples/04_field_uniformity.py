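"""Electrode-configuration study with the quasi-static voxel solver.

Solves the current-injection problem on the stage-1 wrist model (fat,
muscle, blood-filled artery) for band and spot drive electrodes, and
prints the centreline current-density uniformity and the pick-up transfer
resistance at several spacings.  A 2 mm grid keeps this demo fast; the
production analyses use 1 mm.
"""
import numpy as np

from wristbia.fields import (
    build_wrist_model,
    centerline_current_density,
    solve_quasistatic,
    transfer_resistance,
    uniformity_metric,
)

GRID = 2e-3
WINDOW = (0.020, 0.080)  # central window along the 100 mm segment

print("centreline |J| coefficient of variation (lower = more uniform):")
for etype in ("band", "spot"):
    for l_cc in (0.050, 0.070, 0.090):
        m = build_wrist_model("model1", etype, l_cc=l_cc, grid=GRID)
        sol = solve_quasistatic(m, f=1e5, mode="real")
        z, j = centerline_current_density(sol, m)
        cv = uniformity_metric(z, j, WINDOW)
        print(f"  {etype:>4} L_CC={l_cc * 1e3:>3.0f} mm  CV = {cv:.4f}")
# Band electrodes give a far flatter profile than spots, and wider drive
# spacing helps both: the basis for driving with bands and sensing with
# closely spaced inner electrodes.

m = build_wrist_model("model1", "band", l_cc=0.090, grid=GRID)
sol = solve_quasistatic(m, f=1e5, mode="complex")
print("\npick-up transfer resistance (band drive, L_CC = 90 mm):")
for l_pu in (0.010, 0.030, 0.050):
    zc = 0.050
    r = transfer_resistance(sol, m, (zc - l_pu / 2, zc + l_pu / 2))
    print(f"  L_PU={l_pu * 1e3:>2.0f} mm  R = {r:7.2f} ohm")
# R scales almost exactly with L_PU in the uniform central region, the
# proportionality the lumped parallel-tissue model predicts.
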