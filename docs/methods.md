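# Methods

This note records the models implemented in `wristbia`, their
assumptions, the defaults that matter, and the choices made where the
design was genuinely open.

## Parallel-tissue circuit

The wrist segment between the pick-up electrodes is treated as a bundle
of tissue prisms (skin, fat, muscle, blood, cortical and cancellous bone)
conducting in parallel under a uniform axial current density:
R_overall = L_PU / Σ σᵢ(f)·Aᵢ.  The assumptions are the standard ones for
segmental bioimpedance: homogeneous bulk properties per tissue, current
parallel to the limb axis, and geometry constant over the measurement.
These fail near the drive electrodes — quantifying *how much* they fail
for a given electrode layout is exactly what the field solver is for.

**Stage geometries.**  The cuboid segment is 50 mm × 30 mm × 100 mm.
Stage `model1` contains a 3 mm fat ring, muscle, and a circular artery
(basal diameter 2.5 mm); `model2` adds a 1.5 mm skin ring; `model3` adds
a rectangular bone block (cortical shell, thickness chosen to give the
cortical 40 % of the bone area, around a cancellous core) sized to
replace 68 % of the stage-1 muscle area.  Skin thickness, bone placement
and the cortical share are not published for the reference geometry; the
values here are anatomically reasonable defaults and all configurable via
`WristGeometry`.  The artery sits with 3 mm of cover below the top
surface (interpreted as cover-to-artery-top; the centreline option is a
one-line change in `WristGeometry`) and is carved last, overriding any
layer it intersects.

**Dielectric tables.**  Defaults are literature-style β-dispersion curves
tabulated on the eleven simulation frequencies (1 kHz, 100 kHz … 1 MHz)
with log-frequency linear interpolation, anchored to two printed values
(dry skin 0.00065738 S/m at 1 kHz; blood within 0.70–0.82 S/m across the
band) and to the qualitative orderings of the tissues (skin overtakes fat
near 50 kHz and cancellous bone near 200 kHz).  They are plausible
curves, not a reproduction of any specific published table, and are
overridable from CSV.  Consequence: the surrounding-tissue mixture
conductivity of the default `model3` composition spans ≈0.06–0.13 S/m
over the band, which brackets a gelatine-simulant target at the high end
but sits below the ≈0.1 S/m low-frequency figure quoted for the original
geometry — that figure depends on unpublished per-tissue areas, so it is
treated as a plausibility check, not an assertion.  Queries outside the
tabulated grid are rejected rather than extrapolated.

## Parallel-RC inversion

Re(Z) = Rs/(1+(2πfRsCs)²), Im(Z) = −2πfRs²Cs/(1+(2πfRsCs)²), inverted in
closed form as Rs = (Re²+Im²)/Re, Cs = −Im/(2πf(Re²+Im²)).  Phase is
instrument-style degrees, negative for capacitive loads.  Samples with
positive Im(Z) — inductive noise artifacts — clamp Cs to 0 with a logged
warning instead of raising, so noisy sweeps flow through the pipeline;
Re(Z) ≤ 0 is rejected as non-passive.

## Diameter pipeline

Per frequency, both sweeps are inverted to Rs; the estimated area is
Â = A₀ + L_PU·(R₀−Rt)/(σ̄·R₀·Rt) and d̂ = 2√(Â/π), aggregated as
arithmetic mean ± sample SD (n−1) over frequencies.  Frequencies where
Â < 0 are excluded from the aggregate and logged; only if every frequency
fails does the estimate raise.  The blood conductivity σ̄ defaults to
0.7283 S/m — the midpoint of the measured saline-simulant band
(0.7171–0.7395 S/m) — as a single frequency-independent scalar; a
per-frequency array mode exists for simulation-style analyses.  When the
resistance does not change, the pulsatile branch is reported as an open
sentinel (`rp is None`), never a float infinity.

The pump reference uses an artery length of 175 mm.  That constant is not
part of the measured protocol table; it is fixed by requiring
ΔV/L_artery to reproduce the documented volume/area pair
(647.83 mm³ → 3.7019 mm²) and is cross-validated in the tests against all
ten protocol rows at two-decimal precision.

`run_group_experiment` reports OLS trend fits (degree 1 and 2, with R²)
of percent error versus cumulative withdrawn volume; no significance
testing is attached, matching how such protocols are usually reported.

## Conductivity cell

σ = l/(R·S) per measurement (pin spacing l, plate area S, default
1000 mm²; spacings 5–40 mm in 5 mm steps), pooled as mean ± unbiased
(n−1) SD.  Before pooling, per-row conductivities at equal spacing must
agree within a configurable relative threshold (default 5 %) — the
uniformity verification is stated qualitatively in typical protocols, so
the 5 % gate is this package's own explicit criterion.

## Field solver

A simplified stand-in for full FEM: ∇·(κ∇V) = 0 with
κ = σ + j·2πf·ε₀·εr on a regular voxel grid (default 1 mm), 7-point
finite volumes with harmonic-mean face admittivities, uniform inward
current density on the CC+ patch and outward on CC− (default 1 mA),
zero-flux elsewhere.  At ≤1 MHz over a 10 cm segment the quasi-static
approximation is standard; no radiation boundary is needed on an
insulated surface.  The singular Neumann system is gauged by grounding
one interior voxel (equivalent to substituting V=0 there; the dropped
equation is implied by charge conservation) and solved with
Jacobi-preconditioned CG (real mode) or BiCGSTAB (complex mode) to a
relative residual of 1e-8; non-convergence raises with the residual
attached.  The solve is deterministic for fixed inputs.

**Anti-aliased voxelization.**  Per-voxel tissue occupancy fractions are
computed by 8×8 sub-cell sampling of the exact 2-D cross-section, and the
voxel admittivity is the area-weighted mixture.  This makes derived
quantities smooth in the artery diameter — required to resolve the
≈0.01 Ω resistance differences between 2.40 and 2.60 mm arteries, which
binary 1 mm voxelization would quantize away — and makes area fractions
grid-converged (halving the grid moves them by ≪2 %).

**Electrodes.**  Spot electrodes are 10 mm discs on the top surface over
the artery; bands are full rings of 10 mm width (both widths match the
copper-tape hardware; the spot diameter is unpublished and configurable).
PU sensing is post-processing only: the transfer impedance is the
potential difference along a surface-adjacent line above the artery,
interpolated to the exact PU positions and reduced to a resistance via
the RC inversion at the solve frequency.  For reciprocity checks a
patch-averaged four-electrode transfer impedance is provided; with the
symmetric discrete operator, swapping drive and sense is exact to solver
tolerance.

**Verification.**  On a homogeneous block with full-face electrodes the
end-to-end resistance matches L/(σA) (within 2 % at 1 mm; the line-fit
extraction removes the half-cell offset), interior transverse planes
carry the injected current to <0.5 %, and doubling σ halves all transfer
impedances.  The electrode-configuration claims are checked as orderings
(band more uniform than spot; wider CC spacing more uniform; resistance
strictly decreasing in artery diameter), not as absolute reproductions of
any FEM's numbers.

## Synthetic phantom experiments

The generator emulates the pump-driven wrist phantom: artery d₀ = 3.98 mm
and length 175 mm, surrounding simulant conductivity interpolated over
the measured 0.1085–0.1112 S/m band, blood simulant 0.7283 S/m, nine
electrode-configuration codes on an 18 mm pitch (band tapes at 126 mm),
a single 647.83 mm³ withdrawal for the configuration-comparison group and
ten 80.98 mm³ constrictions for the error-growth group.  The lumped
branch capacitance is set so the phase at 1 MHz is ≈−5°, a small
capacitive phase consistent with a mostly resistive gel phantom (the
value is unpublished; configurable).  Instrument noise is multiplicative
on |Z| (0.3 % SD, scaled to typical measured scatter) and additive on
phase (0.1°), with seeded determinism end to end.

Two forward modes encode two physical hypotheses.  In `nyboer` mode the
withdrawn volume removes only blood conductance, so the pipeline is the
exact inverse of the generator — machine-precision recovery is a test,
not a success metric.  In `area_conserving` mode the withdrawn blood is
replaced by surrounding material (conductance σ_st·|dA| added back),
which makes the standard estimator under-read |ΔA| by the factor
(σ_b−σ_st)/σ_b and produces convex percent-error growth with cumulative
volume — the mechanism behind the under-estimation observed with real
gel phantoms.  What passing tests on this generator do **not** show:
robustness to electrode polarisation, temperature/moisture drift of the
gel, RBC-orientation effects in real blood, or contact-impedance
variation; none of these are modelled.

## Problem sizes and numerical choices

Unit tests run the solver at a 2 mm grid (≈19k unknowns); the acceptance
tests and production analyses use the full 1 mm grid (150k unknowns,
~2 s per real solve, ~5 s complex).  Monte-Carlo noise calibration uses
1000 seeds.  Tie-breaks and degenerate inputs: duplicate sweep
frequencies are rejected; mismatched frequency grids raise; zero
withdrawn volume returns the basal state exactly; SD over a single valid
frequency is reported as 0.

## Known limitations

Lumped tables ignore Cole–Cole dispersion shape between grid points
(log-linear interpolation only); the bone block is a rectangle, not a
radius/ulna pair; electrode–skin polarisation is not modelled anywhere;
the field solver's voxel grid cannot represent curved electrode hardware;
and absolute in-vivo diameters would require an external calibration
(e.g. ultrasound) that is out of scope.
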