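"""Synthetic phantom-pumping experiments with known ground truth.

Emulates the gelatine wrist-phantom experiments: a 50 mm x 30 mm cuboid
of surrounding-tissue simulant with one straight blood-filled artery
(d0 = 3.98 mm, 175 mm long), six electrodes at 18 mm pitch, a desktop pump
withdrawing blood simulant in steps, and an impedance analyser sweeping
ten log-spaced frequencies from 1 kHz to 1 MHz.

Two forward modes are provided:

* ``"nyboer"`` - the withdrawn volume only removes blood conductance
  (1/Rt = 1/R0 + sigma_b * dA / L_PU with dA = -dV/L_artery).  The
  estimation pipeline is the exact algebraic inverse of this generator.
* ``"area_conserving"`` - the withdrawn blood is replaced by
  surrounding-tissue material, so the lost conductance is only
  (sigma_b - sigma_st) * |dA| / L_PU.  Running the standard estimator
  (which assumes pure blood loss) on such data under-estimates |dA|,
  reproducing the systematic error mechanism seen in real phantom runs.

Instrument noise is multiplicative on |Z| and additive on the phase, with
seeded determinism.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .circuit import ImpedanceSweep, ParallelRC, cartesian_to_polar, rc_to_impedance
from .diameter import PumpExperiment, reference_diameter
from .dielectrics import MFIA_FREQUENCIES_HZ
from .errors import ConfigurationError

#: Electrode-configuration codes -> (L_CC, L_PU) in metres.  Spot codes use
#: the 18 mm pitch between numbered electrodes 1-6; "B" is the band method
#: whose copper tapes sit beyond the outermost spots.
ELECTRODE_CODES: dict[str, tuple[float, float]] = {
    "90/18": (0.090, 0.018),
    "90/36": (0.090, 0.036),
    "90/54": (0.090, 0.054),
    "72/18": (0.072, 0.018),
    "72/36": (0.072, 0.036),
    "54/18": (0.054, 0.018),
    "B/90": (0.126, 0.090),
    "B/54": (0.126, 0.054),
    "B/18": (0.126, 0.018),
}

#: Pump protocol volumes (m^3): one large Group-A withdrawal; ten equal
#: Group-B constrictions.
GROUP_A_VOLUME_M3 = 647.83e-9
GROUP_B_STEP_VOLUME_M3 = 80.98e-9
GROUP_B_N_STEPS = 10


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and material parameters of the synthetic wrist phantom."""

    width: float = 0.050               # m
    height: float = 0.030              # m
    artery_diameter: float = 0.00398   # m, cast by the metal rod
    artery_length: float = 0.175       # m
    blood_sigma: float = 0.7283        # S/m, mean 0.08 M NaCl conductivity
    surrounding_sigma_lo: float = 0.1085  # S/m at 1 kHz
    surrounding_sigma_hi: float = 0.1112  # S/m at 1 MHz
    electrode_pitch: float = 0.018     # m, spots numbered 1..6
    phase_at_1mhz_deg: float = -5.0    # sets the lumped branch capacitance

    def __post_init__(self):
        if min(self.width, self.height, self.artery_diameter,
               self.artery_length, self.blood_sigma) <= 0:
            raise ConfigurationError("phantom dimensions must be positive")

    @property
    def basal_area(self) -> float:
        return math.pi * self.artery_diameter ** 2 / 4.0

    @property
    def surrounding_area(self) -> float:
        return self.width * self.height - self.basal_area

    def surrounding_sigma(self, f) -> np.ndarray:
        """sigma_st(f): log-frequency interpolation across the printed band."""
        f = np.asarray(f, dtype=float)
        t = (np.log10(f) - 3.0) / 3.0  # 0 at 1 kHz, 1 at 1 MHz
        if np.any(t < -1e-9) or np.any(t > 1 + 1e-9):
            raise ConfigurationError("frequency outside 1 kHz - 1 MHz")
        out = self.surrounding_sigma_lo + t * (
            self.surrounding_sigma_hi - self.surrounding_sigma_lo)
        return out if out.ndim else float(out)

    def branch_capacitance(self, r0: float) -> float:
        """Lumped Cs giving the configured phase at 1 MHz for resistance r0."""
        return math.tan(math.radians(abs(self.phase_at_1mhz_deg))) / (
            2 * math.pi * 1e6 * r0)

    def pump_experiment(self, steps) -> PumpExperiment:
        return PumpExperiment(d0=self.artery_diameter,
                              artery_length=self.artery_length,
                              steps=tuple(steps))


@dataclass(frozen=True)
class NoiseModel:
    """MFIA-style instrument noise: relative on |Z|, additive on phase."""

    magnitude_rel_sd: float = 0.003
    phase_sd_deg: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.magnitude_rel_sd < 0 or self.phase_sd_deg < 0:
            raise ConfigurationError("noise SDs must be non-negative")


#: Convenience noise-free model.
NO_NOISE = NoiseModel(magnitude_rel_sd=0.0, phase_sd_deg=0.0, seed=0)


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------
def forward_phantom_resistance(spec: PhantomSpec, code: str, dv: float,
                               f: float, mode: str = "nyboer") -> float:
    """Phantom resistance (ohm) at one frequency after withdrawing dv (m^3).

    ``dv`` is the cumulative withdrawn blood-simulant volume; ``code`` is a
    Table-style electrode configuration code selecting L_PU.
    """
    if code not in ELECTRODE_CODES:
        raise ConfigurationError(
            f"unknown electrode code {code!r}; expected one of "
            f"{sorted(ELECTRODE_CODES)}")
    if dv < 0 or dv >= spec.basal_area * spec.artery_length:
        raise ConfigurationError("withdrawn volume out of bounds")
    _, l_pu = ELECTRODE_CODES[code]
    sig_st = spec.surrounding_sigma(f)
    g0 = (sig_st * spec.surrounding_area + spec.blood_sigma * spec.basal_area) / l_pu
    if dv == 0.0:
        return 1.0 / g0
    da = dv / spec.artery_length  # |dA|, positive
    if mode == "nyboer":
        g = g0 - spec.blood_sigma * da / l_pu
    elif mode == "area_conserving":
        g = g0 - (spec.blood_sigma - sig_st) * da / l_pu
    else:
        raise ConfigurationError(f"unknown forward mode {mode!r}")
    return 1.0 / g


# ---------------------------------------------------------------------------
# Sweep generation
# ---------------------------------------------------------------------------
def generate_mfia_sweep(r, c: float, grid=None, noise: NoiseModel = NO_NOISE
                        ) -> ImpedanceSweep:
    """Generate a polar-form MFIA sweep for a parallel-RC branch.

    ``r`` may be a scalar or a per-frequency array aligned with ``grid``.
    Noise is applied in polar form (relative on |Z|, additive degrees on
    phase); two calls with equal seeds are identical.
    """
    grid = MFIA_FREQUENCIES_HZ if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ConfigurationError("frequency grid must be non-empty")
    r = np.broadcast_to(np.asarray(r, dtype=float), grid.shape)
    rng = np.random.default_rng(noise.seed)
    mags, phases = [], []
    for fi, ri in zip(grid, r):
        s = rc_to_impedance(ParallelRC(rs=float(ri), cs=c), float(fi))
        mag, ph = cartesian_to_polar(s.re, s.im)
        mags.append(mag)
        phases.append(ph)
    mags = np.array(mags) * (1.0 + noise.magnitude_rel_sd * rng.standard_normal(grid.size))
    phases = np.array(phases) + noise.phase_sd_deg * rng.standard_normal(grid.size)
    return ImpedanceSweep.from_polar(grid, mags, phases)


@dataclass(frozen=True)
class GroupBundle:
    """Everything a pump-protocol analysis consumes, plus ground truth."""

    group: str
    code: str
    spec: PhantomSpec
    experiment: PumpExperiment
    basal_sweep: ImpedanceSweep
    step_sweeps: tuple[ImpedanceSweep, ...]
    manifest: pd.DataFrame  # step, dv_mm3, d_true_mm

    @property
    def l_pu(self) -> float:
        return ELECTRODE_CODES[self.code][1]


def _protocol_sweeps(spec: PhantomSpec, code: str, volumes, mode: str,
                     noise: NoiseModel, grid) -> tuple[ImpedanceSweep, list]:
    grid = MFIA_FREQUENCIES_HZ if grid is None else np.asarray(grid, dtype=float)
    r0 = np.array([forward_phantom_resistance(spec, code, 0.0, f, mode) for f in grid])
    c = spec.branch_capacitance(float(r0[-1]))
    basal = generate_mfia_sweep(r0, c, grid, replace(noise, seed=noise.seed))
    steps = []
    for k, dv in enumerate(volumes, start=1):
        rk = np.array([forward_phantom_resistance(spec, code, dv, f, mode) for f in grid])
        steps.append(generate_mfia_sweep(rk, c, grid, replace(noise, seed=noise.seed + k)))
    return basal, steps


def generate_group_experiment(spec: PhantomSpec | None = None, group: str = "B",
                              noise: NoiseModel = NO_NOISE, mode: str = "nyboer",
                              grid=None) -> GroupBundle | list[GroupBundle]:
    """Generate a full pump-protocol bundle with its ground-truth manifest.

    Group B returns a single bundle (code B/18, ten equal constrictions);
    Group A returns one bundle per Table-style electrode code, each with a
    single large withdrawal.  The manifest diameters follow the pump
    reference formulas exactly.
    """
    spec = spec or PhantomSpec()
    if group == "B":
        volumes = tuple(GROUP_B_STEP_VOLUME_M3 * k for k in range(1, GROUP_B_N_STEPS + 1))
        return _bundle(spec, "B", "B/18", volumes, mode, noise, grid)
    if group == "A":
        volumes = (GROUP_A_VOLUME_M3,)
        return [
            _bundle(spec, "A", code, volumes, mode,
                    replace(noise, seed=noise.seed + 1000 * i), grid)
            for i, code in enumerate(ELECTRODE_CODES)
        ]
    raise ConfigurationError(f"unknown group {group!r}; expected 'A' or 'B'")


def _bundle(spec, group, code, volumes, mode, noise, grid) -> GroupBundle:
    exp = spec.pump_experiment(volumes)
    basal, steps = _protocol_sweeps(spec, code, volumes, mode, noise, grid)
    manifest = pd.DataFrame({
        "step": np.arange(1, len(volumes) + 1),
        "dv_mm3": np.array(volumes) * 1e9,
        "d_true_mm": [reference_diameter(exp, dv) * 1e3 for dv in volumes],
    })
    return GroupBundle(group=group, code=code, spec=spec, experiment=exp,
                       basal_sweep=basal, step_sweeps=tuple(steps),
                       manifest=manifest)
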