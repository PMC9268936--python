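"""Frequency-dependent tissue electrical properties and parallel-tissue algebra.

The wrist segment between the pick-up electrodes is modelled as tissue
prisms connected electrically in parallel: each tissue contributes a
conductance ``sigma_i(f) * A_i / L_PU``, so the overall resistance is

    R_overall(f) = L_PU / sum_i sigma_i(f) * A_i

Default per-tissue conductivity/permittivity tables are literature-style
beta-dispersion curves tabulated on the eleven simulation frequencies
(1 kHz, 100 kHz ... 1 MHz) and interpolated linearly in log-frequency.
They are anchored to two printed values (dry skin at 1 kHz, the whole-band
blood conductivity range) and are fully overridable from CSV.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FrequencyRangeError
from .geometry import STAGES, WristGeometry

EPS0 = 8.8541878128e-12  # F/m

#: Discrete frequencies used in the electrode-configuration simulations.
SIMULATION_FREQUENCIES_HZ = np.array(
    [1e3, 1e5, 2e5, 3e5, 4e5, 5e5, 6e5, 7e5, 8e5, 9e5, 1e6]
)

#: Ten log-spaced MFIA sweep frequencies, 1 kHz .. 1 MHz.
MFIA_FREQUENCIES_HZ = np.logspace(3.0, 6.0, 10)


@dataclass(frozen=True)
class DielectricTable:
    """Conductivity and relative permittivity of one tissue vs frequency."""

    tissue: str
    frequencies: np.ndarray  # Hz, strictly increasing
    sigma: np.ndarray        # S/m
    eps_r: np.ndarray        # dimensionless

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        e = np.asarray(self.eps_r, dtype=float)
        if not (len(f) == len(s) == len(e)) or len(f) < 2:
            raise ConfigurationError("table arrays must share length >= 2")
        if np.any(np.diff(f) <= 0):
            raise ConfigurationError("frequencies must be strictly increasing")
        if np.any(s < 1e-6):
            raise ConfigurationError("conductivity below 1e-6 S/m is non-physical here")
        if np.any(e < 1.0):
            raise ConfigurationError("relative permittivity must be >= 1")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "sigma", s)
        object.__setattr__(self, "eps_r", e)

    def _interp(self, values: np.ndarray, f) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        lo, hi = self.frequencies[0], self.frequencies[-1]
        if np.any(f < lo) or np.any(f > hi):
            raise FrequencyRangeError(
                f"{self.tissue}: frequency outside tabulated grid "
                f"[{lo:g}, {hi:g}] Hz"
            )
        out = np.interp(np.log10(f), np.log10(self.frequencies), values)
        return out if out.ndim else float(out)

    def conductivity(self, f):
        """sigma(f) in S/m; log-frequency linear interpolation."""
        return self._interp(self.sigma, f)

    def permittivity(self, f):
        """Relative permittivity eps_r(f)."""
        return self._interp(self.eps_r, f)

    def admittivity(self, f):
        """Complex admittivity kappa = sigma + j*2*pi*f*eps0*eps_r (S/m)."""
        f = np.asarray(f, dtype=float)
        return self.conductivity(f) + 1j * 2 * np.pi * f * EPS0 * self.permittivity(f)


@dataclass(frozen=True)
class TissueCrossSection:
    """A labelled tissue prism: name and cross-sectional area (m^2)."""

    tissue: str
    area: float

    def __post_init__(self):
        if self.area <= 0:
            raise ConfigurationError(f"{self.tissue}: area must be positive")


_REQUIRED = {
    "model1": {"fat", "muscle", "blood"},
    "model2": {"fat", "muscle", "blood", "skin"},
    "model3": {"fat", "muscle", "blood", "skin", "cortical", "cancellous"},
}


@dataclass(frozen=True)
class WristComposition:
    """A stage's set of tissue cross-sections."""

    sections: tuple[TissueCrossSection, ...]
    stage: str

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ConfigurationError(f"unknown stage {self.stage!r}")
        names = {s.tissue for s in self.sections}
        missing = _REQUIRED[self.stage] - names
        if missing:
            raise ConfigurationError(
                f"{self.stage} composition missing tissues: {sorted(missing)}"
            )

    @property
    def total_area(self) -> float:
        return sum(s.area for s in self.sections)

    def without(self, tissue: str) -> "WristComposition":
        """Composition with one tissue removed (stage check bypassed)."""
        kept = tuple(s for s in self.sections if s.tissue != tissue)
        obj = object.__new__(WristComposition)
        object.__setattr__(obj, "sections", kept)
        object.__setattr__(obj, "stage", self.stage)
        return obj


# ---------------------------------------------------------------------------
# Default tables
# ---------------------------------------------------------------------------
_F = SIMULATION_FREQUENCIES_HZ

_DEFAULTS = {
    # Dry skin: printed 1 kHz anchor; rises steeply through the band so it
    # overtakes fat near 50 kHz and cancellous bone near 200 kHz.
    "skin": (
        [0.00065738, 0.045, 0.090, 0.120, 0.150, 0.170, 0.190, 0.210, 0.230, 0.250, 0.270],
        [1140, 1120, 1000, 920, 860, 820, 790, 770, 750, 735, 720],
    ),
    "fat": (
        [0.0235, 0.0243, 0.0245, 0.0247, 0.0248, 0.0249, 0.0250, 0.0251, 0.0252, 0.0253, 0.0255],
        [1910, 101, 60, 46, 39, 35, 31, 29, 27, 26, 25],
    ),
    "muscle": (
        [0.321, 0.362, 0.382, 0.396, 0.408, 0.419, 0.430, 0.441, 0.452, 0.464, 0.503],
        [435000, 8089, 5100, 4000, 3400, 3000, 2700, 2500, 2300, 2100, 1836],
    ),
    # Whole blood: inside the printed 0.70-0.82 S/m band across 1 kHz-1 MHz.
    "blood": (
        [0.700, 0.732, 0.748, 0.760, 0.770, 0.779, 0.787, 0.795, 0.803, 0.811, 0.820],
        [5258, 5120, 4800, 4500, 4200, 3900, 3700, 3500, 3300, 3150, 3026],
    ),
    "cortical": (
        [0.0202, 0.0208, 0.0211, 0.0214, 0.0216, 0.0218, 0.0220, 0.0222, 0.0224, 0.0226, 0.0244],
        [2702, 228, 180, 160, 150, 145, 140, 135, 130, 127, 124],
    ),
    "cancellous": (
        [0.0804, 0.0839, 0.0848, 0.0855, 0.0860, 0.0865, 0.0870, 0.0875, 0.0880, 0.0885, 0.0902],
        [11700, 472, 380, 330, 300, 280, 265, 250, 240, 230, 220],
    ),
}


def default_tables() -> dict[str, DielectricTable]:
    """Default per-tissue dielectric tables on the 11 simulation frequencies."""
    return {
        name: DielectricTable(name, _F.copy(), np.array(s), np.array(e))
        for name, (s, e) in _DEFAULTS.items()
    }


def default_composition(stage: str, geometry: WristGeometry | None = None) -> WristComposition:
    """Per-tissue areas of the default cuboid geometry for a given stage."""
    geo = geometry or WristGeometry()
    areas = geo.section_areas(stage)
    sections = tuple(TissueCrossSection(t, a) for t, a in areas.items())
    return WristComposition(sections=sections, stage=stage)


# ---------------------------------------------------------------------------
# Parallel-tissue algebra
# ---------------------------------------------------------------------------
def tissue_resistance(section: TissueCrossSection, table: DielectricTable,
                      f: float, length: float) -> float:
    """Resistance of one tissue prism: length / (sigma(f) * area)."""
    if length <= 0:
        raise ConfigurationError("length must be positive")
    return length / (table.conductivity(f) * section.area)


def overall_resistance(comp: WristComposition, tables: dict[str, DielectricTable],
                       f: float, l_pu: float) -> float:
    """Parallel combination of all tissue prisms over a PU spacing l_pu."""
    if l_pu <= 0:
        raise ConfigurationError("l_pu must be positive")
    g = 0.0
    for s in comp.sections:
        if s.tissue not in tables:
            raise ConfigurationError(f"no dielectric table for tissue {s.tissue!r}")
        g += tables[s.tissue].conductivity(f) * s.area
    return l_pu / g


def mixture_conductivity(comp: WristComposition, tables: dict[str, DielectricTable],
                         f: float) -> float:
    """Area-weighted conductivity sum(sigma_i A_i) / sum(A_i)."""
    if not comp.sections:
        raise ConfigurationError("empty composition")
    num = 0.0
    den = 0.0
    for s in comp.sections:
        if s.tissue not in tables:
            raise ConfigurationError(f"no dielectric table for tissue {s.tissue!r}")
        num += tables[s.tissue].conductivity(f) * s.area
        den += s.area
    return num / den


def surrounding_conductivity(comp: WristComposition, tables: dict[str, DielectricTable],
                             f: float) -> float:
    """Mixture conductivity of everything except blood (the sigma_st of the
    phantom design)."""
    return mixture_conductivity(comp.without("blood"), tables, f)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------
_CSV_COLS = ["tissue", "frequency_hz", "sigma_s_per_m", "eps_r"]


def read_dielectric_csv(path) -> dict[str, DielectricTable]:
    """Read per-tissue tables from a long-format CSV."""
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"dielectric CSV missing columns {missing}")
    out = {}
    for tissue, grp in df.groupby("tissue", sort=False):
        grp = grp.sort_values("frequency_hz")
        out[str(tissue)] = DielectricTable(
            str(tissue),
            grp["frequency_hz"].to_numpy(float),
            grp["sigma_s_per_m"].to_numpy(float),
            grp["eps_r"].to_numpy(float),
        )
    return out


def write_dielectric_csv(tables: dict[str, DielectricTable], path) -> None:
    rows = []
    for t in tables.values():
        for f, s, e in zip(t.frequencies, t.sigma, t.eps_r):
            rows.append((t.tissue, f, s, e))
    pd.DataFrame(rows, columns=_CSV_COLS).to_csv(path, index=False)
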