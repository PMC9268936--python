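"""Four-electrode liquid conductivity cell reduction.

Two outer plates drive a uniform current through a cuboid sample; two pin
electrodes at spacing ``l`` pick up the potential drop.  With plate area
``S`` the sample conductivity is ``sigma = l / (R * S)``.  Measurements
are repeated over a grid of pin spacings and pooled as mean +/- unbiased
(n-1) standard deviation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import ImpedanceSweep, impedance_to_rc
from .errors import ConfigurationError

#: Default pin spacing grid, 5 mm .. 40 mm in 5 mm steps.
DEFAULT_SPACINGS_M = tuple(np.arange(5, 45, 5) * 1e-3)

#: Default copper plate area (m^2).
DEFAULT_PLATE_AREA_M2 = 1000e-6


@dataclass(frozen=True)
class CellMeasurement:
    """One resistance reading at a given pin spacing."""

    pin_spacing: float            # m
    resistance: float             # ohm (parallel-RC Rs at one frequency)
    plate_area: float = DEFAULT_PLATE_AREA_M2  # m^2

    def __post_init__(self):
        if self.pin_spacing <= 0 or self.plate_area <= 0:
            raise ConfigurationError("spacing and plate area must be positive")
        if self.resistance <= 0:
            raise ConfigurationError("resistance must be positive")


def sample_conductivity(m: CellMeasurement) -> float:
    """Conductivity l / (R * S) of one measurement, in S/m."""
    return m.pin_spacing / (m.resistance * m.plate_area)


def mean_sd_conductivity(ms: list[CellMeasurement]) -> tuple[float, float]:
    """Arithmetic mean and unbiased (n-1) SD over repeated measurements."""
    if len(ms) < 2:
        raise ConfigurationError("SD needs at least two measurements")
    vals = np.array([sample_conductivity(m) for m in ms])
    return float(vals.mean()), float(vals.std(ddof=1))


def measurements_from_sweep(sweep: ImpedanceSweep, pin_spacing: float,
                            plate_area: float = DEFAULT_PLATE_AREA_M2
                            ) -> list[CellMeasurement]:
    """Per-frequency cell measurements from an MFIA sweep (RC inversion)."""
    return [
        CellMeasurement(pin_spacing=pin_spacing,
                        resistance=impedance_to_rc(s).rs,
                        plate_area=plate_area)
        for s in sweep
    ]


def check_row_uniformity(row_conductivities: dict[str, float],
                         rel_tol: float = 0.05) -> bool:
    """Field-uniformity pre-check before pooling grid-board rows.

    Per-row conductivities at equal pin spacing must agree with their mean
    within ``rel_tol`` relative; raises otherwise.
    """
    vals = np.array(list(row_conductivities.values()), dtype=float)
    if vals.size < 2:
        raise ConfigurationError("need at least two rows to compare")
    mean = vals.mean()
    worst = np.abs(vals - mean).max() / mean
    if worst > rel_tol:
        bad = max(row_conductivities, key=lambda k: abs(row_conductivities[k] - mean))
        raise ConfigurationError(
            f"row {bad!r} deviates {worst:.1%} from the mean (> {rel_tol:.0%}); "
            "field not uniform enough to pool"
        )
    return True


def linear_fit(x, y) -> tuple[float, float, float]:
    """Generic least-squares line fit: (slope, intercept, r_squared).

    Used e.g. to map NaCl concentration to conductivity when choosing a
    blood-simulant molarity.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ConfigurationError("need at least two points")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2
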