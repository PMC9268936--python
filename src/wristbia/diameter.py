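"""Nyboer pulsatile inversion and arterial diameter estimation.

The measured segment is modelled as a basal branch (resistance R0, all
static tissue plus perfused blood) in parallel with a pulsatile blood
branch Rp.  A change in blood cross-sectional area dA maps to a change in
measured resistance via

    dA = -L_PU * (R(t) - R0) / (sigma_b * R0 * R(t))

which is the exact algebraic inverse of the parallel forward model.  The
absolute cross-sectional area after a pump step is then

    A_hat = A0 + L_PU * (R0 - Rt) / (sigma_b * R0 * Rt),      d = 2*sqrt(A/pi)

aggregated as mean +/- sample SD over the sweep frequencies.  Pump-side
reference values come from the withdrawn volume:

    dA_ref = dV / L_artery,    d_ref = 2*sqrt((pi d0^2/4 - dV/L_artery)/pi)

and accuracy is reported as percent error |d_ref - d_hat|/d_ref * 100.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit import ImpedanceSweep, impedance_to_rc
from .errors import (
    ConfigurationError,
    EstimationError,
    GridMismatchError,
    ProtocolError,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class PulsatileDecomposition:
    """Basal / pulsatile split of a measured resistance pair.

    ``rp`` is None when the measurement did not change (open pulsatile
    branch); it is never a float infinity.
    """

    r0: float
    rt: float

    def __post_init__(self):
        if self.r0 <= 0 or self.rt <= 0:
            raise ConfigurationError("resistances must be positive")

    @property
    def dr(self) -> float:
        return self.rt - self.r0

    @property
    def rp(self) -> float | None:
        """Pulsatile branch resistance; None when dr == 0 (open branch)."""
        if self.dr == 0.0:
            return None
        return -self.r0 * self.rt / self.dr

    @property
    def is_open(self) -> bool:
        return self.dr == 0.0


@dataclass(frozen=True)
class PumpExperiment:
    """A stepwise blood-volume withdrawal protocol.

    ``steps`` are cumulative withdrawn volumes (m^3), strictly increasing.
    Optional syringe geometry must be consistent with the volumes
    (dV = pi d_syringe^2 / 4 * dL per step).
    """

    d0: float                    # m, initial artery diameter
    artery_length: float         # m
    steps: tuple[float, ...]     # m^3, cumulative withdrawn volumes
    syringe_inner_diameter: float | None = None
    plunger_displacements: tuple[float, ...] | None = None  # m, cumulative

    def __post_init__(self):
        if self.d0 <= 0 or self.artery_length <= 0:
            raise ConfigurationError("d0 and artery_length must be positive")
        steps = tuple(float(v) for v in self.steps)
        object.__setattr__(self, "steps", steps)
        if steps and (steps[0] <= 0 or np.any(np.diff(steps) <= 0)):
            raise ConfigurationError("cumulative volumes must be strictly increasing")
        if steps and steps[-1] >= self.basal_area * self.artery_length:
            raise ConfigurationError("withdrawn volume exceeds the artery volume")
        if self.syringe_inner_diameter is not None and self.plunger_displacements is not None:
            a = math.pi * self.syringe_inner_diameter ** 2 / 4.0
            for dv, dl in zip(steps, self.plunger_displacements):
                if abs(dv - a * dl) > 1e-9 * max(dv, 1e-300):
                    raise ConfigurationError(
                        "plunger displacements inconsistent with withdrawn volumes"
                    )

    @property
    def basal_area(self) -> float:
        return math.pi * self.d0 ** 2 / 4.0


@dataclass(frozen=True)
class DiameterEstimate:
    """Per-frequency diameters with their mean +/- SD aggregate."""

    frequencies: np.ndarray      # Hz
    diameters: np.ndarray        # m; NaN where the frequency was excluded
    mean: float                  # m
    sd: float                    # m
    excluded: tuple[float, ...] = ()  # frequencies dropped (A_hat < 0)
    percent_error: float | None = None


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------
def area_change_from_resistance(r0: float, rt: float, l_pu: float,
                                sigma_b: float) -> float:
    """Blood cross-sectional area change from a resistance pair.

    Negative for a contraction (rt > r0).
    """
    if r0 <= 0 or rt <= 0:
        raise ConfigurationError("resistances must be positive")
    if sigma_b <= 0 or l_pu <= 0:
        raise ConfigurationError("sigma_b and l_pu must be positive")
    return -l_pu * (rt - r0) / (sigma_b * r0 * rt)


def diameter_from_area(a: float) -> float:
    """Circle-equivalent diameter 2*sqrt(A/pi)."""
    if a < 0:
        raise EstimationError(f"negative cross-sectional area {a:g} m^2")
    return 2.0 * math.sqrt(a / math.pi)


def reference_area_change(dv: float, artery_length: float) -> float:
    """Reference area change dV / L_artery from the withdrawn volume."""
    if artery_length <= 0:
        raise ConfigurationError("artery_length must be positive")
    return dv / artery_length


def reference_diameter(exp: PumpExperiment, dv: float) -> float:
    """Reference absolute diameter after withdrawing a cumulative volume dv."""
    a = exp.basal_area - reference_area_change(dv, exp.artery_length)
    if a < 0:
        raise ConfigurationError(
            f"withdrawn volume {dv:g} m^3 exceeds the artery volume"
        )
    return diameter_from_area(a)


def percent_error(reference: float, estimate: float) -> float:
    """|reference - estimate| / reference * 100."""
    if reference <= 0:
        raise ConfigurationError("reference must be positive")
    return abs(reference - estimate) / reference * 100.0


def estimate_diameter(sweep0: ImpedanceSweep, sweep_t: ImpedanceSweep,
                      l_pu: float, sigma_b, a0: float,
                      reference: float | None = None) -> DiameterEstimate:
    """Estimate the arterial diameter from a basal and a post-step sweep.

    Parameters
    ----------
    sweep0, sweep_t
        Basal and post-pump sweeps on the same frequency grid.
    l_pu
        Pick-up electrode spacing (m).
    sigma_b
        Blood conductivity: a scalar (frequency-independent mean) or an
        array aligned with the sweep grid for per-frequency mode.
    a0
        Basal arterial cross-sectional area (m^2).
    reference
        Optional reference diameter (m) for percent-error reporting.
    """
    if a0 <= 0:
        raise ConfigurationError("a0 must be positive")
    f0 = sweep0.frequencies
    ft = sweep_t.frequencies
    if len(f0) != len(ft) or not np.allclose(f0, ft, rtol=1e-9, atol=0.0):
        raise GridMismatchError("sweeps do not share a frequency grid")

    sig = np.broadcast_to(np.asarray(sigma_b, dtype=float), f0.shape)
    if np.any(sig <= 0):
        raise ConfigurationError("sigma_b must be positive")

    r0 = sweep0.resistances()
    rt = sweep_t.resistances()
    a_hat = a0 + l_pu * (r0 - rt) / (sig * r0 * rt)

    diam = np.full_like(a_hat, np.nan)
    valid = a_hat >= 0
    diam[valid] = 2.0 * np.sqrt(a_hat[valid] / math.pi)
    excluded = tuple(f0[~valid])
    for f in excluded:
        log.warning("negative estimated area at f=%g Hz: frequency excluded", f)
    if not valid.any():
        raise EstimationError("estimated area negative at every frequency")

    vals = diam[valid]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    pe = percent_error(reference, mean) if reference is not None else None
    return DiameterEstimate(
        frequencies=f0, diameters=diam, mean=mean, sd=sd,
        excluded=excluded, percent_error=pe,
    )


# ---------------------------------------------------------------------------
# Whole-protocol runner
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class TrendFit:
    """Ordinary least-squares polynomial fit with its R^2."""

    coefficients: np.ndarray  # numpy.polyfit order (highest degree first)
    r_squared: float

    def __call__(self, x):
        return np.polyval(self.coefficients, x)


@dataclass(frozen=True)
class GroupRunResult:
    """Full result structure of a pump experiment run."""

    table: pd.DataFrame           # one row per step
    per_frequency: pd.DataFrame   # long form, one row per (step, frequency)
    pe_fit_linear: TrendFit       # PE vs cumulative withdrawn volume (mm^3)
    pe_fit_quadratic: TrendFit


def _ols_fit(x: np.ndarray, y: np.ndarray, deg: int) -> TrendFit:
    coeff = np.polyfit(x, y, deg)
    resid = y - np.polyval(coeff, x)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return TrendFit(coefficients=coeff, r_squared=r2)


def run_group_experiment(experiment: PumpExperiment,
                         basal_sweep: ImpedanceSweep,
                         step_sweeps: list[ImpedanceSweep],
                         l_pu: float, sigma_b,
                         a0: float | None = None) -> GroupRunResult:
    """Run a full pump protocol: per-step diameters, errors and trend fits.

    Emits one table row per step (cumulative volume, reference and
    estimated diameters, SD, percent error, mean basal/step resistance)
    plus a per-frequency detail table, and OLS linear/quadratic fits of
    percent error vs cumulative withdrawn volume.
    """
    if len(step_sweeps) != len(experiment.steps):
        raise ProtocolError(
            f"protocol has {len(experiment.steps)} steps but "
            f"{len(step_sweeps)} sweeps were supplied"
        )
    if a0 is None:
        a0 = experiment.basal_area

    rows = []
    detail = []
    r0 = basal_sweep.resistances()
    f = basal_sweep.frequencies
    for k, (dv, sweep) in enumerate(zip(experiment.steps, step_sweeps), start=1):
        d_ref = reference_diameter(experiment, dv)
        est = estimate_diameter(basal_sweep, sweep, l_pu, sigma_b, a0,
                                reference=d_ref)
        rt = sweep.resistances()
        rows.append({
            "step": k,
            "dv_mm3": dv * 1e9,
            "d_ref_mm": d_ref * 1e3,
            "d_est_mm": est.mean * 1e3,
            "d_sd_mm": est.sd * 1e3,
            "pe_percent": est.percent_error,
            "r0_mean_ohm": float(r0.mean()),
            "rt_mean_ohm": float(rt.mean()),
            "dr_mean_ohm": float((rt - r0).mean()),
            "da_est_mm2": (est.mean ** 2 * math.pi / 4.0 - a0) * 1e6,
            "da_ref_mm2": -reference_area_change(dv, experiment.artery_length) * 1e6,
            "n_excluded": len(est.excluded),
        })
        for fi, di, r0i, rti in zip(f, est.diameters, r0, rt):
            detail.append({
                "step": k, "frequency_hz": fi,
                "r0_ohm": r0i, "rt_ohm": rti,
                "d_est_mm": di * 1e3 if np.isfinite(di) else np.nan,
            })

    table = pd.DataFrame(rows)
    x = table["dv_mm3"].to_numpy()
    y = table["pe_percent"].to_numpy()
    return GroupRunResult(
        table=table,
        per_frequency=pd.DataFrame(detail),
        pe_fit_linear=_ols_fit(x, y, 1),
        pe_fit_quadratic=_ols_fit(x, y, 2),
    )
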