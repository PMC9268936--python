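"""Parallel-RC impedance algebra and polar/cartesian conversion.

Each tissue segment (and the whole measured phantom) is lumped as a
resistor Rs in parallel with a capacitor Cs.  The forward map and its
closed-form inverse are

    Re(Z) =  Rs / (1 + (2 pi f Rs Cs)^2)
    Im(Z) = -2 pi f Rs^2 Cs / (1 + (2 pi f Rs Cs)^2)

    Rs = (Re^2 + Im^2) / Re
    Cs = -Im / (2 pi f (Re^2 + Im^2))

Phase convention is instrument-style degrees, negative for capacitive
loads.  Samples with a positive imaginary part (inductive noise artifacts)
are not rejected: Cs clamps to zero with a logged warning so that noisy
sweeps never crash the pipeline.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, NonPhysicalSampleError

log = logging.getLogger(__name__)

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class ParallelRC:
    """A resistor Rs (ohm) in parallel with a capacitor Cs (farad)."""

    rs: float
    cs: float

    def __post_init__(self):
        if self.rs <= 0:
            raise ConfigurationError("rs must be positive")
        if self.cs < 0:
            raise ConfigurationError("cs must be non-negative")

    def impedance(self, f: float) -> complex:
        """Complex impedance 1 / (1/Rs + j 2 pi f Cs)."""
        return 1.0 / (1.0 / self.rs + 1j * _TWO_PI * f * self.cs)


@dataclass(frozen=True)
class ImpedanceSample:
    """One complex impedance measurement at frequency f.

    Cartesian parts are authoritative; polar fields, when present, must be
    consistent with them to 1e-9 relative.
    """

    f: float
    re: float
    im: float
    magnitude: float | None = None
    phase_deg: float | None = None

    def __post_init__(self):
        if self.f <= 0:
            raise ConfigurationError("frequency must be positive")
        if self.magnitude is not None and self.phase_deg is not None:
            re, im = polar_to_cartesian(self.magnitude, self.phase_deg)
            scale = max(abs(self.re), abs(self.im), 1e-300)
            if abs(re - self.re) > 1e-9 * scale or abs(im - self.im) > 1e-9 * scale:
                raise ConfigurationError(
                    f"polar and cartesian forms disagree at f={self.f:g} Hz"
                )

    @classmethod
    def from_polar(cls, f: float, magnitude: float, phase_deg: float) -> "ImpedanceSample":
        re, im = polar_to_cartesian(magnitude, phase_deg)
        return cls(f=f, re=re, im=im, magnitude=magnitude, phase_deg=phase_deg)

    @property
    def z(self) -> complex:
        return complex(self.re, self.im)


@dataclass(frozen=True)
class ImpedanceSweep:
    """An ordered multi-frequency set of impedance samples."""

    samples: tuple[ImpedanceSample, ...]

    def __post_init__(self):
        if not self.samples:
            raise ConfigurationError("sweep must be non-empty")
        object.__setattr__(self, "samples", tuple(self.samples))
        f = self.frequencies
        if np.any(np.diff(f) <= 0):
            raise ConfigurationError("sweep frequencies must be strictly increasing")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([s.f for s in self.samples])

    def resistances(self) -> np.ndarray:
        """Per-frequency parallel-RC resistance Rs via the closed-form inverse."""
        return np.array([impedance_to_rc(s).rs for s in self.samples])

    @classmethod
    def from_polar(cls, f, magnitude, phase_deg) -> "ImpedanceSweep":
        return cls(tuple(
            ImpedanceSample.from_polar(fi, mi, pi)
            for fi, mi, pi in zip(f, magnitude, phase_deg)
        ))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------
def rc_to_impedance(rc: ParallelRC, f: float) -> ImpedanceSample:
    """Forward parallel-RC impedance at frequency f (Hz)."""
    if f <= 0:
        raise ConfigurationError("frequency must be positive")
    w = _TWO_PI * f * rc.rs * rc.cs
    den = 1.0 + w * w
    re = rc.rs / den
    im = -_TWO_PI * f * rc.rs ** 2 * rc.cs / den
    return ImpedanceSample(f=f, re=re, im=im)


def impedance_to_rc(s: ImpedanceSample) -> ParallelRC:
    """Closed-form inversion of one sample to (Rs, Cs).

    Exact inverse of :func:`rc_to_impedance`.  Positive Im(Z) clamps Cs
    to zero (logged); Re(Z) <= 0 is rejected as non-passive.
    """
    if s.re <= 0:
        raise NonPhysicalSampleError(f"Re(Z) = {s.re:g} <= 0 at f={s.f:g} Hz")
    mag2 = s.re * s.re + s.im * s.im
    rs = mag2 / s.re
    if s.im > 0:
        log.warning("positive Im(Z)=%.6g at f=%g Hz: clamping Cs to 0", s.im, s.f)
        return ParallelRC(rs=rs, cs=0.0)
    cs = -s.im / (_TWO_PI * s.f * mag2)
    return ParallelRC(rs=rs, cs=cs)


def polar_to_cartesian(magnitude: float, phase_deg: float) -> tuple[float, float]:
    """(|Z|, theta in degrees) -> (Re, Im)."""
    if magnitude < 0:
        raise ConfigurationError("magnitude must be non-negative")
    th = math.radians(phase_deg)
    return magnitude * math.cos(th), magnitude * math.sin(th)


def cartesian_to_polar(re: float, im: float) -> tuple[float, float]:
    """(Re, Im) -> (|Z|, theta in degrees)."""
    return math.hypot(re, im), math.degrees(math.atan2(im, re))
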