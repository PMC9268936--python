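"""CSV readers/writers, run configuration and report output.

CSV dialect is comma-separated, dot-decimal, UTF-8, mandatory header,
units embedded in the column names (``abs_z_ohm``, ``phase_deg``, ...),
so files interchange bit-exactly regardless of locale.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .circuit import ImpedanceSample, ImpedanceSweep
from .errors import ConfigurationError, WristbiaError

log = logging.getLogger(__name__)

MFIA_COLUMNS = ["frequency_hz", "abs_z_ohm", "phase_deg"]
CARTESIAN_COLUMNS = ["frequency_hz", "re_ohm", "im_ohm"]


class ParseError(WristbiaError, ValueError):
    """A CSV row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


def _read_table(path, columns) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in columns:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            # +2: one for the header, one for 0-based indexing
            raise ParseError(f"{path}: malformed value in column {col!r}",
                             line=int(bad[0]) + 2)
    df = df.astype({c: float for c in columns}).sort_values(columns[0])
    if df[columns[0]].duplicated().any():
        f = df.loc[df[columns[0]].duplicated(), columns[0]].iloc[0]
        raise ConfigurationError(f"{path}: duplicate frequency {f:g} Hz")
    return df.reset_index(drop=True)


def read_mfia_csv(path) -> ImpedanceSweep:
    """Read an instrument-style polar sweep (frequency, |Z|, phase)."""
    df = _read_table(path, MFIA_COLUMNS)
    return ImpedanceSweep.from_polar(
        df["frequency_hz"].to_numpy(),
        df["abs_z_ohm"].to_numpy(),
        df["phase_deg"].to_numpy(),
    )


def read_cartesian_csv(path) -> ImpedanceSweep:
    """Read a cartesian sweep (frequency, Re, Im)."""
    df = _read_table(path, CARTESIAN_COLUMNS)
    return ImpedanceSweep(tuple(
        ImpedanceSample(f=f, re=re, im=im)
        for f, re, im in df.itertuples(index=False)
    ))


def write_sweep_csv(sweep: ImpedanceSweep, path, form: str = "polar") -> None:
    """Write a sweep in polar or cartesian form."""
    from .circuit import cartesian_to_polar

    rows = []
    for s in sweep:
        if form == "polar":
            mag, ph = (s.magnitude, s.phase_deg)
            if mag is None or ph is None:
                mag, ph = cartesian_to_polar(s.re, s.im)
            rows.append((s.f, mag, ph))
        elif form == "cartesian":
            rows.append((s.f, s.re, s.im))
        else:
            raise ConfigurationError(f"unknown form {form!r}")
    cols = MFIA_COLUMNS if form == "polar" else CARTESIAN_COLUMNS
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------
_SCHEMA: dict[str, dict[str, float]] = {
    "geometry": {
        "width_mm": 50.0, "height_mm": 30.0, "length_mm": 100.0,
        "skin_thickness_mm": 1.5, "fat_thickness_mm": 3.0,
        "artery_diameter_mm": 2.5, "artery_depth_mm": 3.0,
    },
    "estimator": {
        "sigma_b_s_per_m": 0.7283, "l_pu_mm": 18.0,
        "d0_mm": 3.98, "artery_length_mm": 175.0,
    },
    "solver": {
        "grid_mm": 1.0, "tolerance": 1e-8, "frequency_hz": 1e5,
    },
    "noise": {
        "magnitude_rel_sd": 0.003, "phase_sd_deg": 0.1,
    },
}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with SI accessors (mm keys converted)."""

    geometry: dict
    estimator: dict
    solver: dict
    noise: dict
    seed: int = 0
    tissue_tables: str | None = None  # optional CSV path

    def si(self, section: str, key: str) -> float:
        """Value of ``<key>`` from ``section``, converting *_mm keys to m."""
        d = getattr(self, section)
        if key.endswith("_mm"):
            return d[key] * 1e-3
        return d[key]


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown sections or keys are rejected with the offending name; missing
    keys fall back to documented defaults.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    known_top = set(_SCHEMA) | {"seed", "tissue_tables"}
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigurationError(
            f"{path}: unknown config section(s) {sorted(unknown)}; "
            f"expected {sorted(known_top)}")
    sections = {}
    for name, defaults in _SCHEMA.items():
        block = raw.get(name, {}) or {}
        bad = set(block) - set(defaults)
        if bad:
            raise ConfigurationError(
                f"{path}: unknown key(s) {sorted(bad)} in section {name!r}; "
                f"expected {sorted(defaults)}")
        merged = {**defaults, **block}
        for k, v in merged.items():
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise ConfigurationError(f"{path}: {name}.{k} must be a number")
            allow_zero = name == "noise"
            if v < 0 or (v == 0 and not allow_zero):
                raise ConfigurationError(f"{path}: {name}.{k} must be positive")
        sections[name] = merged
    tables = raw.get("tissue_tables")
    if tables is not None and not Path(tables).exists():
        raise ConfigurationError(f"{path}: tissue_tables file not found: {tables}")
    return RunConfig(seed=int(raw.get("seed", 0)), tissue_tables=tables, **sections)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------
def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable run description."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(outdir, results: pd.DataFrame, summary: dict,
                 name: str = "results") -> dict[str, Path]:
    """Write a result table plus a structured run summary.

    The summary records the inputs, seed, package version and a config
    hash so a run can be reproduced exactly from its report alone.
    Refuses empty results.
    """
    if results is None or len(results) == 0:
        raise ConfigurationError("refusing to write an empty result table")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{name}.csv"
    results.to_csv(csv_path, index=False)
    full = {
        "package": "wristbia",
        "version": __version__,
        "rows": int(len(results)),
        **summary,
    }
    full["config_hash"] = config_hash({k: v for k, v in full.items()
                                       if k != "config_hash"})
    json_path = outdir / f"{name}_run.json"
    json_path.write_text(json.dumps(full, indent=2, sort_keys=True, default=str))
    log.info("wrote %s (%d rows) and %s", csv_path, len(results), json_path)
    return {"csv": csv_path, "json": json_path}
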