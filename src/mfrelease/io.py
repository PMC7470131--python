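"""Curve CSV reading, fit-report assembly and serialization.

The curve format is a delimited text table with header columns ``time_h``
and ``release`` (plus an optional ``label`` column); units (percent or
fraction) are declared by the caller, percent values are converted to
fraction internally and reported back in the original units.

A :class:`FitReport` collects every classical fit over every stage window
plus the multifractal block, and serializes losslessly to JSON (parameters
round-trip exactly through ``repr``-precision floats) and to a flat CSV
mirroring the customary release-kinetics results table (rows = window,
columns = model, R^2, constants).
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .errors import DomainError, ParseError
from .kinetics import KineticFit, ReleaseCurve, StageWindow, fit_grid_frame
from .mf_release import MultifractalParams

__all__ = ["read_release_csv", "write_release_csv", "parse_window",
           "FitReport", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = 1


def read_release_csv(path, units: str = "percent", label: str | None = None) -> ReleaseCurve:
    """Read and validate a release curve from a CSV file.

    Raises :class:`ParseError` naming the offending row for a missing
    column, a non-numeric cell, or non-increasing (e.g. duplicated) times.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message is adequate
        raise ParseError(f"{path}: {exc}") from exc
    for col in ("time_h", "release"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    for col in ("time_h", "release"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ParseError(
                f"{path}: non-numeric {col!r} value {df[col].iloc[row]!r} in data row {row + 1}")
        if coerced.isna().any():
            row = int(np.nonzero(coerced.isna().to_numpy())[0][0])
            raise ParseError(f"{path}: empty {col!r} cell in data row {row + 1}")
        df[col] = coerced
    times = df["time_h"].to_numpy(float)
    steps = np.diff(times)
    if np.any(steps <= 0):
        row = int(np.nonzero(steps <= 0)[0][0]) + 1
        kind = "duplicated" if times[row] == times[row - 1] else "non-increasing"
        raise ParseError(f"{path}: {kind} timepoint t={times[row]:g} h in data row {row + 1}")
    if label is None:
        label = str(df["label"].iloc[0]) if "label" in df.columns else ""
    try:
        return ReleaseCurve(times=times, released=df["release"].to_numpy(float),
                            units=units, label=label)
    except DomainError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_release_csv(curve: ReleaseCurve, path) -> None:
    df = pd.DataFrame({"time_h": curve.times, "release": curve.released})
    if curve.label:
        df["label"] = curve.label
    df.to_csv(path, index=False)


_WINDOW_RE = re.compile(
    r"^(?P<a>\d+(?:\.\d+)?)(?P<ua>[shd]?)-(?P<b>\d+(?:\.\d+)?)(?P<ub>[shd]?)$")
_UNIT_H = {"s": 1.0 / 3600.0, "h": 1.0, "d": 24.0, "": None}


def parse_window(text: str, name: str = "") -> StageWindow:
    """Parse ``"1-8h"``, ``"1d-5d"``, ``"30s-8h"`` ... into hours.

    A unit suffix (s|h|d) applies to its own bound; a bound without a suffix
    inherits the other bound's unit (hours if neither has one).
    """
    m = _WINDOW_RE.match(text.strip())
    if not m:
        raise DomainError(f"bad window syntax {text!r} (expected e.g. '1-8h' or '1d-5d')")
    ua, ub = _UNIT_H[m.group("ua")], _UNIT_H[m.group("ub")]
    if ua is None and ub is None:
        ua = ub = 1.0
    elif ua is None:
        ua = ub
    elif ub is None:
        ub = ua
    return StageWindow(float(m.group("a")) * ua, float(m.group("b")) * ub, name or text)


@dataclass
class FitReport:
    """All fits of one curve: classical grid + multifractal block + metadata."""

    curve_label: str
    units: str
    grid: dict                      # window -> model -> KineticFit | {"error": ...}
    multifractal: list = field(default_factory=list)   # MultifractalParams or dicts
    metadata: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        def cell(c):
            return c.to_dict() if isinstance(c, KineticFit) else c
        mf = [m.to_dict() if isinstance(m, MultifractalParams) else m
              for m in self.multifractal]
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "curve_label": self.curve_label,
            "units": self.units,
            "fits": {w: {mid: cell(c) for mid, c in row.items()}
                     for w, row in self.grid.items()},
            "multifractal": mf,
            "metadata": self.metadata,
            "warnings": list(self.warnings),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> dict:
        """Re-read a report; parameter values reproduce exactly (JSON floats
        are written at repr precision)."""
        with open(path) as fh:
            return json.load(fh)

    def to_csv(self, path=None):
        df = fit_grid_frame(self.grid)
        if path is not None:
            df.to_csv(path, index=False)
        return df


def input_hash(path) -> str:
    """SHA-256 of an input file, recorded in report metadata."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def library_versions() -> dict:
    from importlib.metadata import version

    import scipy

    return {"mfrelease": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "click": version("click")}
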