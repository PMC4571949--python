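"""Spectrum container and two-column spectrum file IO.

A :class:`Spectrum` couples a strictly increasing wavelength grid (nm) with
unitless values — relative sensitivity, relative absorbance, or a
difference-absorbance (which may be negative).  All downstream fitting
stages operate on this container.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SpectrumKind",
    "Spectrum",
    "SpectrumValidationError",
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
    "resample",
    "default_grid",
]


class SpectrumValidationError(ValueError):
    """Raised when spectrum data violate the container invariants."""


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed."""


class SpectrumKind(str, enum.Enum):
    SENSITIVITY = "sensitivity"
    ABSORBANCE = "absorbance"
    DIFFERENCE = "difference"


@dataclass(frozen=True)
class Spectrum:
    """Wavelength/value pairs of one measured or modeled spectrum.

    Parameters
    ----------
    wavelengths : array of float
        Strictly increasing wavelengths in nm, all positive.
    values : array of float
        Unitless values, same length as ``wavelengths``.  Sensitivity and
        absorbance spectra must be finite and nonnegative; difference
        spectra may take either sign.
    kind : SpectrumKind
    label : str
        Free-text identifier (genotype, file stem, ...).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: SpectrumKind = SpectrumKind.ABSORBANCE
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "kind", SpectrumKind(self.kind))
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise SpectrumValidationError(
                "wavelengths and values must be 1-D arrays of equal length"
            )
        if wl.size < 2:
            raise SpectrumValidationError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(wl)) or np.any(wl <= 0):
            raise SpectrumValidationError("wavelengths must be finite and > 0")
        if np.any(np.diff(wl) <= 0):
            raise SpectrumValidationError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(vals)):
            raise SpectrumValidationError("values must be finite")
        if self.kind in (SpectrumKind.SENSITIVITY, SpectrumKind.ABSORBANCE) and np.any(
            vals < 0
        ):
            raise SpectrumValidationError(
                f"{self.kind.value} values must be nonnegative"
            )

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def window(self, lo: float, hi: float) -> "Spectrum":
        """Restrict to wavelengths within [lo, hi] (inclusive)."""
        mask = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if mask.sum() < 2:
            raise SpectrumValidationError(
                f"window [{lo}, {hi}] nm retains fewer than 2 points"
            )
        return replace(self, wavelengths=self.wavelengths[mask], values=self.values[mask])


def default_grid(lo: float = 300.0, hi: float = 700.0, step: float = 1.0) -> np.ndarray:
    """Canonical working grid: 300–700 nm at 1-nm steps unless overridden."""
    if not (hi > lo > 0) or step <= 0:
        raise ValueError("grid bounds must satisfy 0 < lo < hi and step > 0")
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def read_spectrum(path: str | Path, kind: SpectrumKind | str) -> Spectrum:
    """Read a two-column wavelength/value table (TSV or CSV).

    Delimiter is auto-detected (tab vs comma); ``#`` comment lines and blank
    lines are skipped; exactly two columns are required.
    """
    path = Path(path)
    wl: list[float] = []
    vals: list[float] = []
    delimiter: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if delimiter is None:
                delimiter = "\t" if "\t" in line else ","
            fields = [f.strip() for f in line.split(delimiter)]
            if len(fields) != 2:
                raise SpectrumParseError(
                    f"{path}:{lineno}: expected 2 columns, found {len(fields)}"
                )
            try:
                wl.append(float(fields[0]))
                vals.append(float(fields[1]))
            except ValueError as exc:
                raise SpectrumParseError(
                    f"{path}:{lineno}: non-numeric cell in {fields!r}"
                ) from exc
    if len(wl) < 2:
        raise SpectrumValidationError(f"{path}: fewer than 2 data rows")
    return Spectrum(np.array(wl), np.array(vals), SpectrumKind(kind), label=path.stem)


def write_spectrum(spectrum: Spectrum, path: str | Path, delimiter: str = "\t") -> None:
    """Write a spectrum as a two-column table; values round-trip exactly."""
    with open(path, "w") as fh:
        fh.write(f"# {spectrum.label or 'spectrum'} ({spectrum.kind.value})\n")
        for w, v in zip(spectrum.wavelengths, spectrum.values):
            fh.write(f"{w:.17g}{delimiter}{v:.17g}\n")


def resample(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid``.  No extrapolation:
    every grid point must lie inside the spectrum's wavelength range."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise SpectrumValidationError("grid must be 1-D, strictly increasing, length >= 2")
    lo, hi = spectrum.wavelengths[0], spectrum.wavelengths[-1]
    if grid[0] < lo or grid[-1] > hi:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] nm exceeds data range [{lo}, {hi}] nm; "
            "extrapolation is not supported"
        )
    vals = np.interp(grid, spectrum.wavelengths, spectrum.values)
    return replace(spectrum, wavelengths=grid, values=vals)
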