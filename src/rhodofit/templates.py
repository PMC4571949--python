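"""Log-normal rhodopsin α-band absorbance template.

Visual-pigment α-band absorbance has a fixed shape on a logarithmic
wavelength axis, so a single template parameterized only by the peak
wavelength λmax describes the whole family ("nomogram").  The form used
here is the log-normal template of the fly-pigment literature:

    A(λ) = exp[ -a · x² · (1 + b·x + c·x²) ],   x = log10(λ / λmax)

A(λmax) = 1 by construction, A ∈ (0, 1] everywhere, and the quartic in x
has a single stationary point at x = 0 for the default coefficients, so
the band is strictly unimodal.  The coefficients are data, not code:
alternative published α-band parameterizations can be swapped in via a
YAML config (``template_from_yaml``).

The fit-quality statistic reported alongside every λmax estimate is the
Pearson correlation between the fitted template and the data over the
fitting window (``fit_correlation``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .spectra import Spectrum, SpectrumKind, resample

__all__ = [
    "TemplateParams",
    "alpha_band",
    "template_spectrum",
    "fit_correlation",
    "template_from_yaml",
    "UndefinedCorrelationError",
]

#: Default shape coefficients of the log-normal α-band (unitless).
DEFAULT_SHAPE = {"a": 380.0, "b": 6.09, "c": 25.02}


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined for a constant series."""


@dataclass(frozen=True)
class TemplateParams:
    """λmax plus the shape coefficients of the log-normal α-band.

    ``shape_coefficients`` maps coefficient names (a, b, c) to values; the
    defaults reproduce the standard rhodopsin α-band shape (FWHM ≈ 95 nm
    at λmax = 480 nm).
    """

    lambda_max: float
    shape_coefficients: dict = field(default_factory=lambda: dict(DEFAULT_SHAPE))

    def __post_init__(self) -> None:
        if not 300.0 < self.lambda_max < 700.0:
            raise ValueError(
                f"lambda_max must lie in (300, 700) nm, got {self.lambda_max}"
            )
        missing = {"a", "b", "c"} - set(self.shape_coefficients)
        if missing:
            raise ValueError(f"shape_coefficients missing {sorted(missing)}")

    def with_lambda_max(self, lambda_max: float) -> "TemplateParams":
        return TemplateParams(lambda_max, dict(self.shape_coefficients))


def alpha_band(wavelength, params: TemplateParams):
    """Evaluate the α-band template at ``wavelength`` (nm; scalar or array).

    Returns relative absorbance in (0, 1], equal to 1 at λmax.
    """
    wl = np.asarray(wavelength, dtype=float)
    if np.any(wl <= 0):
        raise ValueError("wavelength must be > 0 nm")
    a = params.shape_coefficients["a"]
    b = params.shape_coefficients["b"]
    c = params.shape_coefficients["c"]
    x = np.log10(wl / params.lambda_max)
    out = np.exp(-a * x * x * (1.0 + b * x + c * x * x))
    return out if out.ndim else float(out)


def template_spectrum(params: TemplateParams, grid) -> Spectrum:
    """α-band template evaluated on a wavelength grid, as an absorbance Spectrum."""
    grid = np.asarray(grid, dtype=float)
    return Spectrum(
        grid,
        alpha_band(grid, params),
        SpectrumKind.ABSORBANCE,
        label=f"template λmax={params.lambda_max:g} nm",
    )


def fit_correlation(model: Spectrum, data: Spectrum, window: tuple[float, float]) -> float:
    """Pearson correlation between model and data values inside ``window``.

    The two spectra are compared on the data's grid restricted to the
    window (the model is resampled if its grid differs); at least three
    points and nonconstant series are required.
    """
    lo, hi = window
    dwin = data.window(lo, hi)
    if len(dwin) < 3:
        raise ValueError("correlation window must contain at least 3 points")
    if np.array_equal(model.wavelengths, data.wavelengths):
        mvals = model.values[(data.wavelengths >= lo) & (data.wavelengths <= hi)]
    else:
        mvals = resample(model, dwin.wavelengths).values
    if np.ptp(mvals) == 0 or np.ptp(dwin.values) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined: constant series in fitting window"
        )
    return float(np.corrcoef(mvals, dwin.values)[0, 1])


def template_from_yaml(path: str | Path, key: str, lambda_max: float = 500.0) -> TemplateParams:
    """Load named shape coefficients from a YAML config.

    The file maps template names to ``{a: ..., b: ..., c: ...}`` blocks
    (optionally under a top-level ``templates:`` section).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    table = doc.get("templates", doc)
    if key not in table:
        raise KeyError(f"template {key!r} not found in {path}")
    coeffs = {k: float(v) for k, v in table[key].items()}
    return TemplateParams(lambda_max, coeffs)
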