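"""Rhodopsin/metarhodopsin difference-spectrum construction and decomposition.

Fly rhodopsins are bistable: blue light converts the dark R form to a
thermostable metarhodopsin M, and orange light converts it back.
Microspectrophotometry therefore measures a *difference spectrum*

    DS(λ) = a_M · T(λ; λmax_M) − a_R · T(λ; λmax_R)

(M-state absorbance minus R-state absorbance), where T is the α-band
template.  Decomposition fixes λmax_R at the value determined
electrophysiologically and estimates λmax_M plus both amplitudes.  Two
separate amplitudes are fit rather than a single photoconversion
fraction: photoconversion need not be complete and the MSP path length is
uncalibrated, and unequal amplitudes absorb both effects.  At each
candidate λmax_M the amplitudes are a linear least-squares problem, so
the search is again a deterministic 1-D scan over λmax_M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ._search import grid_refine_minimize
from .fitting import InsufficientDataError, _as_wavelengths
from .spectra import Spectrum, SpectrumKind
from .templates import TemplateParams, alpha_band, fit_correlation

__all__ = [
    "MSPFit",
    "DifferenceDecomposition",
    "build_difference",
    "fit_difference",
    "transmission_to_absorbance",
    "DegenerateDecompositionError",
]


class DegenerateDecompositionError(ValueError):
    """Difference spectrum is identically zero in the fitting window."""


@dataclass(frozen=True)
class MSPFit:
    """Result of one difference-spectrum decomposition."""

    lambda_max_M: float
    amplitude_M: float
    amplitude_R: float
    correlation: float
    lambda_max_R_fixed: float
    clamped: bool = False  # an amplitude hit the nonnegativity bound

    def to_dict(self) -> dict:
        return {
            "lambda_max_M": self.lambda_max_M,
            "amplitude_M": self.amplitude_M,
            "amplitude_R": self.amplitude_R,
            "correlation": self.correlation,
            "lambda_max_R_fixed": self.lambda_max_R_fixed,
            "clamped": self.clamped,
        }


def build_difference(
    lambda_max_R: float,
    lambda_max_M: float,
    amplitude_R: float,
    amplitude_M: float,
    grid,
    params: TemplateParams | None = None,
) -> Spectrum:
    """Model difference spectrum a_M·T(λ;λmax_M) − a_R·T(λ;λmax_R) on ``grid``."""
    if amplitude_R < 0 or amplitude_M < 0:
        raise ValueError("amplitudes must be nonnegative")
    grid = np.asarray(grid, dtype=float)
    shape = None if params is None else dict(params.shape_coefficients)
    pr = TemplateParams(lambda_max_R) if shape is None else TemplateParams(lambda_max_R, shape)
    pm = TemplateParams(lambda_max_M) if shape is None else TemplateParams(lambda_max_M, dict(shape))
    ds = amplitude_M * alpha_band(grid, pm) - amplitude_R * alpha_band(grid, pr)
    return Spectrum(grid, ds, SpectrumKind.DIFFERENCE, label="model difference spectrum")


def _solve_amplitudes(tm: np.ndarray, tr: np.ndarray, y: np.ndarray):
    """Least-squares (a_M, a_R) for y ≈ a_M·tm − a_R·tr, clamped to ≥ 0."""
    design = np.column_stack([tm, -tr])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    a_m, a_r = float(coef[0]), float(coef[1])
    clamped = False
    if a_m < 0 or a_r < 0:
        clamped = True
        if a_m < 0 and a_r < 0:
            a_m = a_r = 0.0
        elif a_m < 0:
            a_m = 0.0
            a_r = max(0.0, -float(tr @ y) / float(tr @ tr))
        else:
            a_r = 0.0
            a_m = max(0.0, float(tm @ y) / float(tm @ tm))
    resid = y - (a_m * tm - a_r * tr)
    return a_m, a_r, float(resid @ resid), clamped


class DifferenceDecomposition(RegressorMixin, BaseEstimator):
    """Estimate λmax_M and amplitudes from a difference spectrum.

    Parameters
    ----------
    lambda_max_R : float
        R-form λmax (nm) held fixed during the fit, normally the value
        estimated from the same genotype's sensitivity spectrum.
    window : (float, float), default (440, 650)
        Fitting window in nm.
    search : (float, float), default (400, 650)
        λmax_M search interval (nm).
    shape_coefficients : dict or None
        Template shape override; None uses the package default.

    Attributes
    ----------
    lambda_max_M_, amplitude_M_, amplitude_R_ : float
    correlation_ : float
        Pearson r between the calculated and measured DS over the window.
    clamped_ : bool
        True if an amplitude was held at the nonnegativity bound.
    """

    def __init__(
        self,
        lambda_max_R: float = 480.0,
        window: tuple[float, float] = (440.0, 650.0),
        search: tuple[float, float] = (400.0, 650.0),
        shape_coefficients: dict | None = None,
        grid_step: float = 1.0,
        refine_tol: float = 1e-3,
    ) -> None:
        self.lambda_max_R = lambda_max_R
        self.window = window
        self.search = search
        self.shape_coefficients = shape_coefficients
        self.grid_step = grid_step
        self.refine_tol = refine_tol

    def _params(self, lam: float) -> TemplateParams:
        if self.shape_coefficients is None:
            return TemplateParams(lam)
        return TemplateParams(lam, dict(self.shape_coefficients))

    def fit(self, X, y) -> "DifferenceDecomposition":
        wl = _as_wavelengths(X)
        vals = np.asarray(y, dtype=float)
        if wl.shape != vals.shape:
            raise ValueError("X and y must have matching lengths")
        if not 300.0 < self.lambda_max_R < 700.0:
            raise ValueError("lambda_max_R must lie in (300, 700) nm")
        lo, hi = self.window
        mask = (wl >= lo) & (wl <= hi)
        wwl, wv = wl[mask], vals[mask]
        if wwl.size < 5:
            raise InsufficientDataError(
                f"window [{lo}, {hi}] nm contains {wwl.size} points; need >= 5"
            )
        if np.max(np.abs(wv)) == 0:
            raise DegenerateDecompositionError(
                "difference spectrum identically zero in window"
            )
        tr = alpha_band(wwl, self._params(self.lambda_max_R))

        def sse(lam: float) -> float:
            tm = alpha_band(wwl, self._params(lam))
            return _solve_amplitudes(tm, tr, wv)[2]

        lam = grid_refine_minimize(sse, self.search, self.grid_step, self.refine_tol)
        tm = alpha_band(wwl, self._params(lam))
        a_m, a_r, _, clamped = _solve_amplitudes(tm, tr, wv)
        calc = a_m * tm - a_r * tr
        model = Spectrum(wwl, calc, SpectrumKind.DIFFERENCE)
        data = Spectrum(wwl, wv, SpectrumKind.DIFFERENCE)
        self.lambda_max_M_ = lam
        self.amplitude_M_ = a_m
        self.amplitude_R_ = a_r
        self.correlation_ = fit_correlation(model, data, (lo, hi))
        self.clamped_ = clamped
        return self

    def predict(self, X) -> np.ndarray:
        wl = _as_wavelengths(X)
        tm = alpha_band(wl, self._params(self.lambda_max_M_))
        tr = alpha_band(wl, self._params(self.lambda_max_R))
        return self.amplitude_M_ * tm - self.amplitude_R_ * tr

    def result_(self) -> MSPFit:
        return MSPFit(
            lambda_max_M=self.lambda_max_M_,
            amplitude_M=self.amplitude_M_,
            amplitude_R=self.amplitude_R_,
            correlation=self.correlation_,
            lambda_max_R_fixed=float(self.lambda_max_R),
            clamped=self.clamped_,
        )


def fit_difference(
    ds: Spectrum,
    lambda_max_R_fixed: float,
    window: tuple[float, float] = (440.0, 650.0),
    search: tuple[float, float] = (400.0, 650.0),
    params: TemplateParams | None = None,
) -> MSPFit:
    """Decompose a measured difference spectrum with the R form fixed."""
    est = DifferenceDecomposition(
        lambda_max_R=lambda_max_R_fixed,
        window=window,
        search=search,
        shape_coefficients=None if params is None else dict(params.shape_coefficients),
    )
    est.fit(ds.wavelengths, ds.values)
    return est.result_()


def transmission_to_absorbance(spectrum: Spectrum) -> Spectrum:
    """Convert a raw transmission spectrum to absorbance, A = −log10 T."""
    if np.any(spectrum.values <= 0):
        raise ValueError("transmission values must be > 0 to take −log10")
    return Spectrum(
        spectrum.wavelengths,
        -np.log10(spectrum.values),
        SpectrumKind.ABSORBANCE,
        label=spectrum.label,
    )
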