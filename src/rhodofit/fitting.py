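"""R-form λmax estimation from spectral-sensitivity spectra.

A fly photoreceptor sensitivity spectrum carries two peaks: a dominant UV
peak from the sensitizing pigment and a visible α-band peak from the
rhodopsin itself.  The R-form λmax is estimated by fitting the log-normal
α-band template to the visible window only (default 420–620 nm, which
excludes the sensitizing-pigment band), minimizing the sum of squared
residuals between ``scale · template(λ; λmax)`` and the windowed data.
The amplitude is solved in closed form at each candidate λmax, so the
problem reduces to a deterministic 1-D search.

:class:`SensitivityTemplateFit` is a scikit-learn style estimator
(``fit(X, y)`` with wavelengths as X and sensitivities as y);
:func:`fit_sensitivity` is the spectrum-level convenience wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ._search import grid_refine_minimize
from .spectra import Spectrum, SpectrumKind
from .templates import TemplateParams, alpha_band, fit_correlation

__all__ = [
    "SensitivityFit",
    "SensitivityTemplateFit",
    "fit_sensitivity",
    "InsufficientDataError",
    "DegenerateFitError",
]


class InsufficientDataError(ValueError):
    """Fitting window contains too few points."""


class DegenerateFitError(ValueError):
    """Data are constant (or empty) in the fitting window."""


@dataclass(frozen=True)
class SensitivityFit:
    """Result of one sensitivity fit: the Table-row quantities."""

    lambda_max_R: float
    scale: float
    correlation: float
    window: tuple[float, float]
    n_points: int

    def to_dict(self) -> dict:
        return {
            "lambda_max_R": self.lambda_max_R,
            "scale": self.scale,
            "correlation": self.correlation,
            "window": list(self.window),
            "n_points": self.n_points,
        }


def _as_wavelengths(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 1:
        raise ValueError("X must be 1-D wavelengths or a single-column 2-D array")
    return X


class SensitivityTemplateFit(RegressorMixin, BaseEstimator):
    """Fit the α-band template to a sensitivity spectrum (visible window).

    Parameters
    ----------
    window : (float, float), default (420, 620)
        Fitting window in nm; chosen to exclude the UV sensitizing-pigment
        peak near 350 nm.
    search : (float, float), default (400, 650)
        Interval searched for λmax, in nm.
    shape_coefficients : dict or None
        Log-normal shape coefficients; None uses the package default.
    normalize : bool, default True
        Scale the windowed data to unit maximum before fitting (amplitude
        is refit afterwards on the raw data so ``scale_`` stays in data
        units).
    grid_step, refine_tol : float
        Coarse scan step and refinement tolerance for λmax, in nm.

    Attributes
    ----------
    lambda_max_ : float
        Estimated R-form λmax (nm).
    scale_ : float
        Nonnegative template amplitude in data units.
    correlation_ : float
        Pearson r between fitted curve and data over the window.
    n_points_ : int
        Number of data points inside the window.
    """

    def __init__(
        self,
        window: tuple[float, float] = (420.0, 620.0),
        search: tuple[float, float] = (400.0, 650.0),
        shape_coefficients: dict | None = None,
        normalize: bool = True,
        grid_step: float = 1.0,
        refine_tol: float = 1e-3,
    ) -> None:
        self.window = window
        self.search = search
        self.shape_coefficients = shape_coefficients
        self.normalize = normalize
        self.grid_step = grid_step
        self.refine_tol = refine_tol

    def _params(self, lambda_max: float) -> TemplateParams:
        if self.shape_coefficients is None:
            return TemplateParams(lambda_max)
        return TemplateParams(lambda_max, dict(self.shape_coefficients))

    def fit(self, X, y) -> "SensitivityTemplateFit":
        wl = _as_wavelengths(X)
        vals = np.asarray(y, dtype=float)
        if wl.shape != vals.shape:
            raise ValueError("X and y must have matching lengths")
        lo, hi = self.window
        mask = (wl >= lo) & (wl <= hi)
        wwl, wv = wl[mask], vals[mask]
        if wwl.size < 5:
            raise InsufficientDataError(
                f"window [{lo}, {hi}] nm contains {wwl.size} points; need >= 5"
            )
        if np.ptp(wv) == 0:
            raise DegenerateFitError("sensitivity constant in fitting window")
        peak = wv.max()
        yfit = wv / peak if self.normalize else wv

        def sse(lam: float) -> float:
            t = alpha_band(wwl, self._params(lam))
            s = max(0.0, float(t @ yfit) / float(t @ t))
            r = yfit - s * t
            return float(r @ r)

        lam = grid_refine_minimize(sse, self.search, self.grid_step, self.refine_tol)
        t = alpha_band(wwl, self._params(lam))
        scale = max(0.0, float(t @ wv) / float(t @ t))
        model = Spectrum(wwl, np.maximum(scale * t, 0.0), SpectrumKind.SENSITIVITY)
        data = Spectrum(wwl, np.maximum(wv, 0.0), SpectrumKind.SENSITIVITY)
        self.lambda_max_ = lam
        self.scale_ = scale
        self.correlation_ = fit_correlation(model, data, (lo, hi))
        self.n_points_ = int(wwl.size)
        return self

    def predict(self, X) -> np.ndarray:
        wl = _as_wavelengths(X)
        return self.scale_ * alpha_band(wl, self._params(self.lambda_max_))

    def result_(self) -> SensitivityFit:
        return SensitivityFit(
            lambda_max_R=self.lambda_max_,
            scale=self.scale_,
            correlation=self.correlation_,
            window=(float(self.window[0]), float(self.window[1])),
            n_points=self.n_points_,
        )


def fit_sensitivity(
    spectrum: Spectrum,
    window: tuple[float, float] = (420.0, 620.0),
    search: tuple[float, float] = (400.0, 650.0),
    params: TemplateParams | None = None,
) -> SensitivityFit:
    """Estimate the R-form λmax of a sensitivity spectrum.

    See :class:`SensitivityTemplateFit` for the procedure.  ``params``
    supplies alternative template shape coefficients (its own λmax is
    ignored — λmax is what is being estimated).
    """
    est = SensitivityTemplateFit(
        window=window,
        search=search,
        shape_coefficients=None if params is None else dict(params.shape_coefficients),
    )
    est.fit(spectrum.wavelengths, spectrum.values)
    return est.result_()
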