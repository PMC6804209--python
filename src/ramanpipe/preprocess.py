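"""Spectral preprocessing chain.

Axis calibration from a reference peak table, transmission correction,
iterative-polyfit autofluorescence removal (fit, point-wise minimum,
refit), Savitzky-Golay smoothing, region cropping and per-spectrum 0-1
normalization — applied in that fixed order by
:func:`preprocess_pipeline`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .spectra import RamanSpectrum

__all__ = [
    "CalibrationTable",
    "AxisCalibration",
    "BaselineFitConfig",
    "BaselineResult",
    "PreprocessConfig",
    "DEFAULT_REGIONS",
    "calibrate_axis",
    "correct_transmission",
    "remove_baseline",
    "remove_baseline_matrix",
    "savitzky_golay",
    "crop_to_regions",
    "minmax_normalize",
    "preprocess_pipeline",
    "preprocess_matrix",
]

#: Fingerprint + CH-stretching regions; the silent region in between
#: carries no class information and is dropped by default.
DEFAULT_REGIONS = ((500.0, 1700.0), (2800.0, 3000.0))


@dataclass(frozen=True)
class CalibrationTable:
    """(detector pixel, reference Raman shift cm^-1) pairs."""

    pixels: np.ndarray
    shifts: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        sh = np.asarray(self.shifts, dtype=float)
        if px.shape != sh.shape or px.ndim != 1:
            raise ValueError("pixels and shifts must be matching 1-D arrays")
        if px.size < 2:
            raise ValueError("need at least 2 calibration pairs")
        if np.unique(px).size != px.size:
            raise ValueError("calibration pixel indices must be distinct")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "shifts", sh)


@dataclass(frozen=True)
class AxisCalibration:
    """Fitted pixel -> cm^-1 map evaluated at every pixel."""

    axis: np.ndarray
    coefficients: np.ndarray  # power-series, ascending
    residuals: np.ndarray  # shift residual at each reference pair


def calibrate_axis(table: CalibrationTable, n_pixels: int,
                   fit_degree: int = 2) -> AxisCalibration:
    """Least-squares polynomial pixel->wavenumber calibration."""
    if fit_degree >= table.pixels.size:
        raise ValueError(
            f"fit_degree {fit_degree} needs more than {table.pixels.size} pairs"
        )
    poly = np.polynomial.Polynomial.fit(table.pixels, table.shifts, fit_degree)
    axis = poly(np.arange(n_pixels, dtype=float))
    residuals = table.shifts - poly(table.pixels)
    return AxisCalibration(
        axis=axis,
        coefficients=poly.convert().coef,
        residuals=residuals,
    )


def correct_transmission(spectrum: RamanSpectrum,
                         transmission: np.ndarray) -> RamanSpectrum:
    """Divide intensities channel-wise by the system transmission curve."""
    t = np.asarray(transmission, dtype=float)
    if t.shape != spectrum.intensities.shape:
        raise ValueError("transmission must match the spectrum length")
    if np.any(t <= 0):
        raise ValueError("transmission entries must be > 0")
    return spectrum.with_intensities(spectrum.intensities / t)


@dataclass(frozen=True)
class BaselineFitConfig:
    degree: int = 9
    max_iterations: int = 100
    tolerance: float = 1e-6  # relative change of the fit between iterations

    def __post_init__(self) -> None:
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass(frozen=True)
class BaselineResult:
    corrected: RamanSpectrum
    baseline: np.ndarray
    converged: bool
    n_iterations: int


def _modified_polyfit(x: np.ndarray, Y: np.ndarray,
                      config: BaselineFitConfig):
    """Iterative modified polyfit on rows of Y (n_spectra x n_channels).

    Fit a degree-d polynomial, clip the working signal to the point-wise
    minimum of signal and fit, refit; stop when the fit's maximum relative
    change drops below tolerance.  Returns (baselines, converged, iters).
    """
    # Map x to [-1, 1]: degree 9 on raw cm^-1 values is ill-conditioned.
    u = 2.0 * (x - x[0]) / (x[-1] - x[0]) - 1.0 if x[-1] > x[0] else np.zeros_like(x)
    V = np.polynomial.polynomial.polyvander(u, config.degree)
    Q, _ = np.linalg.qr(V)  # fit = Q (Q^T y), never form the hat matrix

    work = Y.T.copy()  # (n_channels, n_spectra)
    fit = Q @ (Q.T @ work)
    converged = np.zeros(work.shape[1], dtype=bool)
    n_iter = np.ones(work.shape[1], dtype=int)
    scale = np.maximum(np.abs(fit).max(axis=0), 1e-300)
    for it in range(2, config.max_iterations + 1):
        if converged.all():
            break
        work = np.minimum(work, fit)
        new_fit = Q @ (Q.T @ work)
        delta = np.abs(new_fit - fit).max(axis=0) / scale
        newly = delta < config.tolerance
        n_iter[~converged] = it
        converged |= newly
        fit = new_fit
        scale = np.maximum(np.abs(fit).max(axis=0), 1e-300)
    return fit.T, converged, n_iter


def remove_baseline(spectrum: RamanSpectrum,
                    config: BaselineFitConfig | None = None) -> BaselineResult:
    """Autofluorescence removal via iterative polynomial fitting.

    Returns the corrected spectrum and the fitted background; a spectrum
    that did not converge within ``max_iterations`` is flagged
    (``converged=False``), never silently accepted.
    """
    config = config or BaselineFitConfig()
    if len(spectrum) <= config.degree + 1:
        raise ValueError(
            f"need more than degree+1={config.degree + 1} channels, "
            f"got {len(spectrum)}"
        )
    baselines, conv, iters = _modified_polyfit(
        spectrum.wavenumbers, spectrum.intensities[None, :], config
    )
    baseline = baselines[0]
    return BaselineResult(
        corrected=spectrum.with_intensities(spectrum.intensities - baseline),
        baseline=baseline,
        converged=bool(conv[0]),
        n_iterations=int(iters[0]),
    )


def remove_baseline_matrix(wavenumbers: np.ndarray, Y: np.ndarray,
                           config: BaselineFitConfig | None = None):
    """Batch variant: corrected matrix, baselines, per-spectrum flags."""
    config = config or BaselineFitConfig()
    Y = np.asarray(Y, dtype=float)
    if Y.shape[1] <= config.degree + 1:
        raise ValueError("need more than degree+1 channels")
    baselines, conv, iters = _modified_polyfit(np.asarray(wavenumbers, float), Y, config)
    return Y - baselines, baselines, conv, iters


def _check_uniform_axis(wn: np.ndarray) -> bool:
    d = np.diff(wn)
    return bool(np.allclose(d, d[0], rtol=1e-6, atol=0.0))


def savitzky_golay(spectrum: RamanSpectrum, window: int = 21, order: int = 3,
                   resample: bool = False) -> RamanSpectrum:
    """Savitzky-Golay smoothing (window 21, order 3 by default).

    Requires a uniform wavenumber axis; with ``resample=True`` the spectrum
    is first linearly interpolated onto a uniform grid of the same span and
    channel count.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if order >= window:
        raise ValueError("order must be smaller than window")
    if window > len(spectrum):
        raise ValueError("window larger than spectrum")
    wn, y = spectrum.wavenumbers, spectrum.intensities
    if not _check_uniform_axis(wn):
        if not resample:
            raise ValueError(
                "non-uniform axis; pass resample=True to interpolate first"
            )
        uniform = np.linspace(wn[0], wn[-1], wn.size)
        y = np.interp(uniform, wn, y)
        wn = uniform
    return RamanSpectrum(wn, savgol_filter(y, window, order))


def crop_to_regions(spectrum: RamanSpectrum,
                    regions: Sequence[tuple]) -> RamanSpectrum:
    """Keep channels whose wavenumber falls inside any [lo, hi] region."""
    mask = _region_mask(spectrum.wavenumbers, regions)
    if not mask.any():
        raise ValueError("cropping removed every channel")
    return RamanSpectrum(spectrum.wavenumbers[mask], spectrum.intensities[mask])


def _region_mask(wn: np.ndarray, regions: Sequence[tuple]) -> np.ndarray:
    regions = [tuple(r) for r in regions]
    if not regions:
        raise ValueError("need at least one region")
    for (lo, hi) in regions:
        if lo >= hi:
            raise ValueError(f"bad region ({lo}, {hi})")
    ordered = sorted(regions)
    if ordered != regions:
        raise ValueError("regions must be sorted")
    for (_a, a_hi), (b_lo, _b) in zip(ordered, ordered[1:]):
        if b_lo <= a_hi:
            raise ValueError("regions must not overlap")
    mask = np.zeros(wn.size, dtype=bool)
    for lo, hi in regions:
        mask |= (wn >= lo) & (wn <= hi)
    return mask


def minmax_normalize(spectrum: RamanSpectrum,
                     on_constant: str = "raise") -> RamanSpectrum:
    """Per-spectrum 0-1 normalization: (x - min) / (max - min).

    A constant spectrum has zero range; by default this raises, with
    ``on_constant="zeros"`` it maps to the all-zero spectrum instead.
    """
    y = spectrum.intensities
    lo, hi = y.min(), y.max()
    if hi == lo:
        if on_constant == "zeros":
            return spectrum.with_intensities(np.zeros_like(y))
        raise ValueError(
            "constant spectrum cannot be 0-1 normalized "
            "(use on_constant='zeros' for an all-zeros fallback)"
        )
    return spectrum.with_intensities((y - lo) / (hi - lo))


@dataclass(frozen=True)
class PreprocessConfig:
    """Stage parameters; a ``None`` stage is skipped."""

    transmission: np.ndarray | None = None
    baseline: BaselineFitConfig | None = field(default_factory=BaselineFitConfig)
    sg_window: int | None = 21
    sg_order: int = 3
    regions: tuple | None = DEFAULT_REGIONS
    on_constant: str = "raise"
    resample: bool = False


def preprocess_pipeline(spectrum: RamanSpectrum,
                        config: PreprocessConfig | None = None) -> RamanSpectrum:
    """Fixed-order chain: transmission correction -> baseline removal ->
    Savitzky-Golay smoothing -> region crop -> 0-1 normalization."""
    config = config or PreprocessConfig()
    s = spectrum
    if config.transmission is not None:
        s = correct_transmission(s, config.transmission)
    if config.baseline is not None:
        s = remove_baseline(s, config.baseline).corrected
    if config.sg_window is not None:
        s = savitzky_golay(s, config.sg_window, config.sg_order,
                           resample=config.resample)
    if config.regions is not None:
        s = crop_to_regions(s, config.regions)
    return minmax_normalize(s, on_constant=config.on_constant)


def preprocess_matrix(wavenumbers: np.ndarray, Y: np.ndarray,
                      config: PreprocessConfig | None = None):
    """Batch pipeline over rows of Y.

    Returns ``(wavenumbers, matrix, info)`` where ``info`` counts baseline
    non-convergence and constant-spectrum fallbacks.  Identical per-row to
    :func:`preprocess_pipeline` (same stages, vectorized).
    """
    config = config or PreprocessConfig()
    wn = np.asarray(wavenumbers, dtype=float)
    Y = np.asarray(Y, dtype=float)
    info = {"baseline_not_converged": 0, "constant_fallbacks": 0}
    if config.transmission is not None:
        t = np.asarray(config.transmission, dtype=float)
        if np.any(t <= 0):
            raise ValueError("transmission entries must be > 0")
        Y = Y / t[None, :]
    if config.baseline is not None:
        Y, _, conv, _ = remove_baseline_matrix(wn, Y, config.baseline)
        info["baseline_not_converged"] = int((~conv).sum())
    if config.sg_window is not None:
        if not _check_uniform_axis(wn):
            if not config.resample:
                raise ValueError("non-uniform axis; set resample=True")
            uniform = np.linspace(wn[0], wn[-1], wn.size)
            Y = np.stack([np.interp(uniform, wn, row) for row in Y])
            wn = uniform
        Y = savgol_filter(Y, config.sg_window, config.sg_order, axis=1)
    if config.regions is not None:
        mask = _region_mask(wn, config.regions)
        if not mask.any():
            raise ValueError("cropping removed every channel")
        wn, Y = wn[mask], Y[:, mask]
    lo = Y.min(axis=1, keepdims=True)
    hi = Y.max(axis=1, keepdims=True)
    flat = (hi == lo).ravel()
    if flat.any():
        if config.on_constant != "zeros":
            raise ValueError(
                f"{int(flat.sum())} constant spectra cannot be normalized"
            )
        info["constant_fallbacks"] = int(flat.sum())
    span = np.where(hi > lo, hi - lo, 1.0)
    Y = (Y - lo) / span
    Y[flat] = 0.0
    return wn, Y, info
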