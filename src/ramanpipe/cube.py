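"""Hyperspectral cube handling: per-pixel preprocessing, band-image
extraction at Raman shifts of interest, and two-band pseudo-color
overlays."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import PreprocessConfig, preprocess_matrix
from .spectra import RamanSpectrum

__all__ = [
    "HyperspectralCube",
    "BandImage",
    "preprocess_cube",
    "extract_band_image",
    "two_band_overlay",
]


@dataclass
class HyperspectralCube:
    """(line position x scan step x wavenumber) intensities.

    ``pitch_um`` is (along-line pitch, scan-step pitch); the default scan
    samples a 100 um laser line at 5 um and travels 500 um at 10 um steps.
    """

    data: np.ndarray
    wavenumbers: np.ndarray
    pitch_um: tuple = (5.0, 10.0)
    label: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (line, step, channel)")
        if self.wavenumbers.size != self.data.shape[2]:
            raise ValueError("axis length must equal the spectral dimension")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube intensities must be finite")
        if any(p <= 0 for p in self.pitch_um):
            raise ValueError("pitches must be positive")

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:2]

    def pixel_spectrum(self, i: int, j: int) -> RamanSpectrum:
        return RamanSpectrum(self.wavenumbers, self.data[i, j])


@dataclass(frozen=True)
class BandImage:
    """2-D intensity slice of a cube around one band center."""

    values: np.ndarray
    center: float
    half_window: float
    label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("band image must be 2-D")

    @property
    def shape(self) -> tuple:
        return self.values.shape


def preprocess_cube(cube: HyperspectralCube,
                    config: PreprocessConfig | None = None) -> HyperspectralCube:
    """Run the spectral preprocessing chain on every pixel spectrum.

    Constant pixels are handled per the config's ``on_constant`` flag;
    the all-zeros fallback is the sensible batch default here.
    """
    config = config or PreprocessConfig(on_constant="zeros")
    ny, nx, _ = cube.data.shape
    flat = cube.data.reshape(ny * nx, -1)
    wn, out, _info = preprocess_matrix(cube.wavenumbers, flat, config)
    return HyperspectralCube(
        data=out.reshape(ny, nx, wn.size),
        wavenumbers=wn,
        pitch_um=cube.pitch_um,
        label=cube.label,
    )


def extract_band_image(cube: HyperspectralCube, center: float,
                       half_window: float = 5.0) -> BandImage:
    """Mean intensity over channels within center +/- half_window.

    With ``half_window=0`` the single nearest channel is sliced.
    """
    wn = cube.wavenumbers
    if half_window < 0:
        raise ValueError("half_window must be >= 0")
    if half_window == 0:
        if not (wn[0] <= center <= wn[-1]):
            raise ValueError(f"center {center} outside axis range")
        idx = int(np.argmin(np.abs(wn - center)))
        values = cube.data[:, :, idx]
    else:
        mask = (wn >= center - half_window) & (wn <= center + half_window)
        if not mask.any():
            raise ValueError(
                f"window [{center - half_window}, {center + half_window}] "
                "contains no channels"
            )
        values = cube.data[:, :, mask].mean(axis=2)
    return BandImage(values=values, center=float(center),
                     half_window=float(half_window), label=cube.label)


def _scale01(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi > lo:
        return (values - lo) / (hi - lo)
    # constant image: clip the constant into [0, 1] rather than inventing
    # contrast that is not there
    return np.clip(values, 0.0, 1.0)


def two_band_overlay(image_a: BandImage, image_b: BandImage) -> np.ndarray:
    """RGB overlay: ``image_a`` drives magenta (R+B), ``image_b`` green.

    Each image is min-max scaled independently; a pixel maximal in A and
    zero in B renders pure magenta.  Returns an (H, W, 3) float array.
    """
    a, b = image_a.values, image_b.values
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    sa, sb = _scale01(a), _scale01(b)
    rgb = np.empty(a.shape + (3,))
    rgb[..., 0] = sa
    rgb[..., 1] = sb
    rgb[..., 2] = sa
    return rgb
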