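"""Core spectral data containers.

A :class:`RamanSpectrum` is one calibrated spectrum (wavenumber axis in
cm^-1 plus intensities); a :class:`LabeledSpectrumSet` is a stack of
spectra sharing one axis, with a class label (and optionally a biopsy id)
per spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RamanSpectrum", "LabeledSpectrumSet"]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass(frozen=True)
class RamanSpectrum:
    """One spectrum: strictly increasing wavenumber axis + intensities."""

    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        wn = _as_float_array(self.wavenumbers, "wavenumbers")
        y = _as_float_array(self.intensities, "intensities")
        if wn.ndim != 1 or y.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if wn.shape != y.shape:
            raise ValueError(
                f"axis length {wn.size} != intensity length {y.size}"
            )
        if wn.size >= 2 and not np.all(np.diff(wn) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, intensities: np.ndarray) -> "RamanSpectrum":
        """Same axis, new intensities."""
        return RamanSpectrum(self.wavenumbers, intensities)


@dataclass
class LabeledSpectrumSet:
    """Spectra matrix (n_spectra x n_channels) with per-spectrum labels."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    labels: np.ndarray
    biopsy_ids: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.wavenumbers = _as_float_array(self.wavenumbers, "wavenumbers")
        self.intensities = _as_float_array(self.intensities, "intensities")
        self.labels = np.asarray(self.labels)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D (n_spectra, n_channels)")
        if self.wavenumbers.size != self.intensities.shape[1]:
            raise ValueError("axis length must equal n_channels")
        if self.labels.shape != (self.intensities.shape[0],):
            raise ValueError("labels must have one entry per spectrum")
        if self.biopsy_ids is not None:
            self.biopsy_ids = np.asarray(self.biopsy_ids)
            if self.biopsy_ids.shape != self.labels.shape:
                raise ValueError("biopsy_ids must have one entry per spectrum")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def spectrum(self, i: int) -> RamanSpectrum:
        return RamanSpectrum(self.wavenumbers, self.intensities[i])

    def subset(self, indices) -> "LabeledSpectrumSet":
        indices = np.asarray(indices)
        return LabeledSpectrumSet(
            wavenumbers=self.wavenumbers,
            intensities=self.intensities[indices],
            labels=self.labels[indices],
            biopsy_ids=None if self.biopsy_ids is None else self.biopsy_ids[indices],
        )
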