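"""Synthetic Raman data generator.

Produces labeled spectrum sets and hyperspectral cubes with the
statistical structure the downstream analysis assumes: pseudo-Voigt bands
at twelve reference positions with class-dependent amplitudes (including
class-specific absent bands), a smooth autofluorescence background,
additive noise, optional cosmic spikes, and spatially structured
concentration maps for cubes.

The per-class amplitude tiers in :data:`AMPLITUDE_TIERS` are documented
stand-ins encoding qualitative class differences ("high"/"small" band
levels); they are editable defaults, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .spectra import LabeledSpectrumSet, RamanSpectrum

__all__ = [
    "CLASS_NAMES",
    "ADENOMA_CLASSES",
    "IMAGING_CLASSES",
    "BAND_CENTERS",
    "ZERO_BANDS",
    "AMPLITUDE_TIERS",
    "BAND_WIDTHS",
    "BandProfile",
    "SyntheticConfig",
    "SpatialPattern",
    "make_class_profile",
    "simulate_spectrum",
    "simulate_labeled_dataset",
    "simulate_cube",
    "uniform_pattern",
    "two_compartment_pattern",
    "smooth_random_pattern",
    "default_cube_shape",
]

#: The seven tissue classes.
CLASS_NAMES = (
    "gland",
    "corticotroph",
    "gonadotroph",
    "somatotroph",
    "plurihormonal",
    "null_cell",
    "periosteal",
)

#: Adenoma subtypes (all lack the 1004 cm^-1 phenylalanine band).
ADENOMA_CLASSES = frozenset(
    {"corticotroph", "gonadotroph", "somatotroph", "plurihormonal", "null_cell"}
)

#: Classes used for band imaging / texture work (six of the seven).
IMAGING_CLASSES = (
    "gland",
    "corticotroph",
    "gonadotroph",
    "somatotroph",
    "null_cell",
    "periosteal",
)

#: The twelve reference band positions (cm^-1).
BAND_CENTERS = (
    590.0, 658.0, 874.0, 939.0, 1004.0, 1093.0,
    1254.0, 1331.0, 1445.0, 1663.0, 2873.0, 2945.0,
)

#: Bands absent per class: adenomas lack 1004; gonadotroph additionally
#: lacks 1093; the periosteal layer lacks 590, 658, 1004 and 1093.
ZERO_BANDS: Mapping[str, frozenset] = {
    "gland": frozenset(),
    "corticotroph": frozenset({1004.0}),
    "gonadotroph": frozenset({1004.0, 1093.0}),
    "somatotroph": frozenset({1004.0}),
    "plurihormonal": frozenset({1004.0}),
    "null_cell": frozenset({1004.0}),
    "periosteal": frozenset({590.0, 658.0, 1004.0, 1093.0}),
}

# Qualitative class signatures as relative band heights.  Classes sharing a
# zero-band set must differ in SHAPE (band-height ratios): downstream 0-1
# normalization removes any global scale factor.  One editable table.
AMPLITUDE_TIERS: Mapping[str, tuple] = {
    #               590   658   874   939  1004  1093  1254  1331  1445  1663  2873  2945
    "gland":        (0.35, 0.40, 0.35, 0.35, 1.00, 0.35, 0.60, 0.70, 0.90, 0.80, 0.70, 0.90),
    "corticotroph": (0.35, 0.40, 0.35, 0.35, 0.00, 0.35, 0.60, 0.70, 0.90, 0.80, 0.50, 0.65),
    "gonadotroph":  (0.30, 0.35, 0.30, 0.30, 0.00, 0.00, 0.55, 0.65, 0.85, 0.75, 0.70, 0.90),
    "somatotroph":  (0.30, 0.30, 0.55, 0.30, 0.00, 0.30, 0.45, 0.50, 1.00, 0.90, 0.80, 1.00),
    "plurihormonal": (0.55, 0.30, 0.60, 0.30, 0.00, 0.55, 0.50, 0.90, 0.70, 0.55, 0.80, 0.60),
    "null_cell":    (0.15, 0.20, 0.15, 0.15, 0.00, 0.30, 0.50, 0.60, 0.85, 0.45, 0.70, 0.90),
    "periosteal":   (0.00, 0.00, 0.60, 0.70, 0.00, 0.00, 0.80, 0.85, 0.60, 0.55, 0.40, 0.50),
}

#: Default FWHM per band (cm^-1); CH-stretching bands are broader.
BAND_WIDTHS: Mapping[float, float] = {
    590.0: 14.0, 658.0: 14.0, 874.0: 14.0, 939.0: 16.0,
    1004.0: 10.0, 1093.0: 16.0, 1254.0: 22.0, 1331.0: 20.0,
    1445.0: 24.0, 1663.0: 26.0, 2873.0: 40.0, 2945.0: 40.0,
}

_LORENTZ_FRACTION = 0.5  # pseudo-Voigt mixing, fixed

# Fixed positive degree-5 coefficients for the default smooth background;
# deterministic given the config so the generative mean has a closed form.
_BASELINE_COEFFS = np.array([1.0, 0.6, 0.8, 0.4, 0.7, 0.5])


@dataclass(frozen=True)
class BandProfile:
    """Per-class band model: (center cm^-1, amplitude >= 0, FWHM cm^-1)."""

    class_name: str
    bands: tuple  # of (center, amplitude, width)

    def __post_init__(self) -> None:
        if self.class_name not in CLASS_NAMES:
            raise ValueError(
                f"unknown class {self.class_name!r}; valid: {CLASS_NAMES}"
            )
        for center, amp, width in self.bands:
            if center not in BAND_CENTERS:
                raise ValueError(f"band center {center} not a reference position")
            if amp < 0:
                raise ValueError("band amplitudes must be >= 0")
            if not (2.0 < width < 60.0):
                raise ValueError("band FWHM must lie in (2, 60) cm^-1")

    @property
    def centers(self) -> np.ndarray:
        return np.array([b[0] for b in self.bands])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([b[1] for b in self.bands])

    @property
    def widths(self) -> np.ndarray:
        return np.array([b[2] for b in self.bands])

    def amplitude_at(self, center: float) -> float:
        for c, a, _ in self.bands:
            if c == center:
                return a
        raise KeyError(center)

    def scaled(self, factors: Mapping[float, float]) -> "BandProfile":
        """New profile with per-center amplitude scale factors."""
        bands = tuple(
            (c, a * factors.get(c, 1.0), w) for c, a, w in self.bands
        )
        return BandProfile(self.class_name, bands)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the generator; deterministic under a fixed seed."""

    n_spectra_per_class: int = 50
    axis: tuple = (500.0, 3200.0, 2.0)  # start, stop, step (cm^-1)
    baseline: tuple = ("polynomial", 0.5)  # kind, magnitude rel. tallest peak
    noise_sd: float = 0.02  # relative to the tallest peak
    cosmic_spike_rate: float = 0.0  # expected spikes per spectrum
    amplitude_jitter_sd: float = 0.15  # log-normal sigma
    seed: int = 0

    def __post_init__(self) -> None:
        start, stop, step = self.axis
        if start > 500.0 or stop < 3200.0:
            raise ValueError("axis must cover at least 500-3200 cm^-1")
        if step <= 0:
            raise ValueError("axis step must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.cosmic_spike_rate < 0:
            raise ValueError("cosmic_spike_rate must be >= 0")
        kind, magnitude = self.baseline
        if kind not in ("polynomial", "exponential-decay"):
            raise ValueError("baseline kind must be polynomial or exponential-decay")
        if magnitude < 0:
            raise ValueError("baseline magnitude must be >= 0")
        if self.n_spectra_per_class < 1:
            raise ValueError("n_spectra_per_class must be >= 1")

    def wavenumbers(self) -> np.ndarray:
        start, stop, step = self.axis
        n = int(np.floor((stop - start) / step)) + 1
        return start + step * np.arange(n)


@dataclass(frozen=True)
class SpatialPattern:
    """Per-band 2-D concentration maps in [0, 1] sharing one shape."""

    shape: tuple
    maps: Mapping[float, np.ndarray]

    def __post_init__(self) -> None:
        for center, m in self.maps.items():
            m = np.asarray(m, dtype=float)
            if m.shape != tuple(self.shape):
                raise ValueError(
                    f"map for band {center} has shape {m.shape}, expected {self.shape}"
                )
            if m.min() < 0 or m.max() > 1:
                raise ValueError(f"map for band {center} must lie in [0, 1]")


def make_class_profile(class_name: str, rng_seed: int) -> BandProfile:
    """Band profile for a class with seed-reproducible amplitude jitter.

    Amplitudes are the class tier values multiplied by log-normal jitter
    (sigma 0.15); class-specific zero bands stay exactly zero.
    """
    if class_name not in CLASS_NAMES:
        raise ValueError(
            f"unknown class {class_name!r}; valid classes: {CLASS_NAMES}"
        )
    rng = np.random.default_rng(rng_seed)
    tiers = AMPLITUDE_TIERS[class_name]
    zeros = ZERO_BANDS[class_name]
    jitter = rng.lognormal(mean=0.0, sigma=0.15, size=len(BAND_CENTERS))
    bands = []
    for center, tier, j in zip(BAND_CENTERS, tiers, jitter):
        amp = 0.0 if center in zeros else tier * j
        bands.append((center, amp, BAND_WIDTHS[center]))
    return BandProfile(class_name, tuple(bands))


def pseudo_voigt(wavenumbers: np.ndarray, center: float, fwhm: float,
                 eta: float = _LORENTZ_FRACTION) -> np.ndarray:
    """Unit-height pseudo-Voigt line shape."""
    x = np.asarray(wavenumbers, dtype=float) - center
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    gamma = fwhm / 2.0
    gauss = np.exp(-0.5 * (x / sigma) ** 2)
    lorentz = 1.0 / (1.0 + (x / gamma) ** 2)
    return eta * lorentz + (1.0 - eta) * gauss


def _peak_basis(profile: BandProfile, wavenumbers: np.ndarray) -> np.ndarray:
    """(n_bands, n_channels) unit-height shapes at the profile's centers."""
    if not profile.bands:
        return np.zeros((0, wavenumbers.size))
    return np.stack(
        [pseudo_voigt(wavenumbers, c, w) for c, _, w in profile.bands]
    )


def _baseline_curve(config: SyntheticConfig, peak_scale: float) -> np.ndarray:
    """Deterministic smooth background, scaled by magnitude x tallest peak."""
    kind, magnitude = config.baseline
    wn = config.wavenumbers()
    u = (wn - wn[0]) / (wn[-1] - wn[0])
    if kind == "polynomial":
        shape = np.polynomial.polynomial.polyval(u, _BASELINE_COEFFS)
    else:  # exponential-decay
        shape = np.exp(-3.0 * u)
    shape = shape / shape.max()
    return magnitude * peak_scale * shape


def simulate_spectrum(profile: BandProfile, config: SyntheticConfig,
                      seed: int) -> RamanSpectrum:
    """One spectrum: sum of pseudo-Voigt bands + background + noise (+ spikes).

    A peakless profile with zero background magnitude and zero noise yields
    the all-zero spectrum.
    """
    if config.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    wn = config.wavenumbers()
    amps = profile.amplitudes if profile.bands else np.zeros(0)
    signal = amps @ _peak_basis(profile, wn) if amps.size else np.zeros(wn.size)
    peak_scale = float(amps.max()) if amps.size and amps.max() > 0 else 0.0
    y = signal + _baseline_curve(config, peak_scale)
    noise_scale = peak_scale if peak_scale > 0 else 1.0
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd * noise_scale, size=wn.size)
    if config.cosmic_spike_rate > 0:
        n_spikes = rng.poisson(config.cosmic_spike_rate)
        if n_spikes:
            idx = rng.integers(0, wn.size, size=n_spikes)
            y[idx] += noise_scale * rng.uniform(5.0, 20.0, size=n_spikes)
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite synthetic intensities")
    return RamanSpectrum(wn, y)


def simulate_labeled_dataset(config: SyntheticConfig) -> LabeledSpectrumSet:
    """7 x n_spectra_per_class labeled spectra, reproducible under seed.

    Each spectrum carries its own jittered amplitude draw; generation is
    vectorized per class off a single generator seeded with ``config.seed``.
    Spectra are round-robin assigned to four pseudo-biopsies per class so
    grouped splitting is exercisable.
    """
    rng = np.random.default_rng(config.seed)
    wn = config.wavenumbers()
    n = config.n_spectra_per_class
    blocks, labels, biopsies = [], [], []
    for class_name in CLASS_NAMES:
        base = make_class_profile(class_name, rng_seed=int(rng.integers(2**31)))
        basis = _peak_basis(base, wn)
        tier_amps = base.amplitudes
        jitter = rng.lognormal(0.0, config.amplitude_jitter_sd, size=(n, len(BAND_CENTERS)))
        amps = tier_amps[None, :] * jitter  # zero bands stay zero
        peak_scale = float(tier_amps.max()) if tier_amps.max() > 0 else 1.0
        block = amps @ basis + _baseline_curve(config, float(tier_amps.max()))[None, :]
        if config.noise_sd > 0:
            block = block + rng.normal(0.0, config.noise_sd * peak_scale, size=block.shape)
        if config.cosmic_spike_rate > 0:
            n_spikes = rng.poisson(config.cosmic_spike_rate, size=n)
            for i, k in enumerate(n_spikes):
                if k:
                    idx = rng.integers(0, wn.size, size=k)
                    block[i, idx] += peak_scale * rng.uniform(5.0, 20.0, size=k)
        blocks.append(block)
        labels.extend([class_name] * n)
        biopsies.extend(f"{class_name}_b{i % 4}" for i in range(n))
    return LabeledSpectrumSet(
        wavenumbers=wn,
        intensities=np.vstack(blocks),
        labels=np.array(labels),
        biopsy_ids=np.array(biopsies),
    )


def default_cube_shape() -> tuple:
    """Spatial grid of the default scan: 100 um line at 5 um pitch (20
    positions) x 500 um travel at 10 um steps (50 positions)."""
    return (20, 50)


def uniform_pattern(shape: tuple, centers: Sequence[float],
                    value: float = 1.0) -> SpatialPattern:
    maps = {c: np.full(shape, float(value)) for c in centers}
    return SpatialPattern(tuple(shape), maps)


def two_compartment_pattern(shape: tuple, left_bands: Sequence[float],
                            right_bands: Sequence[float],
                            uniform_bands: Sequence[float] = ()) -> SpatialPattern:
    """Anticorrelated left/right compartments (Fig.-5-style layout).

    ``left_bands`` get concentration 1 on the left half of the scan axis and
    0 on the right; ``right_bands`` the complement; ``uniform_bands`` are 1
    everywhere.
    """
    shape = tuple(shape)
    half = shape[1] // 2
    left = np.zeros(shape)
    left[:, :half] = 1.0
    right = 1.0 - left
    maps = {}
    for c in left_bands:
        maps[c] = left.copy()
    for c in right_bands:
        maps[c] = right.copy()
    for c in uniform_bands:
        maps[c] = np.ones(shape)
    return SpatialPattern(shape, maps)


def smooth_random_pattern(shape: tuple, centers: Sequence[float], seed: int,
                          correlation_length: float = 3.0) -> SpatialPattern:
    """Smooth random concentration fields rescaled to [0, 1] per band."""
    rng = np.random.default_rng(seed)
    maps = {}
    for c in centers:
        f = gaussian_filter(rng.normal(size=shape), sigma=correlation_length)
        lo, hi = f.min(), f.max()
        maps[c] = (f - lo) / (hi - lo) if hi > lo else np.zeros(shape)
    return SpatialPattern(tuple(shape), maps)


def simulate_cube(profile: BandProfile, pattern: SpatialPattern,
                  config: SyntheticConfig, seed: int,
                  pitch_um: tuple = (5.0, 10.0)):
    """Hyperspectral cube whose pixel (i, j) is the profile's spectrum with
    each band amplitude scaled by that band's concentration map at (i, j).

    The background is shared across pixels (deterministic given config);
    noise is drawn per voxel.
    """
    from .cube import HyperspectralCube  # local import avoids a cycle

    active = [c for c, a, _ in profile.bands if a > 0]
    missing = [c for c in active if c not in pattern.maps]
    if missing:
        raise ValueError(f"pattern lacks maps for bands {missing}")
    shapes = {np.asarray(m).shape for m in pattern.maps.values()}
    if len(shapes) > 1:
        raise ValueError(f"pattern maps disagree on shape: {shapes}")

    rng = np.random.default_rng(seed)
    wn = config.wavenumbers()
    ny, nx = pattern.shape
    basis = _peak_basis(profile, wn)
    amps = profile.amplitudes
    data = np.zeros((ny, nx, wn.size))
    for k, (center, amp, _) in enumerate(profile.bands):
        if amp <= 0:
            continue
        conc = np.asarray(pattern.maps[center], dtype=float)
        data += amp * conc[:, :, None] * basis[k][None, None, :]
    peak_scale = float(amps.max()) if amps.size and amps.max() > 0 else 0.0
    data += _baseline_curve(config, peak_scale)[None, None, :]
    if config.noise_sd > 0:
        scale = peak_scale if peak_scale > 0 else 1.0
        data += rng.normal(0.0, config.noise_sd * scale, size=data.shape)
    return HyperspectralCube(
        data=data, wavenumbers=wn, pitch_um=tuple(pitch_um),
        label=profile.class_name,
    )
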