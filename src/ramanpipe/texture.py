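"""Grey-level co-occurrence texture quantification of band images.

GLCMs at the four one-pixel offsets (0, 45, 90, 135 degrees), the four
Haralick statistics (contrast, correlation, energy, homogeneity), their
per-image aggregation and per-(class, band) medians, and 2-D correlation
coefficients between band images of different classes.

Coordinate convention: row index increases downward, so the 0/45/90/135
degree offsets are (0, 1), (-1, 1), (-1, 0), (-1, -1) in (row, col).
GLCMs are non-symmetric (ordered pairs) and normalized by the pair count,
matching the reference implementation's defaults; a symmetric option
exists.  An undefined correlation (constant image) is reported as NaN,
never coerced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cube import BandImage

__all__ = [
    "OFFSETS_BY_ANGLE",
    "DEFAULT_OFFSETS",
    "GLCM",
    "TextureFeatures",
    "quantize_image",
    "compute_glcm",
    "haralick_features",
    "image_texture",
    "class_texture_summary",
    "corr2",
    "center_crop",
    "class_band_correlation_matrix",
]

OFFSETS_BY_ANGLE: Mapping[int, tuple] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}

DEFAULT_OFFSETS = tuple(OFFSETS_BY_ANGLE.values())

FEATURE_NAMES = ("contrast", "correlation", "energy", "homogeneity")


@dataclass(frozen=True)
class GLCM:
    matrix: np.ndarray  # (L, L)
    levels: int
    offset: tuple
    normalized: bool

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (self.levels, self.levels):
            raise ValueError("GLCM must be (levels x levels)")
        if self.levels < 2:
            raise ValueError("need at least 2 grey levels")
        if np.any(m < 0):
            raise ValueError("co-occurrence entries must be >= 0")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class TextureFeatures:
    """The four Haralick statistics; correlation is NaN when undefined."""

    contrast: float
    correlation: float
    energy: float
    homogeneity: float

    @property
    def correlation_defined(self) -> bool:
        return not math.isnan(self.correlation)

    def as_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "correlation": self.correlation,
            "energy": self.energy,
            "homogeneity": self.homogeneity,
        }


def _image_values(image) -> np.ndarray:
    if isinstance(image, BandImage):
        return image.values
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValueError("image must be 2-D")
    return arr


def quantize_image(image, n_levels: int = 8) -> np.ndarray:
    """Linear binning of [min, max] into levels 1..n_levels.

    A constant image maps entirely to level 1.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    arr = _image_values(image)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.ones(arr.shape, dtype=int)
    q = np.floor((arr - lo) / (hi - lo) * n_levels).astype(int)
    return np.clip(q, 0, n_levels - 1) + 1


def compute_glcm(qimage: np.ndarray, offset: tuple, n_levels: int | None = None,
                 normalize: bool = True, symmetric: bool = False) -> GLCM:
    """Count level pairs at pixel positions (p, p + offset).

    ``qimage`` holds integer levels 1..L (from :func:`quantize_image`).
    Entry (i, j) of the (unnormalized) matrix counts ordered pairs whose
    first pixel has level i+1 and whose offset neighbor has level j+1.
    """
    q = np.asarray(qimage)
    if q.ndim != 2:
        raise ValueError("quantized image must be 2-D")
    dr, dc = (int(offset[0]), int(offset[1]))
    if dr == 0 and dc == 0:
        raise ValueError("offset must be nonzero")
    if abs(dr) >= q.shape[0] or abs(dc) >= q.shape[1]:
        raise ValueError(f"image {q.shape} too small for offset {(dr, dc)}")
    L = int(n_levels) if n_levels is not None else int(q.max())
    if q.min() < 1 or q.max() > L:
        raise ValueError("levels must lie in 1..n_levels")

    rows = slice(max(0, -dr), q.shape[0] - max(0, dr))
    cols = slice(max(0, -dc), q.shape[1] - max(0, dc))
    first = q[rows, cols]
    second = q[rows.start + dr: rows.stop + dr, cols.start + dc: cols.stop + dc]
    counts = np.zeros((L, L))
    np.add.at(counts, (first.ravel() - 1, second.ravel() - 1), 1.0)
    if symmetric:
        counts = counts + counts.T
    if normalize:
        total = counts.sum()
        if total > 0:
            counts = counts / total
    return GLCM(matrix=counts, levels=L, offset=(dr, dc), normalized=normalize)


def haralick_features(glcm: GLCM) -> TextureFeatures:
    """Contrast, correlation, energy and homogeneity of a normalized GLCM.

    contrast    = sum p(i,j) (i-j)^2
    correlation = sum p(i,j) (i-mu_i)(j-mu_j) / (sigma_i sigma_j)
    energy      = sum p(i,j)^2
    homogeneity = sum p(i,j) / (1 + |i-j|)

    A constant image gives contrast 0 and energy 1; a diagonal GLCM gives
    homogeneity 1; correlation is NaN when either marginal is degenerate.
    """
    if not glcm.normalized:
        raise ValueError("haralick_features requires a normalized GLCM")
    p = glcm.matrix
    L = glcm.levels
    i = np.arange(1, L + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float((p * (ii - jj) ** 2).sum())
    energy = float((p * p).sum())
    homogeneity = float((p / (1.0 + np.abs(ii - jj))).sum())
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((i * pi).sum())
    mu_j = float((i * pj).sum())
    var_i = float(((i - mu_i) ** 2 * pi).sum())
    var_j = float(((i - mu_j) ** 2 * pj).sum())
    if var_i <= 0 or var_j <= 0:
        correlation = math.nan
    else:
        cov = float((p * (ii - mu_i) * (jj - mu_j)).sum())
        correlation = cov / math.sqrt(var_i * var_j)
    return TextureFeatures(contrast, correlation, energy, homogeneity)


def image_texture(image, n_levels: int = 8,
                  offsets: Sequence[tuple] = DEFAULT_OFFSETS) -> TextureFeatures:
    """Quantize, compute a GLCM per offset, average the features.

    Undefined correlations are excluded from the mean; if every offset is
    undefined the aggregated correlation is NaN.
    """
    q = quantize_image(image, n_levels)
    feats = [
        haralick_features(compute_glcm(q, off, n_levels=n_levels))
        for off in offsets
    ]
    corr = [f.correlation for f in feats if not math.isnan(f.correlation)]
    return TextureFeatures(
        contrast=float(np.mean([f.contrast for f in feats])),
        correlation=float(np.mean(corr)) if corr else math.nan,
        energy=float(np.mean([f.energy for f in feats])),
        homogeneity=float(np.mean([f.homogeneity for f in feats])),
    )


def class_texture_summary(images: Mapping, n_levels: int = 8,
                          offsets: Sequence[tuple] = DEFAULT_OFFSETS
                          ) -> pd.DataFrame:
    """Median texture features per (class, band).

    ``images`` maps (class, band) -> iterable of images.  Returns a tidy
    frame with one row per (class, band); empty groups are omitted.
    Features are aggregated mean-over-offsets within an image, then
    median-over-images within a group.
    """
    rows = []
    for (cls, band), group in images.items():
        group = list(group)
        if not group:
            continue
        feats = [image_texture(im, n_levels=n_levels, offsets=offsets)
                 for im in group]
        row = {"class": cls, "band": band, "n_images": len(group)}
        for name in FEATURE_NAMES:
            values = [getattr(f, name) for f in feats]
            defined = [v for v in values if not math.isnan(v)]
            row[name] = float(np.median(defined)) if defined else math.nan
        rows.append(row)
    return pd.DataFrame(rows)


def corr2(image_a, image_b) -> float:
    """2-D correlation coefficient (Pearson r of the flattened images).

    Identical images give 1; an image against its negative gives -1; the
    value is NaN (undefined) if either image is constant.
    """
    a = _image_values(image_a).ravel()
    b = _image_values(image_b).ravel()
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0:
        return math.nan
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def center_crop(image, shape: tuple) -> np.ndarray:
    """Crop an image symmetrically to the requested (rows, cols)."""
    arr = _image_values(image)
    r, c = shape
    if r > arr.shape[0] or c > arr.shape[1]:
        raise ValueError(f"cannot crop {arr.shape} to {shape}")
    r0 = (arr.shape[0] - r) // 2
    c0 = (arr.shape[1] - c) // 2
    return arr[r0:r0 + r, c0:c0 + c]


def class_band_correlation_matrix(images: Mapping, reference: str = "gland"
                                  ) -> pd.DataFrame:
    """corr2 of each class's band image against the reference class's image
    at the same band, after center-cropping to the common minimal shape.

    ``images`` maps class -> {band -> image}.  Returns a (class x band)
    frame; the reference row is identically 1 wherever its image is
    non-constant.
    """
    if reference not in images:
        raise ValueError(f"reference class {reference!r} not among images")
    classes = list(images.keys())
    bands = sorted({b for per_class in images.values() for b in per_class})
    shapes = [
        _image_values(im).shape
        for per_class in images.values() for im in per_class.values()
    ]
    common = (min(s[0] for s in shapes), min(s[1] for s in shapes))
    if common[0] < 2 or common[1] < 2:
        raise ValueError("no usable common image shape")
    out = pd.DataFrame(index=classes, columns=bands, dtype=float)
    for band in bands:
        if band not in images[reference]:
            continue
        ref_img = center_crop(images[reference][band], common)
        for cls in classes:
            if band in images[cls]:
                out.loc[cls, band] = corr2(
                    center_crop(images[cls][band], common), ref_img
                )
    return out
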