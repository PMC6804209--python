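"""Plain-text / HDF5 readers and writers.

Labeled spectrum sets travel as CSV (row 1 = labels, column 1 =
wavenumber, one intensity column per spectrum); cubes as HDF5 with a
``/cube`` dataset, a ``/wavenumber`` axis and pitch attributes.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .cube import HyperspectralCube
from .spectra import LabeledSpectrumSet, RamanSpectrum

__all__ = [
    "write_labeled_csv",
    "read_labeled_csv",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "read_transmission_csv",
    "write_cube_h5",
    "read_cube_h5",
]

_BIOPSY_MARKER = "#biopsy"


def write_labeled_csv(dataset: LabeledSpectrumSet, path) -> None:
    path = Path(path)
    header = ["wavenumber"] + [str(label) for label in dataset.labels]
    lines = [",".join(header)]
    if dataset.biopsy_ids is not None:
        lines.append(",".join([_BIOPSY_MARKER] + [str(b) for b in dataset.biopsy_ids]))
    block = np.column_stack([dataset.wavenumbers, dataset.intensities.T])
    for row in block:
        lines.append(",".join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_labeled_csv(path) -> LabeledSpectrumSet:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip().split(",")
        labels = np.array(header[1:])
        pos = fh.tell()
        second = fh.readline().strip().split(",")
        biopsy_ids = None
        if second and second[0] == _BIOPSY_MARKER:
            biopsy_ids = np.array(second[1:])
        else:
            fh.seek(pos)
        block = np.loadtxt(fh, delimiter=",")
    block = np.atleast_2d(block)
    return LabeledSpectrumSet(
        wavenumbers=block[:, 0],
        intensities=block[:, 1:].T,
        labels=labels,
        biopsy_ids=biopsy_ids,
    )


def write_spectrum_csv(spectrum: RamanSpectrum, path) -> None:
    pd.DataFrame(
        {"wavenumber": spectrum.wavenumbers, "intensity": spectrum.intensities}
    ).to_csv(path, index=False)


def read_spectrum_csv(path) -> RamanSpectrum:
    df = pd.read_csv(path)
    return RamanSpectrum(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


def read_transmission_csv(path) -> np.ndarray:
    """Two-column CSV (wavenumber, transmission); returns the curve."""
    df = pd.read_csv(path)
    return df.iloc[:, 1].to_numpy(dtype=float)


def write_cube_h5(cube: HyperspectralCube, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("cube", data=cube.data)
        fh.create_dataset("wavenumber", data=cube.wavenumbers)
        fh.attrs["pitch_line_um"] = cube.pitch_um[0]
        fh.attrs["pitch_step_um"] = cube.pitch_um[1]
        if cube.label is not None:
            fh.attrs["label"] = cube.label


def read_cube_h5(path) -> HyperspectralCube:
    with h5py.File(path, "r") as fh:
        return HyperspectralCube(
            data=fh["cube"][()],
            wavenumbers=fh["wavenumber"][()],
            pitch_um=(
                float(fh.attrs.get("pitch_line_um", 5.0)),
                float(fh.attrs.get("pitch_step_um", 10.0)),
            ),
            label=(
                str(fh.attrs["label"]) if "label" in fh.attrs else None
            ),
        )
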