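"""Reading, writing, validation and regridding of Raman spectral tables.

A spectral table is a plain CSV or TSV file whose first column,
``wavenumber``, holds the Raman-shift axis in cm⁻¹ and whose remaining
columns hold one spectrum each (column header = spectrum id).  Class labels
live in a sibling two-column manifest ``<stem>.labels.csv`` with columns
``id,class_name``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "read_spectrum_table",
    "write_spectrum_table",
    "resample_to_grid",
]

AXIS_COLUMN = "wavenumber"


def _validate_axis(axis: np.ndarray) -> None:
    if axis.ndim != 1:
        raise ValueError("axis must be one-dimensional")
    if not np.all(np.isfinite(axis)):
        raise ValueError("axis contains NaN/Inf")
    if np.any(np.diff(axis) <= 0):
        raise ValueError("axis not strictly increasing")


@dataclass
class Spectrum:
    """A single Raman measurement: wavenumber axis (cm⁻¹) and intensities."""

    axis: np.ndarray
    intensities: np.ndarray
    id: str = "spectrum"

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        _validate_axis(self.axis)
        if self.axis.shape != self.intensities.shape:
            raise ValueError("axis and intensities must have the same length")
        if self.axis.size < 1:
            raise ValueError("spectrum must have at least one channel")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain NaN/Inf")

    def __len__(self) -> int:
        return self.axis.size


@dataclass
class SpectrumSet:
    """N spectra sharing one wavenumber axis, with optional class labels."""

    axis: np.ndarray
    intensity_matrix: np.ndarray
    ids: Optional[Sequence[str]] = None
    labels: Optional[np.ndarray] = None
    class_names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity_matrix = np.atleast_2d(
            np.asarray(self.intensity_matrix, dtype=float)
        )
        _validate_axis(self.axis)
        n, length = self.intensity_matrix.shape
        if n < 1:
            raise ValueError("no spectra")
        if length != self.axis.size:
            raise ValueError("intensity rows must match axis length")
        if not np.all(np.isfinite(self.intensity_matrix)):
            raise ValueError("intensities contain NaN/Inf")
        if self.ids is None:
            self.ids = [f"s{i}" for i in range(n)]
        self.ids = list(self.ids)
        if len(self.ids) != n:
            raise ValueError("one id per spectrum required")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels must have one entry per spectrum")
            c = int(self.labels.max()) + 1
            present = np.unique(self.labels)
            if self.labels.min() < 0:
                raise ValueError("labels must be non-negative")
            if self.class_names is not None:
                self.class_names = list(self.class_names)
                if len(self.class_names) < c:
                    raise ValueError("fewer class names than label values")
            if present.size != c:
                raise ValueError("every class index in 0..C-1 must occur")

    @property
    def n_spectra(self) -> int:
        return self.intensity_matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return self.axis.size

    @property
    def n_classes(self) -> int:
        if self.labels is None:
            return 0
        return int(self.labels.max()) + 1

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.axis, self.intensity_matrix[i], id=self.ids[i])

    def subset(self, indices: np.ndarray) -> "SpectrumSet":
        """Row subset keeping the axis; labels re-validated, class set must survive."""
        indices = np.asarray(indices, dtype=int)
        labels = None if self.labels is None else self.labels[indices]
        return SpectrumSet(
            self.axis,
            self.intensity_matrix[indices],
            ids=[self.ids[i] for i in indices],
            labels=labels,
            class_names=self.class_names,
        )


def _manifest_path(path: Path) -> Path:
    return path.with_suffix(".labels.csv")


def read_spectrum_table(path: os.PathLike | str, dialect: Optional[str] = None) -> SpectrumSet:
    """Read a spectral table (CSV/TSV, auto-detected) plus optional manifest.

    Parameters
    ----------
    path:
        Spectral table whose first column is the wavenumber axis.
    dialect:
        Field separator; ``None`` sniffs ``\\t`` vs ``,`` from the header line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError("no spectra")
    sep = dialect or ("\t" if "\t" in header else ",")
    frame = pd.read_csv(path, sep=sep)
    if frame.shape[1] < 2 or frame.shape[0] == 0:
        raise ValueError("no spectra")
    axis = pd.to_numeric(frame.iloc[:, 0], errors="coerce").to_numpy()
    if np.any(~np.isfinite(axis)):
        row = int(np.flatnonzero(~np.isfinite(axis))[0])
        raise ValueError(f"non-numeric intensity at ({row}, 0)")
    if np.any(np.diff(axis) <= 0):
        raise ValueError("axis not strictly increasing")
    ids = [str(c) for c in frame.columns[1:]]
    mat = np.empty((len(ids), axis.size))
    for j, col in enumerate(frame.columns[1:]):
        vals = pd.to_numeric(frame[col], errors="coerce").to_numpy()
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            raise ValueError(f"non-numeric intensity at ({int(bad[0])}, {j + 1})")
        mat[j] = vals

    labels = None
    class_names = None
    manifest = _manifest_path(path)
    if manifest.exists():
        mf = pd.read_csv(manifest, dtype=str)
        mapping = dict(zip(mf["id"], mf["class_name"]))
        names = sorted(set(mapping.values()))
        index = {name: i for i, name in enumerate(names)}
        labels = np.array([index[mapping[i]] for i in ids], dtype=int)
        class_names = names
    return SpectrumSet(axis, mat, ids=ids, labels=labels, class_names=class_names)


def write_spectrum_table(sset: SpectrumSet, path: os.PathLike | str, dialect: str = ",") -> Path:
    """Write a spectral table; a label manifest is written alongside if labeled."""
    path = Path(path)
    data = {AXIS_COLUMN: sset.axis}
    for i, sid in enumerate(sset.ids):
        data[sid] = sset.intensity_matrix[i]
    pd.DataFrame(data).to_csv(path, sep=dialect, index=False, float_format="%.12g")
    if sset.labels is not None:
        names = sset.class_names or [f"class{c}" for c in range(sset.n_classes)]
        pd.DataFrame(
            {"id": sset.ids, "class_name": [names[l] for l in sset.labels]}
        ).to_csv(_manifest_path(path), index=False)
    return path


def resample_to_grid(s: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linear interpolation of a spectrum onto a new wavenumber grid.

    The grid must lie within the source axis range; extrapolation is refused.
    """
    grid = np.asarray(grid, dtype=float)
    _validate_axis(grid)
    if grid[0] < s.axis[0] or grid[-1] > s.axis[-1]:
        raise ValueError("extrapolation not permitted")
    return Spectrum(grid, np.interp(grid, s.axis, s.intensities), id=s.id)
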