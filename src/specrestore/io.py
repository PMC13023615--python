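"""Reading and writing spectra tables (delimited text) and cubes (HDF5).

Canonical table layout: a header row whose cells are the wavenumber values,
optionally preceded by a ``sample_label`` column, then one spectrum per row.
Cube container: HDF5 with datasets ``axis`` (L,), ``data`` (H, W, L) and an
optional ``mask`` (H, W).
"""

from __future__ import annotations

import csv
import os

import h5py
import numpy as np

from specrestore.dataset import HyperCube, SpectrumSet, WavenumberAxis

__all__ = [
    "read_spectra_table",
    "write_spectra_table",
    "read_cube",
    "write_cube",
    "SpectraFormatError",
]

LABEL_COLUMN = "sample_label"


class SpectraFormatError(ValueError):
    """Raised when a spectra table or cube file violates the format contract."""


def _sniff_delimiter(path: str | os.PathLike) -> str:
    with open(path, newline="") as fh:
        first = fh.readline()
    for cand in ("\t", ",", ";"):
        if cand in first:
            return cand
    return ","


def read_spectra_table(path: str | os.PathLike, delimiter: str | None = None) -> SpectrumSet:
    """Read a delimited spectra table.

    The header encodes the wavenumber axis; files with a descending axis are
    reversed so the returned axis is always ascending.
    """
    delimiter = delimiter or _sniff_delimiter(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        rows = [row for row in reader if row]
    if len(rows) < 2:
        raise SpectraFormatError(f"{path}: need a header row and at least one spectrum")
    header = rows[0]
    has_label = header[0].strip() == LABEL_COLUMN
    axis_cells = header[1:] if has_label else header
    try:
        axis_values = np.array([float(cell) for cell in axis_cells], dtype=np.float64)
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: non-numeric wavenumber in header ({exc})") from exc
    n_cols = len(header)

    labels: list = []
    data = np.empty((len(rows) - 1, axis_values.size), dtype=np.float64)
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != n_cols:
            raise SpectraFormatError(
                f"{path}: row {r} has {len(row)} cells, expected {n_cols}"
            )
        cells = row
        if has_label:
            labels.append(row[0])
            cells = row[1:]
        for c, cell in enumerate(cells):
            try:
                data[r - 2, c] = float(cell)
            except ValueError as exc:
                raise SpectraFormatError(
                    f"{path}: non-numeric value at row {r}, column {c + 1}: {cell!r}"
                ) from exc

    if axis_values.size >= 2 and axis_values[0] > axis_values[-1]:
        axis_values = axis_values[::-1].copy()
        data = data[:, ::-1].copy()
    axis = WavenumberAxis(axis_values)
    label_arr = np.array(labels) if has_label else None
    return SpectrumSet(axis=axis, intensities=data, sample_labels=label_arr)


def write_spectra_table(
    spectra: SpectrumSet,
    path: str | os.PathLike,
    delimiter: str = ",",
    include_labels: bool = True,
) -> None:
    """Write a SpectrumSet; %.17g cells give lossless float64 round-trips."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        header = ["%.17g" % v for v in spectra.axis.values]
        if include_labels:
            header = [LABEL_COLUMN] + header
        writer.writerow(header)
        for i in range(spectra.n_spectra):
            cells = ["%.17g" % v for v in spectra.intensities[i]]
            if include_labels:
                cells = [str(spectra.sample_labels[i])] + cells
            writer.writerow(cells)


def read_cube(path: str | os.PathLike) -> HyperCube:
    """Read an HDF5 cube container with datasets ``axis``, ``data``, ``mask``."""
    with h5py.File(path, "r") as fh:
        if "axis" not in fh:
            raise SpectraFormatError(f"{path}: missing required dataset 'axis'")
        if "data" not in fh:
            raise SpectraFormatError(f"{path}: missing required dataset 'data'")
        axis_values = np.asarray(fh["axis"], dtype=np.float64)
        data = np.asarray(fh["data"], dtype=np.float64)
        if data.ndim != 3 or data.shape[2] != axis_values.size:
            raise SpectraFormatError(
                f"{path}: data shape {data.shape} incompatible with axis "
                f"length {axis_values.size}"
            )
        mask = np.asarray(fh["mask"], dtype=bool) if "mask" in fh else None
    return HyperCube(axis=WavenumberAxis(axis_values), data=data, mask=mask)


def write_cube(cube: HyperCube, path: str | os.PathLike) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("axis", data=cube.axis.values, dtype=np.float64)
        fh.create_dataset("data", data=cube.data, dtype=np.float64)
        if cube.mask is not None:
            fh.create_dataset("mask", data=cube.mask.astype(bool))
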