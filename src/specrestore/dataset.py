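"""Core data carriers: wavenumber axis, spectrum sets, cubes, paired data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WavenumberAxis", "SpectrumSet", "HyperCube", "PairedDataset"]


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly ascending spectral axis in cm^-1.

    After trimming (e.g. removal of the CO2 window) the axis is no longer
    uniform, so anything that converts index distances to wavenumber
    distances must use :attr:`values` directly; :attr:`sampling_interval`
    is the median step and only valid for locally uniform regions.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1:
            raise ValueError("axis values must be one-dimensional")
        if values.size < 8:
            raise ValueError(f"axis needs at least 8 points, got {values.size}")
        if not np.all(np.isfinite(values)):
            raise ValueError("axis values must be finite")
        diffs = np.diff(values)
        if not np.all(diffs > 0):
            raise ValueError("axis must be strictly ascending")
        object.__setattr__(self, "values", values)

    @property
    def n_points(self) -> int:
        return int(self.values.size)

    @property
    def sampling_interval(self) -> float:
        """Median cm^-1 per index step."""
        return float(np.median(np.diff(self.values)))

    def __len__(self) -> int:
        return self.n_points

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:  # frozen dataclass wants it; cheap digest
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))

    def indices_in(self, lo: float, hi: float) -> np.ndarray:
        """Integer indices whose wavenumber lies in [lo, hi]."""
        if lo > hi:
            lo, hi = hi, lo
        return np.nonzero((self.values >= lo) & (self.values <= hi))[0]


@dataclass
class SpectrumSet:
    """A stack of spectra sharing one axis, labelled by sample (FOV)."""

    axis: WavenumberAxis
    intensities: np.ndarray
    sample_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim == 1:
            arr = arr[None, :]
        if arr.ndim != 2:
            raise ValueError("intensities must be a 2-D array (n, L)")
        if arr.shape[1] != self.axis.n_points:
            raise ValueError(
                f"row length {arr.shape[1]} != axis length {self.axis.n_points}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        self.intensities = arr
        if self.sample_labels is None:
            labels = np.zeros(arr.shape[0], dtype=np.int64)
        else:
            labels = np.asarray(self.sample_labels)
            if labels.shape != (arr.shape[0],):
                raise ValueError("sample_labels must have one entry per spectrum")
        self.sample_labels = labels

    @property
    def n_spectra(self) -> int:
        return int(self.intensities.shape[0])

    def __len__(self) -> int:
        return self.n_spectra

    def select(self, row_mask: np.ndarray) -> "SpectrumSet":
        """Subset rows (boolean mask or integer index array)."""
        return SpectrumSet(
            axis=self.axis,
            intensities=self.intensities[row_mask],
            sample_labels=self.sample_labels[row_mask],
        )

    def with_intensities(self, intensities: np.ndarray) -> "SpectrumSet":
        return SpectrumSet(
            axis=self.axis,
            intensities=intensities,
            sample_labels=self.sample_labels.copy(),
        )


@dataclass
class HyperCube:
    """A hyperspectral image: per-pixel spectra plus an optional foreground mask."""

    axis: WavenumberAxis
    data: np.ndarray  # (height, width, L)
    mask: np.ndarray | None = None  # (height, width) boolean

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError("cube data must be 3-D (height, width, L)")
        if data.shape[2] != self.axis.n_points:
            raise ValueError("cube spectral dimension does not match axis length")
        if not np.all(np.isfinite(data)):
            raise ValueError("cube data must be finite")
        self.data = data
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != data.shape[:2]:
                raise ValueError("mask shape must match cube spatial dimensions")
            self.mask = mask

    @property
    def height(self) -> int:
        return int(self.data.shape[0])

    @property
    def width(self) -> int:
        return int(self.data.shape[1])

    def to_spectra(self, mask: np.ndarray | None = None, label=0) -> SpectrumSet:
        """Flatten (optionally masked) pixels into a SpectrumSet."""
        if mask is None:
            rows = self.data.reshape(-1, self.axis.n_points)
        else:
            rows = self.data[np.asarray(mask, dtype=bool)]
        labels = np.full(rows.shape[0], label)
        return SpectrumSet(axis=self.axis, intensities=rows, sample_labels=labels)


@dataclass
class PairedDataset:
    """Aligned LQ/HQ spectra of the same pixels.

    ``hq_with_baseline`` is the raw high-quality acquisition (target A);
    ``hq_baseline_free`` is its SNIP-corrected counterpart (target B).
    Row i of every member refers to the same pixel.
    """

    lq: SpectrumSet
    hq_with_baseline: SpectrumSet
    hq_baseline_free: SpectrumSet
    scan_counts: np.ndarray

    def __post_init__(self) -> None:
        n = self.lq.n_spectra
        for name in ("hq_with_baseline", "hq_baseline_free"):
            member: SpectrumSet = getattr(self, name)
            if member.axis != self.lq.axis:
                raise ValueError(f"{name} axis differs from lq axis")
            if member.n_spectra != n:
                raise ValueError(f"{name} row count differs from lq")
        counts = np.asarray(self.scan_counts, dtype=np.int64)
        if counts.shape != (n,):
            raise ValueError("scan_counts must have one entry per spectrum")
        if np.any(counts <= 0):
            raise ValueError("scan counts must be positive")
        self.scan_counts = counts

    @property
    def axis(self) -> WavenumberAxis:
        return self.lq.axis

    @property
    def n_spectra(self) -> int:
        return self.lq.n_spectra

    @property
    def fov_labels(self) -> np.ndarray:
        """Unique FOV labels, in first-appearance order."""
        labels = self.lq.sample_labels
        _, first = np.unique(labels, return_index=True)
        return labels[np.sort(first)]

    def select(self, row_mask: np.ndarray) -> "PairedDataset":
        return PairedDataset(
            lq=self.lq.select(row_mask),
            hq_with_baseline=self.hq_with_baseline.select(row_mask),
            hq_baseline_free=self.hq_baseline_free.select(row_mask),
            scan_counts=self.scan_counts[row_mask],
        )

    def split_fov(self, held_out) -> tuple["PairedDataset", "PairedDataset"]:
        """(train, test) split leaving one FOV out."""
        mask = self.lq.sample_labels == held_out
        if not mask.any():
            raise ValueError(f"no spectra with FOV label {held_out!r}")
        if mask.all():
            raise ValueError("cannot hold out the only FOV")
        return self.select(~mask), self.select(mask)
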