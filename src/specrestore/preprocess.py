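"""Preparation and normalization pipeline.

Preparation: Otsu foreground masking on integrated band intensity,
mean-background (atmospheric) subtraction, spectral trimming (detector edges
and the CO2 window).  Preprocessing: per-spectrum SNV followed by global
min-max scaling with train-only bounds; both steps are exactly invertible
given the stored :class:`NormalizationState`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

from specrestore.dataset import HyperCube, SpectrumSet
from specrestore.filters import SNIPParams, snip_baseline

__all__ = [
    "NormalizationState",
    "TrimSpec",
    "otsu_mask",
    "atmospheric_correct",
    "trim",
    "snv",
    "inverse_snv",
    "minmax_fit",
    "minmax_apply",
    "minmax_invert",
    "build_targets",
    "normalize_stage",
]

DEFAULT_BAND_RANGES = ((1000.0, 1800.0), (2800.0, 3000.0))
CO2_RANGE = (2250.0, 2401.0)
DEFAULT_EDGE_BOUNDS = (964.0, 3800.0)


@dataclass
class NormalizationState:
    """Invertibility contract of the normalization pipeline.

    Per-spectrum SNV statistics plus the stage-wise global min-max bounds
    (fit on training rows only).  ``stage`` is "stage1" (baseline retained)
    or "stage2" (baseline-free).
    """

    snv_mean: np.ndarray
    snv_sd: np.ndarray
    stage: str
    global_min: float
    global_max: float

    def __post_init__(self) -> None:
        self.snv_mean = np.asarray(self.snv_mean, dtype=np.float64)
        self.snv_sd = np.asarray(self.snv_sd, dtype=np.float64)
        if self.stage not in ("stage1", "stage2"):
            raise ValueError("stage must be 'stage1' or 'stage2'")
        if np.any(self.snv_sd <= 0):
            raise ValueError("all snv_sd entries must be positive")
        if not self.global_max > self.global_min:
            raise ValueError("global_max must exceed global_min")

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.global_min, self.global_max)

    def to_dict(self) -> dict:
        return {
            "snv_mean": self.snv_mean.tolist(),
            "snv_sd": self.snv_sd.tolist(),
            "stage": self.stage,
            "global_min": self.global_min,
            "global_max": self.global_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationState":
        return cls(
            snv_mean=np.asarray(d["snv_mean"], dtype=np.float64),
            snv_sd=np.asarray(d["snv_sd"], dtype=np.float64),
            stage=d["stage"],
            global_min=float(d["global_min"]),
            global_max=float(d["global_max"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "NormalizationState":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def select(self, row_mask) -> "NormalizationState":
        return NormalizationState(
            snv_mean=self.snv_mean[row_mask],
            snv_sd=self.snv_sd[row_mask],
            stage=self.stage,
            global_min=self.global_min,
            global_max=self.global_max,
        )


@dataclass
class TrimSpec:
    """Which wavenumber ranges to drop.

    ``excluded`` ranges (e.g. the CO2 window) are removed wherever they fall;
    ``edge_bounds`` (lo, hi), if given, drop everything outside [lo, hi].
    """

    excluded: tuple = ()
    edge_bounds: tuple | None = None

    def __post_init__(self) -> None:
        ranges = [tuple(float(v) for v in r) for r in self.excluded]
        for lo, hi in ranges:
            if lo >= hi:
                raise ValueError(f"excluded range ({lo}, {hi}) must have lo < hi")
        for (_, hi1), (lo2, _) in zip(
            sorted(ranges), sorted(ranges)[1:]
        ):
            if lo2 < hi1:
                raise ValueError("excluded ranges must not overlap")
        self.excluded = tuple(ranges)
        if self.edge_bounds is not None:
            lo, hi = (float(v) for v in self.edge_bounds)
            if lo >= hi:
                raise ValueError("edge_bounds must have lo < hi")
            self.edge_bounds = (lo, hi)

    @classmethod
    def standard(cls) -> "TrimSpec":
        """Detector-edge trim plus the CO2 exclusion window."""
        return cls(excluded=(CO2_RANGE,), edge_bounds=DEFAULT_EDGE_BOUNDS)

    def keep_mask(self, axis_values: np.ndarray) -> np.ndarray:
        keep = np.ones(axis_values.size, dtype=bool)
        if self.edge_bounds is not None:
            lo, hi = self.edge_bounds
            keep &= (axis_values >= lo) & (axis_values <= hi)
        for lo, hi in self.excluded:
            keep &= ~((axis_values >= lo) & (axis_values <= hi))
        return keep


# ---------------------------------------------------------------------------
# Preparation
# ---------------------------------------------------------------------------

def integrated_band_image(cube: HyperCube, band_ranges=DEFAULT_BAND_RANGES) -> np.ndarray:
    """Per-pixel summed absorbance over the union of the band ranges."""
    idx = np.unique(
        np.concatenate([cube.axis.indices_in(lo, hi) for lo, hi in band_ranges])
    )
    if idx.size == 0:
        raise ValueError("band ranges contain no axis points")
    return cube.data[:, :, idx].sum(axis=2)


def otsu_mask(cube: HyperCube, band_ranges=DEFAULT_BAND_RANGES) -> np.ndarray:
    """Foreground mask from Otsu's threshold on integrated band intensity."""
    scalars = integrated_band_image(cube, band_ranges)
    if np.ptp(scalars) == 0:
        raise ValueError("integrated intensities are all equal; no Otsu threshold exists")
    threshold = threshold_otsu(scalars)
    return scalars > threshold


def atmospheric_correct(cube: HyperCube, mask: np.ndarray) -> HyperCube:
    """Subtract the mean background (non-sample) spectrum from each foreground
    pixel; background pixels are left untouched."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.data.shape[:2]:
        raise ValueError("mask shape must match cube spatial dimensions")
    n_background = int((~mask).sum())
    if n_background == 0:
        raise ValueError("atmospheric correction needs at least one background pixel")
    background_mean = cube.data[~mask].mean(axis=0)
    data = cube.data.copy()
    data[mask] -= background_mean
    return HyperCube(axis=cube.axis, data=data, mask=mask)


def trim(spectra: SpectrumSet, spec: TrimSpec) -> SpectrumSet:
    """Drop excluded wavenumbers from the axis and every row.

    The returned axis keeps actual wavenumbers, so index->cm^-1 lookups stay
    correct across the (now non-uniform) CO2 gap.
    """
    keep = spec.keep_mask(spectra.axis.values)
    if keep.sum() < 8:
        raise ValueError("trim would leave fewer than 8 axis points")
    from specrestore.dataset import WavenumberAxis

    return SpectrumSet(
        axis=WavenumberAxis(spectra.axis.values[keep]),
        intensities=spectra.intensities[:, keep],
        sample_labels=spectra.sample_labels.copy(),
    )


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def snv(rows: np.ndarray, ddof: int = 1) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standard Normal Variate: per-row centering and scaling.

    Returns (transformed rows, means, sds).  Uses the sample sd (ddof=1) by
    default.  Raises on constant rows, naming the first offending index.
    """
    x = np.asarray(rows, dtype=np.float64)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    means = x.mean(axis=1)
    sds = x.std(axis=1, ddof=ddof)
    bad = np.nonzero(sds <= 0)[0]
    if bad.size:
        raise ValueError(f"constant spectrum at row {bad[0]}: SNV undefined")
    out = (x - means[:, None]) / sds[:, None]
    if single:
        return out[0], means, sds
    return out, means, sds


def inverse_snv(rows: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    x = np.asarray(rows, dtype=np.float64)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    out = x * np.asarray(sds)[:, None] + np.asarray(means)[:, None]
    return out[0] if single else out


def minmax_fit(train_rows: np.ndarray) -> tuple[float, float]:
    """Global min/max over the training rows only (LOSO discipline)."""
    x = np.asarray(train_rows, dtype=np.float64)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError("degenerate min-max bounds: max == min")
    return lo, hi


def minmax_apply(rows: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    """Scale by train-derived bounds. Held-out values may leave [0, 1] and
    are deliberately NOT clipped (clipping would break invertibility)."""
    lo, hi = bounds
    if hi <= lo:
        raise ValueError("degenerate min-max bounds: max <= min")
    return (np.asarray(rows, dtype=np.float64) - lo) / (hi - lo)


def minmax_invert(rows: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    lo, hi = bounds
    return np.asarray(rows, dtype=np.float64) * (hi - lo) + lo


def normalize_stage(
    rows: np.ndarray,
    stage: str,
    bounds: tuple[float, float] | None = None,
) -> tuple[np.ndarray, NormalizationState]:
    """SNV + min-max in one step.

    If ``bounds`` is None the min-max range is fit on these rows (training
    use); otherwise the provided train-derived bounds are applied.
    """
    transformed, means, sds = snv(rows)
    if bounds is None:
        bounds = minmax_fit(transformed)
    out = minmax_apply(transformed, bounds)
    state = NormalizationState(
        snv_mean=means, snv_sd=sds, stage=stage,
        global_min=bounds[0], global_max=bounds[1],
    )
    return out, state


def denormalize_stage(rows: np.ndarray, state: NormalizationState) -> np.ndarray:
    """Exact inverse of :func:`normalize_stage` given its stored state."""
    return inverse_snv(minmax_invert(rows, state.bounds), state.snv_mean, state.snv_sd)


def build_targets(
    hq: SpectrumSet, snip_params: SNIPParams
) -> tuple[SpectrumSet, NormalizationState, SpectrumSet, NormalizationState]:
    """Construct the two supervision targets from HQ spectra.

    Target A keeps the native baseline; target B subtracts the SNIP baseline.
    Each is normalized under its own stage statistics (min-max fit on the
    rows given here, which should be training rows).

    Returns (target_a, state_a, target_b, state_b).
    """
    baseline = snip_baseline(hq.intensities, snip_params)
    corrected = hq.intensities - baseline
    a_rows, state_a = normalize_stage(hq.intensities, "stage1")
    b_rows, state_b = normalize_stage(corrected, "stage2")
    return (
        hq.with_intensities(a_rows),
        state_a,
        hq.with_intensities(b_rows),
        state_b,
    )
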