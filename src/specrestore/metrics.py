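"""Evaluation suite: global fidelity metrics, peak-aware metrics, the
background-window stability metric, difficulty scores, the second-derivative
view, and the leave-one-sample-out (LOSO) evaluation harness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.signal import find_peaks

from specrestore.bridge import bridge_apply
from specrestore.dataset import PairedDataset, WavenumberAxis
from specrestore.filters import SGParams, SNIPParams, sg_filter, traditional_restore, tune_sg
from specrestore.models import (
    FoldArrays,
    TrainConfig,
    UnetConfig,
    prepare_stage_arrays,
    train_cascade,
    train_single,
)

__all__ = [
    "SpectrumMetrics",
    "PeakSet",
    "PeakMatchResult",
    "DifficultyScore",
    "MetricSummary",
    "sam_degrees",
    "global_metrics",
    "detect_peaks",
    "match_peaks",
    "reduction_percent",
    "difficulty_scores",
    "stability_metric",
    "second_derivative_view",
    "loso_evaluate",
    "ProcessedInputBaseline",
    "OracleMethod",
    "TraditionalMethod",
    "SingleUnetMethod",
    "CascadeUnetMethod",
]

PROMINENCE_THRESHOLD = 0.02
MAX_PEAKS = 20
MATCH_TOLERANCE = 4
STABILITY_WINDOW = (2500.0, 2600.0)
INPUT_BASELINE_NAME = "input"


# ---------------------------------------------------------------------------
# Global metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrumMetrics:
    rmse: float
    mae: float
    sam_deg: float
    pcc: float


def sam_degrees(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Spectral angle in degrees between matching rows (vectorized)."""
    a = np.atleast_2d(np.asarray(pred, dtype=np.float64))
    b = np.atleast_2d(np.asarray(target, dtype=np.float64))
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("SAM undefined for zero-norm spectra")
    cosine = np.clip(np.sum(a * b, axis=1) / (na * nb), -1.0, 1.0)
    return np.degrees(np.arccos(cosine))


def global_metrics(pred: np.ndarray, target: np.ndarray) -> SpectrumMetrics:
    """RMSE, MAE, SAM (degrees) and Pearson correlation for one spectrum."""
    p = np.asarray(pred, dtype=np.float64).ravel()
    t = np.asarray(target, dtype=np.float64).ravel()
    if p.shape != t.shape:
        raise ValueError("pred and target must have equal length")
    diff = p - t
    rmse = float(np.sqrt(np.mean(diff * diff)))
    mae = float(np.mean(np.abs(diff)))
    sam = float(sam_degrees(p, t)[0])
    if np.ptp(p) == 0 or np.ptp(t) == 0:
        raise ValueError("PCC undefined for constant spectra")
    pcc = float(np.corrcoef(p, t)[0, 1])
    return SpectrumMetrics(rmse=rmse, mae=mae, sam_deg=sam, pcc=pcc)


def global_metrics_rows(pred: np.ndarray, target: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized per-row metrics for (n, L) arrays."""
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    diff = p - t
    rmse = np.sqrt(np.mean(diff * diff, axis=1))
    mae = np.mean(np.abs(diff), axis=1)
    sam = sam_degrees(p, t)
    pc = p - p.mean(axis=1, keepdims=True)
    tc = t - t.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(pc, axis=1) * np.linalg.norm(tc, axis=1)
    if np.any(denom == 0):
        raise ValueError("PCC undefined for constant spectra")
    pcc = np.sum(pc * tc, axis=1) / denom
    return {"rmse": rmse, "mae": mae, "sam_deg": sam, "pcc": pcc}


def reduction_percent(m_lq: float, m_method: float) -> float:
    """100 * (M_LQ - M_method) / M_LQ relative to the processed input."""
    if m_lq <= 0:
        raise ValueError("baseline metric must be positive")
    return 100.0 * (m_lq - m_method) / m_lq


# ---------------------------------------------------------------------------
# Peak-aware metrics
# ---------------------------------------------------------------------------

@dataclass
class PeakSet:
    """Detected peaks, sorted by prominence (descending), capped at 20."""

    indices: np.ndarray
    wavenumbers: np.ndarray
    heights: np.ndarray
    prominences: np.ndarray

    @property
    def n_peaks(self) -> int:
        return int(self.indices.size)

    def __len__(self) -> int:
        return self.n_peaks


def detect_peaks(
    spectrum: np.ndarray,
    axis: WavenumberAxis,
    prominence: float = PROMINENCE_THRESHOLD,
    max_peaks: int = MAX_PEAKS,
) -> PeakSet:
    """Local maxima with topographic prominence >= the threshold; the top
    ``max_peaks`` by prominence are retained."""
    x = np.asarray(spectrum, dtype=np.float64).ravel()
    idx, props = find_peaks(x, prominence=prominence)
    proms = props["prominences"]
    order = np.argsort(-proms, kind="stable")[:max_peaks]
    idx = idx[order]
    proms = proms[order]
    return PeakSet(
        indices=idx,
        wavenumbers=axis.values[idx],
        heights=x[idx],
        prominences=proms,
    )


@dataclass
class PeakMatchResult:
    """One-to-one matched peak pairs within the index tolerance."""

    target_indices: np.ndarray
    pred_indices: np.ndarray
    e_pos: np.ndarray  # |nu(pred) - nu(target)|, cm^-1
    e_amp: np.ndarray  # signed height bias, pred - target
    n_unmatched_target: int
    n_unmatched_pred: int

    @property
    def n_matched(self) -> int:
        return int(self.target_indices.size)


def match_peaks(
    target: PeakSet,
    pred: PeakSet,
    tolerance: int = MATCH_TOLERANCE,
) -> PeakMatchResult:
    """Optimal one-to-one matching in spectral index space.

    Solved as a minimum-cost assignment that first maximizes the number of
    pairs within +-``tolerance`` samples, then minimizes the total index
    distance; position errors are reported in wavenumber units using the
    actual axis values.
    """
    nt, npred = target.n_peaks, pred.n_peaks
    if nt == 0 or npred == 0:
        return PeakMatchResult(
            target_indices=np.empty(0, dtype=int),
            pred_indices=np.empty(0, dtype=int),
            e_pos=np.empty(0),
            e_amp=np.empty(0),
            n_unmatched_target=nt,
            n_unmatched_pred=npred,
        )
    dist = np.abs(target.indices[:, None] - pred.indices[None, :]).astype(np.float64)
    big = 1e6  # dwarfs any feasible total, so feasible matches are maximized
    cost = np.where(dist <= tolerance, dist, big)
    rows, cols = linear_sum_assignment(cost)
    keep = cost[rows, cols] < big
    rows, cols = rows[keep], cols[keep]
    e_pos = np.abs(pred.wavenumbers[cols] - target.wavenumbers[rows])
    e_amp = pred.heights[cols] - target.heights[rows]
    return PeakMatchResult(
        target_indices=target.indices[rows],
        pred_indices=pred.indices[cols],
        e_pos=e_pos,
        e_amp=e_amp,
        n_unmatched_target=nt - rows.size,
        n_unmatched_pred=npred - cols.size,
    )


# ---------------------------------------------------------------------------
# Difficulty score and stability metric
# ---------------------------------------------------------------------------

@dataclass
class DifficultyScore:
    z_rmse: np.ndarray
    z_sam: np.ndarray
    z_noise: np.ndarray
    z_baseline: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.z_rmse + self.z_sam + self.z_noise + self.z_baseline


def _zscore(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64)
    sd = values.std()  # population sd
    if sd == 0:
        warnings.warn("zero spread in difficulty component; z-scores set to 0",
                      stacklevel=3)
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def difficulty_scores(
    lq_raw: np.ndarray,
    rmse: np.ndarray,
    sam: np.ndarray,
    noise_sg: SGParams = SGParams(11, 3),
    n_low_bins: int = 8,
) -> DifficultyScore:
    """Combined difficulty score S_i = z(RMSE) + z(SAM) + z(noise) + z(baseline).

    Noise proxy: sd of the residual after SG smoothing of the raw LQ
    spectrum.  Baseline proxy: fraction of low-frequency (rFFT bins
    1..n_low_bins) power in the total non-DC power.
    """
    x = np.asarray(lq_raw, dtype=np.float64)
    if x.shape[0] < 2:
        raise ValueError("difficulty scores need at least 2 spectra")
    noise = np.std(x - sg_filter(x, noise_sg), axis=1)
    spectrum_power = np.abs(np.fft.rfft(x - x.mean(axis=1, keepdims=True), axis=1)) ** 2
    non_dc = spectrum_power[:, 1:]
    total = non_dc.sum(axis=1)
    total[total == 0] = 1.0
    low = non_dc[:, :n_low_bins].sum(axis=1)
    baseline_frac = low / total
    return DifficultyScore(
        z_rmse=_zscore(rmse),
        z_sam=_zscore(sam),
        z_noise=_zscore(noise),
        z_baseline=_zscore(baseline_frac),
    )


def stability_metric(
    spectrum: np.ndarray,
    axis: WavenumberAxis,
    window: tuple[float, float] = STABILITY_WINDOW,
) -> float:
    """Band-free background noise: sd of the residual after a straight-line
    fit over the given wavenumber window (default 2500-2600 cm^-1)."""
    idx = axis.indices_in(*window)
    if idx.size < 3:
        raise ValueError("stability window must contain at least 3 axis points")
    nu = axis.values[idx]
    y = np.asarray(spectrum, dtype=np.float64)[idx]
    coeffs = np.polyfit(nu, y, 1)
    residual = y - np.polyval(coeffs, nu)
    return float(residual.std())


def second_derivative_view(
    spectra: np.ndarray, sampling_interval: float = 1.0
) -> np.ndarray:
    """SG second derivative (window 17, poly 3) with respect to wavenumber."""
    return sg_filter(spectra, SGParams(17, 3, 2), sampling_interval)


# ---------------------------------------------------------------------------
# Restoration methods for the LOSO harness
# ---------------------------------------------------------------------------

class RestorationMethod:
    """fit() sees only training data; predict() maps held-out LQ rows into
    the stage-2 evaluation domain."""

    name: str = "method"

    def fit(self, train: PairedDataset, train_arrays: FoldArrays) -> None:
        pass

    def predict(self, test: PairedDataset, test_arrays: FoldArrays) -> np.ndarray:
        raise NotImplementedError


class ProcessedInputBaseline(RestorationMethod):
    """The no-learning reference: raw input through SNIP + stage-2
    normalization (identical domain to the targets)."""

    name = INPUT_BASELINE_NAME

    def __init__(self, snip: SNIPParams):
        self.snip = snip

    def predict(self, test, test_arrays):
        return bridge_apply(
            test_arrays.lq_norm, test_arrays.lq_state, self.snip,
            test_arrays.stage2_state,
        )


class OracleMethod(RestorationMethod):
    """Returns the target itself; pins the 100%-reduction end of the scale."""

    name = "oracle"

    def predict(self, test, test_arrays):
        return test_arrays.target_b.copy()


class TraditionalMethod(RestorationMethod):
    """Supervised-tuned SG smoothing + physics bridge + SNIP."""

    name = "traditional"

    def __init__(self, snip: SNIPParams, sg: SGParams | None = None,
                 n_trials: int = 60, seed: int = 0, lambda_sam: float = 0.1):
        self.snip = snip
        self.sg = sg
        self._fixed_sg = sg is not None
        self.n_trials = n_trials
        self.seed = seed
        self.lambda_sam = lambda_sam

    def fit(self, train, train_arrays):
        if not self._fixed_sg:
            self.sg, _ = tune_sg(train, n_trials=self.n_trials, seed=self.seed,
                                 lambda_sam=self.lambda_sam)

    def predict(self, test, test_arrays):
        return traditional_restore(
            test_arrays.lq_norm, test_arrays.lq_state, self.sg, self.snip,
            test_arrays.stage2_state,
        )


class SingleUnetMethod(RestorationMethod):
    name = "single"

    def __init__(self, unet_cfg: UnetConfig | None = None,
                 train_cfg: TrainConfig | None = None):
        self.unet_cfg = unet_cfg
        self.train_cfg = train_cfg
        self.model = None
        self.history = None

    def fit(self, train, train_arrays):
        self.model, self.history = train_single(
            train_arrays, self.unet_cfg, self.train_cfg
        )

    def predict(self, test, test_arrays):
        return self.model.predict_norm(test_arrays.lq_norm)


class CascadeUnetMethod(RestorationMethod):
    name = "cascade"

    def __init__(self, snip: SNIPParams, unet_cfg: UnetConfig | None = None,
                 train_cfg: TrainConfig | None = None):
        self.snip = snip
        self.unet_cfg = unet_cfg
        self.train_cfg = train_cfg
        self.model = None
        self.history = None

    def fit(self, train, train_arrays):
        self.model, self.history = train_cascade(
            train_arrays, self.unet_cfg, self.train_cfg, snip=self.snip
        )

    def predict(self, test, test_arrays):
        return self.model.predict_norm(test_arrays.lq_norm, test_arrays.lq_state)


# ---------------------------------------------------------------------------
# LOSO harness
# ---------------------------------------------------------------------------

@dataclass
class MetricSummary:
    """Per-spectrum metrics -> per-FOV medians -> mean +- sd across FOVs,
    plus percentage reductions vs the processed-input baseline."""

    fov_medians: dict = field(default_factory=dict)  # [method][metric][fov]
    mean: dict = field(default_factory=dict)  # [method][metric]
    sd: dict = field(default_factory=dict)
    reduction: dict = field(default_factory=dict)  # [method][metric] (on means)
    reduction_per_fov: dict = field(default_factory=dict)  # [method][metric][fov]
    per_spectrum: dict = field(default_factory=dict)  # [method][fov][metric] -> array
    peak_bias: dict = field(default_factory=dict)  # [method] -> quantile summary

    METRICS = ("rmse", "mae", "sam_deg", "pcc")

    def to_records(self) -> list[dict]:
        """Tidy rows: (method, fov, metric, value)."""
        rows = []
        for method, metrics in self.fov_medians.items():
            for metric, fovs in metrics.items():
                for fov, value in fovs.items():
                    rows.append({"method": method, "fov": fov,
                                 "metric": metric, "value": value})
        return rows


def _peak_errors(pred: np.ndarray, target: np.ndarray, axis: WavenumberAxis):
    """Pooled matched-peak position errors and signed height biases."""
    e_pos, e_amp = [], []
    for i in range(pred.shape[0]):
        matched = match_peaks(
            detect_peaks(target[i], axis), detect_peaks(pred[i], axis)
        )
        e_pos.extend(matched.e_pos.tolist())
        e_amp.extend(matched.e_amp.tolist())
    return np.asarray(e_pos), np.asarray(e_amp)


def loso_evaluate(
    methods: list[RestorationMethod],
    data: PairedDataset,
    folds=None,
    peak_metrics: bool = False,
) -> MetricSummary:
    """Leave-one-FOV-out evaluation.

    Per fold: all statistics and model fits use the training FOVs only; the
    held-out FOV is normalized with train-derived bounds and every method is
    scored against its stage-2 baseline-free target.  ``folds`` optionally
    restricts which FOV labels are held out (default: all).  With
    ``peak_metrics`` the matched-peak height-bias quantiles (25th, median,
    75th, IQR) and the median position error are pooled per method.
    """
    labels = data.fov_labels
    if labels.size < 2:
        raise ValueError("LOSO evaluation needs at least 2 FOVs")
    if folds is None:
        folds = list(labels)
    summary = MetricSummary()
    peak_pool: dict[str, list] = {m.name: [] for m in methods}
    for method in methods:
        summary.fov_medians[method.name] = {m: {} for m in MetricSummary.METRICS}
    for fov in folds:
        train, test = data.split_fov(fov)
        train_arrays = prepare_stage_arrays(train)
        test_arrays = prepare_stage_arrays(
            test, train_arrays.stage1_bounds, train_arrays.stage2_bounds
        )
        for method in methods:
            method.fit(train, train_arrays)
            pred = method.predict(test, test_arrays)
            per_row = global_metrics_rows(pred, test_arrays.target_b)
            summary.per_spectrum.setdefault(method.name, {})[fov] = per_row
            for metric in MetricSummary.METRICS:
                summary.fov_medians[method.name][metric][fov] = float(
                    np.median(per_row[metric])
                )
            if peak_metrics:
                peak_pool[method.name].append(
                    _peak_errors(pred, test_arrays.target_b, data.axis)
                )
    if peak_metrics:
        for name, chunks in peak_pool.items():
            e_pos = np.concatenate([c[0] for c in chunks]) if chunks else np.empty(0)
            e_amp = np.concatenate([c[1] for c in chunks]) if chunks else np.empty(0)
            if e_amp.size:
                q25, q50, q75 = np.percentile(e_amp, [25, 50, 75])
            else:
                q25 = q50 = q75 = np.nan
            summary.peak_bias[name] = {
                "p25": float(q25),
                "median": float(q50),
                "p75": float(q75),
                "iqr": float(q75 - q25),
                "e_pos_median": float(np.median(e_pos)) if e_pos.size else np.nan,
                "n_matched": int(e_amp.size),
            }
    for method in methods:
        summary.mean[method.name] = {}
        summary.sd[method.name] = {}
        for metric in MetricSummary.METRICS:
            values = np.array(list(summary.fov_medians[method.name][metric].values()))
            summary.mean[method.name][metric] = float(values.mean())
            summary.sd[method.name][metric] = float(values.std(ddof=1)) if values.size > 1 else 0.0
    baseline = summary.mean.get(INPUT_BASELINE_NAME)
    if baseline is not None:
        for method in methods:
            summary.reduction[method.name] = {}
            summary.reduction_per_fov[method.name] = {}
            for metric in ("rmse", "mae", "sam_deg"):
                summary.reduction[method.name][metric] = reduction_percent(
                    baseline[metric], summary.mean[method.name][metric]
                )
                per_fov = {}
                for fov, base_val in summary.fov_medians[INPUT_BASELINE_NAME][metric].items():
                    per_fov[fov] = reduction_percent(
                        base_val, summary.fov_medians[method.name][metric][fov]
                    )
                summary.reduction_per_fov[method.name][metric] = per_fov
    return summary
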