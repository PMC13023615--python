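"""1D U-Net models: the single end-to-end network and the two-stage cascade
joined by the deterministic physics bridge, plus their training loops,
inference pipeline and checkpoint format.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from specrestore import nn
from specrestore.bridge import bridge_apply
from specrestore.dataset import PairedDataset, SpectrumSet, WavenumberAxis
from specrestore.filters import SNIPParams
from specrestore.nn import Tensor, autodiff as ad
from specrestore.preprocess import (
    NormalizationState,
    minmax_apply,
    minmax_fit,
    snv,
)

__all__ = [
    "UnetConfig",
    "TrainConfig",
    "FoldArrays",
    "prepare_stage_arrays",
    "Unet1D",
    "build_unet",
    "SingleModel",
    "CascadeModel",
    "train_single",
    "train_cascade",
    "infer",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class UnetConfig:
    """Architecture hyperparameters (desk-scale defaults)."""

    depth: int = 3
    base_channels: int = 16
    kernel_size: int = 9
    n_res_blocks: int = 2
    attention_enabled: bool = True
    input_length: int = 256
    precision: str = "float32"  # internal training dtype; I/O stays float64

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if self.input_length < 2 ** self.depth:
            raise ValueError("input_length too short for the requested depth")
        if self.precision not in ("float32", "float64"):
            raise ValueError("precision must be 'float32' or 'float64'")

    @property
    def dtype(self):
        return np.float32 if self.precision == "float32" else np.float64

    @property
    def pad_multiple(self) -> int:
        return 2 ** self.depth

    @property
    def padded_length(self) -> int:
        m = self.pad_multiple
        return ((self.input_length + m - 1) // m) * m

    def to_dict(self) -> dict:
        return {
            "depth": self.depth,
            "base_channels": self.base_channels,
            "kernel_size": self.kernel_size,
            "n_res_blocks": self.n_res_blocks,
            "attention_enabled": self.attention_enabled,
            "input_length": self.input_length,
            "precision": self.precision,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UnetConfig":
        return cls(**d)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol: Adadelta, early stopping on validation loss."""

    learning_rate: float = 0.05
    batch_size: int = 32
    patience: int = 30
    max_epochs: int = 5000
    seed: int = 0
    validation_fraction: float = 0.1
    rho: float = 0.95
    eps: float = 1e-6
    w1: float = 1.0  # stage-1 loss weight (cascade deep supervision)
    w2: float = 1.0  # stage-2 loss weight

    def __post_init__(self) -> None:
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "learning_rate", "batch_size", "patience", "max_epochs", "seed",
            "validation_fraction", "rho", "eps", "w1", "w2")}

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# Stage-domain data preparation
# ---------------------------------------------------------------------------

@dataclass
class FoldArrays:
    """Normalized arrays for one LOSO fold side (train or held-out).

    ``lq_state`` carries the per-row SNV statistics of the LQ rows together
    with the stage-1 bounds; it is the side-channel the bridge needs.
    """

    lq_norm: np.ndarray
    target_a: np.ndarray
    target_b: np.ndarray
    lq_state: NormalizationState
    stage1_bounds: tuple[float, float]
    stage2_bounds: tuple[float, float]
    sample_labels: np.ndarray
    axis: WavenumberAxis

    @property
    def stage2_state(self) -> NormalizationState:
        """Stage-2 state with the LQ rows' statistics as placeholders; only
        its global bounds matter for the outgoing bridge scaling."""
        return NormalizationState(
            snv_mean=self.lq_state.snv_mean,
            snv_sd=self.lq_state.snv_sd,
            stage="stage2",
            global_min=self.stage2_bounds[0],
            global_max=self.stage2_bounds[1],
        )


def prepare_stage_arrays(
    part: PairedDataset,
    stage1_bounds: tuple[float, float] | None = None,
    stage2_bounds: tuple[float, float] | None = None,
) -> FoldArrays:
    """Normalize one fold side into the stage-1/stage-2 spaces.

    With ``stage1_bounds``/``stage2_bounds`` None the min-max ranges are fit
    on these rows (training side); held-out sides must pass the train-derived
    bounds, preserving LOSO discipline.
    """
    lq_snv, lq_mean, lq_sd = snv(part.lq.intensities)
    hq_snv, _, _ = snv(part.hq_with_baseline.intensities)
    if stage1_bounds is None:
        stage1_bounds = minmax_fit(np.vstack([lq_snv, hq_snv]))
    b_snv, _, _ = snv(part.hq_baseline_free.intensities)
    if stage2_bounds is None:
        stage2_bounds = minmax_fit(b_snv)
    lq_state = NormalizationState(
        snv_mean=lq_mean, snv_sd=lq_sd, stage="stage1",
        global_min=stage1_bounds[0], global_max=stage1_bounds[1],
    )
    return FoldArrays(
        lq_norm=minmax_apply(lq_snv, stage1_bounds),
        target_a=minmax_apply(hq_snv, stage1_bounds),
        target_b=minmax_apply(b_snv, stage2_bounds),
        lq_state=lq_state,
        stage1_bounds=stage1_bounds,
        stage2_bounds=stage2_bounds,
        sample_labels=part.lq.sample_labels.copy(),
        axis=part.axis,
    )


# ---------------------------------------------------------------------------
# Architecture
# ---------------------------------------------------------------------------

class Unet1D(nn.Module):
    """Encoder-decoder with residual bottleneck, skip concatenation and
    optional position-wise spectral attention in the decoder."""

    def __init__(self, cfg: UnetConfig, rng: np.random.Generator):
        k = cfg.kernel_size
        ch = cfg.base_channels
        dt = cfg.dtype
        self.cfg = cfg
        self.inc = nn.Sequential(
            nn.Conv1d(1, ch, k, rng=rng, dtype=dt), nn.ReLU(),
            nn.Conv1d(ch, ch, k, rng=rng, dtype=dt), nn.ReLU(),
        )
        downs, enc_blocks = [], []
        chans = ch
        for _ in range(cfg.depth):
            downs.append(nn.Conv1d(chans, chans * 2, k, stride=2, rng=rng, dtype=dt))
            enc_blocks.append(nn.Sequential(
                nn.ReLU(), nn.Conv1d(chans * 2, chans * 2, k, rng=rng, dtype=dt),
                nn.ReLU(),
            ))
            chans *= 2
        self.downs = downs
        self.enc_blocks = enc_blocks
        self.bottleneck = nn.Sequential(
            *[nn.ResidualBlock(chans, k, rng=rng, dtype=dt)
              for _ in range(cfg.n_res_blocks)]
        )
        ups, dec_blocks, attns = [], [], []
        for _ in range(cfg.depth):
            ups.append(nn.Conv1d(chans, chans // 2, k, rng=rng, dtype=dt))
            dec_blocks.append(nn.Sequential(
                nn.Conv1d(chans, chans // 2, k, rng=rng, dtype=dt), nn.ReLU(),
                nn.Conv1d(chans // 2, chans // 2, k, rng=rng, dtype=dt), nn.ReLU(),
            ))
            if cfg.attention_enabled:
                attns.append(nn.SpectralAttention(chans // 2, rng=rng, dtype=dt))
            chans //= 2
        self.ups = ups
        self.dec_blocks = dec_blocks
        self.attns = attns
        self.head = nn.Conv1d(chans, 1, 1, rng=rng, dtype=dt)

    def forward(self, x: Tensor) -> Tensor:
        h = self.inc(x)
        skips = [h]
        for down, block in zip(self.downs, self.enc_blocks):
            h = block(down(h))
            skips.append(h)
        h = self.bottleneck(h)
        for i, (up, dec) in enumerate(zip(self.ups, self.dec_blocks)):
            h = up(ad.upsample2(h))
            skip = skips[-(i + 2)]
            h = dec(ad.concat(skip, h))
            if self.attns:
                h = self.attns[i](h)
        return self.head(h)

    def forward_rows(self, rows: np.ndarray) -> Tensor:
        """(n, L) -> graph output cropped back to (n, 1, L)."""
        rows = np.asarray(rows, dtype=self.cfg.dtype)
        L = rows.shape[1]
        if L != self.cfg.input_length:
            raise ValueError(
                f"input length {L} != configured length {self.cfg.input_length}"
            )
        Lp = self.cfg.padded_length
        if Lp != L:
            rows = np.pad(rows, ((0, 0), (0, Lp - L)), mode="edge")
        out = self.forward(Tensor(rows[:, None, :]))
        if Lp != L:
            out = ad.crop1d(out, 0, L)
        return out

    def predict(self, rows: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Forward pass without gradient bookkeeping; batch-size independent."""
        rows = np.asarray(rows)
        outs = []
        for start in range(0, rows.shape[0], batch_size):
            out = self.forward_rows(rows[start : start + batch_size])
            outs.append(out.data[:, 0, :].astype(np.float64))
        return np.vstack(outs)


def build_unet(cfg: UnetConfig, seed: int = 0) -> Unet1D:
    """Construct an untrained network with seeded He initialization."""
    return Unet1D(cfg, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# Trained model containers
# ---------------------------------------------------------------------------

@dataclass
class SingleModel:
    """End-to-end network: stage-1 normalized LQ -> stage-2 target."""

    unet: Unet1D
    stage1_bounds: tuple[float, float]
    stage2_bounds: tuple[float, float]
    axis: WavenumberAxis
    snip: SNIPParams | None = None

    kind = "single"

    def predict_norm(self, lq_norm: np.ndarray, lq_state=None) -> np.ndarray:
        return self.unet.predict(lq_norm)

    def predict_rows(self, lq_raw: np.ndarray) -> np.ndarray:
        lq_snv, _, _ = snv(lq_raw)
        return self.predict_norm(minmax_apply(lq_snv, self.stage1_bounds))


@dataclass
class CascadeModel:
    """Denoiser -> physics bridge -> refiner; the bridge stays active at
    inference."""

    unet1: Unet1D
    unet2: Unet1D
    snip: SNIPParams
    stage1_bounds: tuple[float, float]
    stage2_bounds: tuple[float, float]
    axis: WavenumberAxis

    kind = "cascade"

    def _stage2_state(self) -> NormalizationState:
        return NormalizationState(
            snv_mean=np.zeros(1), snv_sd=np.ones(1), stage="stage2",
            global_min=self.stage2_bounds[0], global_max=self.stage2_bounds[1],
        )

    def predict_norm(
        self,
        lq_norm: np.ndarray,
        lq_state: NormalizationState,
        skip_bridge: bool = False,
    ) -> np.ndarray:
        out1 = self.unet1.predict(lq_norm)
        if skip_bridge:
            bridged = out1
        else:
            bridged = bridge_apply(out1, lq_state, self.snip, self._stage2_state())
        return self.unet2.predict(bridged)

    def stage1_prediction(self, lq_norm: np.ndarray) -> np.ndarray:
        return self.unet1.predict(lq_norm)

    def predict_rows(self, lq_raw: np.ndarray, skip_bridge: bool = False) -> np.ndarray:
        lq_snv, mean, sd = snv(lq_raw)
        state = NormalizationState(
            snv_mean=mean, snv_sd=sd, stage="stage1",
            global_min=self.stage1_bounds[0], global_max=self.stage1_bounds[1],
        )
        lq_norm = minmax_apply(lq_snv, self.stage1_bounds)
        return self.predict_norm(lq_norm, state, skip_bridge=skip_bridge)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _check_finite_loss(value: float, stage: str, epoch: int) -> None:
    if not np.isfinite(value):
        raise RuntimeError(
            f"non-finite {stage} loss ({value}) at epoch {epoch}; "
            "try a smaller learning rate or check input normalization"
        )


def _split_validation(n: int, fraction: float, rng: np.random.Generator):
    perm = rng.permutation(n)
    n_val = int(round(n * fraction))
    if fraction > 0 and n_val == 0:
        n_val = 1
    return perm[n_val:], perm[:n_val]


def _mse_np(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a - b) ** 2))


def train_single(
    data: PairedDataset | FoldArrays,
    unet_cfg: UnetConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> tuple[SingleModel, dict]:
    """Train the end-to-end network on stage-1 LQ -> stage-2 target-B pairs.

    Early-stops on validation MSE and restores the best-validation weights.
    Returns (model, history).
    """
    arrays = data if isinstance(data, FoldArrays) else prepare_stage_arrays(data)
    train_cfg = train_cfg or TrainConfig()
    if unet_cfg is None:
        unet_cfg = UnetConfig(input_length=arrays.lq_norm.shape[1])
    model = build_unet(unet_cfg, seed=train_cfg.seed)
    opt = nn.Adadelta(model.parameters(), learning_rate=train_cfg.learning_rate,
                      rho=train_cfg.rho, eps=train_cfg.eps)
    rng = np.random.default_rng(train_cfg.seed)
    x, y = arrays.lq_norm, arrays.target_b
    train_idx, val_idx = _split_validation(x.shape[0], train_cfg.validation_fraction, rng)

    best_val = np.inf
    best_state = None
    best_epoch = -1
    waited = 0
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(train_cfg.max_epochs):
        perm = rng.permutation(train_idx.size)
        epoch_losses = []
        for start in range(0, train_idx.size, train_cfg.batch_size):
            idx = train_idx[perm[start : start + train_cfg.batch_size]]
            out = model.forward_rows(x[idx])
            loss = ad.mse_loss(out, y[idx][:, None, :])
            _check_finite_loss(float(loss.data), "training", epoch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        train_loss = float(np.mean(epoch_losses))
        if val_idx.size:
            val_loss = _mse_np(model.predict(x[val_idx]), y[val_idx])
        else:
            val_loss = train_loss
        _check_finite_loss(val_loss, "validation", epoch)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = [p.copy() for p in model.state_arrays()]
            best_epoch = epoch
            waited = 0
        else:
            waited += 1
            if waited > train_cfg.patience:
                break
    if best_state is not None:
        model.load_state_arrays(best_state)
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = float(best_val)
    return (
        SingleModel(
            unet=model,
            stage1_bounds=arrays.stage1_bounds,
            stage2_bounds=arrays.stage2_bounds,
            axis=arrays.axis,
        ),
        history,
    )


def train_cascade(
    data: PairedDataset | FoldArrays,
    unet_cfg: UnetConfig | None = None,
    train_cfg: TrainConfig | None = None,
    snip: SNIPParams | None = None,
) -> tuple[CascadeModel, dict]:
    """Train the two-stage cascade with deep supervision.

    Loss = w1 * MSE(unet1(lq), target_a) + w2 * MSE(unet2(bridge(unet1(lq))),
    target_b).  The bridge is stop-gradient: unet1 receives gradients only
    from the stage-1 term, unet2 only from the stage-2 term.  Early stopping
    monitors the combined validation loss; best-validation weights of both
    networks are restored.
    """
    arrays = data if isinstance(data, FoldArrays) else prepare_stage_arrays(data)
    train_cfg = train_cfg or TrainConfig()
    if unet_cfg is None:
        unet_cfg = UnetConfig(input_length=arrays.lq_norm.shape[1])
    if snip is None:
        snip = SNIPParams(max_half_window=max(2, arrays.lq_norm.shape[1] // 8))
    unet1 = build_unet(unet_cfg, seed=train_cfg.seed)
    unet2 = build_unet(unet_cfg, seed=train_cfg.seed + 1)
    opt1 = nn.Adadelta(unet1.parameters(), learning_rate=train_cfg.learning_rate,
                       rho=train_cfg.rho, eps=train_cfg.eps)
    opt2 = nn.Adadelta(unet2.parameters(), learning_rate=train_cfg.learning_rate,
                       rho=train_cfg.rho, eps=train_cfg.eps)
    rng = np.random.default_rng(train_cfg.seed)
    x, ya, yb = arrays.lq_norm, arrays.target_a, arrays.target_b
    state = arrays.lq_state
    stage2_state = arrays.stage2_state
    train_idx, val_idx = _split_validation(x.shape[0], train_cfg.validation_fraction, rng)

    model = CascadeModel(
        unet1=unet1, unet2=unet2, snip=snip,
        stage1_bounds=arrays.stage1_bounds,
        stage2_bounds=arrays.stage2_bounds,
        axis=arrays.axis,
    )

    def combined_val_loss() -> float:
        out1 = unet1.predict(x[val_idx])
        l1 = _mse_np(out1, ya[val_idx])
        bridged = bridge_apply(out1, state.select(val_idx), snip, stage2_state)
        l2 = _mse_np(unet2.predict(bridged), yb[val_idx])
        return train_cfg.w1 * l1 + train_cfg.w2 * l2

    best_val = np.inf
    best_state = None
    best_epoch = -1
    waited = 0
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(train_cfg.max_epochs):
        perm = rng.permutation(train_idx.size)
        epoch_losses = []
        for start in range(0, train_idx.size, train_cfg.batch_size):
            idx = train_idx[perm[start : start + train_cfg.batch_size]]
            # stage 1: denoiser against target A
            out1 = unet1.forward_rows(x[idx])
            loss1 = ad.mse_loss(out1, ya[idx][:, None, :])
            _check_finite_loss(float(loss1.data), "stage-1", epoch)
            if train_cfg.w1 > 0:
                opt1.zero_grad()
                loss1.backward()
                opt1.step()
            # bridge (stop-gradient: uses the numpy output, not the graph)
            bridged = bridge_apply(out1.data[:, 0, :], state.select(idx), snip,
                                   stage2_state)
            # stage 2: refiner against target B
            out2 = unet2.forward_rows(bridged)
            loss2 = ad.mse_loss(out2, yb[idx][:, None, :])
            _check_finite_loss(float(loss2.data), "stage-2", epoch)
            if train_cfg.w2 > 0:
                opt2.zero_grad()
                loss2.backward()
                opt2.step()
            epoch_losses.append(
                train_cfg.w1 * float(loss1.data) + train_cfg.w2 * float(loss2.data)
            )
        train_loss = float(np.mean(epoch_losses))
        val_loss = combined_val_loss() if val_idx.size else train_loss
        _check_finite_loss(val_loss, "validation", epoch)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = (
                [p.copy() for p in unet1.state_arrays()],
                [p.copy() for p in unet2.state_arrays()],
            )
            best_epoch = epoch
            waited = 0
        else:
            waited += 1
            if waited > train_cfg.patience:
                break
    if best_state is not None:
        unet1.load_state_arrays(best_state[0])
        unet2.load_state_arrays(best_state[1])
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = float(best_val)
    return model, history


# ---------------------------------------------------------------------------
# Inference and checkpointing
# ---------------------------------------------------------------------------

def infer(model: SingleModel | CascadeModel, lq_raw: SpectrumSet) -> SpectrumSet:
    """Full pipeline on raw LQ spectra -> stage-2 normalized restorations."""
    if lq_raw.axis != model.axis:
        raise ValueError("input axis differs from the model's training axis")
    restored = model.predict_rows(lq_raw.intensities)
    return lq_raw.with_intensities(restored)


def save_model(model: SingleModel | CascadeModel, directory: str | os.PathLike) -> None:
    os.makedirs(directory, exist_ok=True)
    manifest: dict = {
        "kind": model.kind,
        "stage1_bounds": list(model.stage1_bounds),
        "stage2_bounds": list(model.stage2_bounds),
        "axis": model.axis.values.tolist(),
        "version": 1,
    }
    weights: dict[str, np.ndarray] = {}
    if model.kind == "single":
        manifest["unet_cfg"] = model.unet.cfg.to_dict()
        manifest["snip"] = model.snip.to_dict() if model.snip else None
        for i, arr in enumerate(model.unet.state_arrays()):
            weights[f"unet_{i}"] = arr
    else:
        manifest["unet1_cfg"] = model.unet1.cfg.to_dict()
        manifest["unet2_cfg"] = model.unet2.cfg.to_dict()
        manifest["snip"] = model.snip.to_dict()
        for i, arr in enumerate(model.unet1.state_arrays()):
            weights[f"unet1_{i}"] = arr
        for i, arr in enumerate(model.unet2.state_arrays()):
            weights[f"unet2_{i}"] = arr
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    np.savez(os.path.join(directory, "weights.npz"), **weights)


def load_model(directory: str | os.PathLike) -> SingleModel | CascadeModel:
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    weights = np.load(os.path.join(directory, "weights.npz"))
    axis = WavenumberAxis(np.asarray(manifest["axis"], dtype=np.float64))
    s1 = tuple(manifest["stage1_bounds"])
    s2 = tuple(manifest["stage2_bounds"])
    if manifest["kind"] == "single":
        unet = build_unet(UnetConfig.from_dict(manifest["unet_cfg"]))
        n = len(unet.parameters())
        unet.load_state_arrays([weights[f"unet_{i}"] for i in range(n)])
        snip = SNIPParams.from_dict(manifest["snip"]) if manifest["snip"] else None
        return SingleModel(unet=unet, stage1_bounds=s1, stage2_bounds=s2,
                           axis=axis, snip=snip)
    unet1 = build_unet(UnetConfig.from_dict(manifest["unet1_cfg"]))
    unet2 = build_unet(UnetConfig.from_dict(manifest["unet2_cfg"]))
    unet1.load_state_arrays([weights[f"unet1_{i}"] for i in range(len(unet1.parameters()))])
    unet2.load_state_arrays([weights[f"unet2_{i}"] for i in range(len(unet2.parameters()))])
    return CascadeModel(
        unet1=unet1, unet2=unet2,
        snip=SNIPParams.from_dict(manifest["snip"]),
        stage1_bounds=s1, stage2_bounds=s2, axis=axis,
    )
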