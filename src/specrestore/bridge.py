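"""The physics bridge: a deterministic, parameter-free layer between the two
networks of the cascade.

It maps stage-1-normalized spectra back to physical absorbance using the
input's stored statistics (inverse min-max, then inverse SNV), subtracts the
SNIP baseline there — where the clipping geometry is meaningful — and
re-normalizes the baseline-free result into the stage-2 evaluation space.
The layer has zero trainable parameters and is treated as a constant with
respect to its input during backpropagation (stop-gradient): the first
network learns only from its own stage-1 loss, the second only from the
stage-2 loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from specrestore.filters import SNIPParams, snip_baseline
from specrestore.preprocess import (
    NormalizationState,
    inverse_snv,
    minmax_apply,
    minmax_invert,
    snv,
)

__all__ = ["BridgeConfig", "bridge", "bridge_apply", "bridge_active_at_inference"]


@dataclass
class BridgeConfig:
    snip: SNIPParams
    stage1_state: NormalizationState
    stage2_state: NormalizationState

    def __post_init__(self) -> None:
        if self.stage1_state.stage != "stage1":
            raise ValueError("stage1_state must carry stage label 'stage1'")
        if self.stage2_state.stage != "stage2":
            raise ValueError("stage2_state must carry stage label 'stage2'")

    @property
    def n_parameters(self) -> int:
        """The bridge is non-learnable by construction."""
        return 0

    def to_dict(self) -> dict:
        return {
            "snip": self.snip.to_dict(),
            "stage1_state": self.stage1_state.to_dict(),
            "stage2_state": self.stage2_state.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BridgeConfig":
        return cls(
            snip=SNIPParams.from_dict(d["snip"]),
            stage1_state=NormalizationState.from_dict(d["stage1_state"]),
            stage2_state=NormalizationState.from_dict(d["stage2_state"]),
        )


def bridge_apply(
    rows: np.ndarray,
    stage1_state: NormalizationState,
    snip: SNIPParams,
    stage2_state: NormalizationState,
) -> np.ndarray:
    """Core bridge map on a (n, L) stage-1-normalized batch.

    ``stage1_state`` must hold the per-row SNV statistics of exactly these
    rows (they travel with the batch as side-channel data); only the global
    bounds of ``stage2_state`` are used for the outgoing scaling — the
    baseline-free rows receive fresh per-row SNV statistics.
    """
    x = np.asarray(rows, dtype=np.float64)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if stage1_state.snv_mean.shape[0] != x.shape[0]:
        raise ValueError(
            f"stage-1 state carries {stage1_state.snv_mean.shape[0]} per-spectrum "
            f"statistics but the batch has {x.shape[0]} rows"
        )
    absorbance = inverse_snv(
        minmax_invert(x, stage1_state.bounds),
        stage1_state.snv_mean,
        stage1_state.snv_sd,
    )
    corrected = absorbance - snip_baseline(absorbance, snip)
    renorm, _, _ = snv(corrected)
    out = minmax_apply(renorm, stage2_state.bounds)
    return out[0] if single else out


def bridge(rows: np.ndarray, cfg: BridgeConfig) -> np.ndarray:
    """Apply the bridge using a bundled :class:`BridgeConfig`."""
    return bridge_apply(rows, cfg.stage1_state, cfg.snip, cfg.stage2_state)


def bridge_active_at_inference(
    model,
    lq_raw,
    rtol: float = 1e-9,
) -> None:
    """Assert the bridge actually participates in the inference graph.

    Runs the cascade on raw LQ spectra with and without its bridge and
    raises AssertionError if the two paths agree — which would mean the
    bridge had silently become a no-op/bypass.
    """
    with_bridge = model.predict_rows(lq_raw)
    without = model.predict_rows(lq_raw, skip_bridge=True)
    if np.allclose(with_bridge, without, rtol=rtol, atol=1e-9):
        raise AssertionError(
            "physics bridge appears inactive: inference with and without the "
            "bridge produced identical outputs"
        )
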