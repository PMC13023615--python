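# specrestore

Physics-informed denoising and baseline correction for low-scan-count FTIR
spectra. The package restores high-quality absorbance spectra from fast 1- or
8-scan acquisitions and benchmarks three restoration strategies:

- **Traditional**: supervised-tuned Savitzky–Golay smoothing followed by SNIP
  baseline subtraction in the physical absorbance domain.
- **Single U-Net**: a 1D encoder–decoder (residual bottleneck, spectral
  attention, skip connections) mapping normalized noisy inputs directly to
  baseline-free targets.
- **Cascade U-Net**: two networks joined by a deterministic, invertible
  **physics bridge** — inverse min–max + inverse SNV using the input's stored
  statistics, SNIP baseline subtraction in absorbance space, and stage-2
  re-normalization. The bridge has zero trainable parameters, is stop-gradient
  during training (deep supervision: each network learns from its own loss),
  and stays active at inference.

Evaluation follows a leave-one-sample-out (LOSO) protocol over imaging fields
of view, with global metrics (RMSE, MAE, SAM in degrees, PCC), peak-aware
metrics (prominence-based detection, optimal one-to-one matching within ±4
samples, position/height bias), a band-free background-window stability
metric, and a combined difficulty score.

Everything runs on synthetic paired low-/high-quality spectra produced by the
built-in generator (band structure in the fingerprint, Amide I/II and CHx
regions; polynomial + oscillatory baseline drift; shared water-vapor lines;
multiplicative scatter; white noise scaling as σ₀/√scans). No external data
is required.

The neural-network layer is a small, self-contained numpy reverse-mode
autodiff engine (`specrestore.nn`) with 1D convolutions and an Adadelta
optimizer; gradients are verified against finite differences in the tests.

## Tests

```bash
python -m pytest tests/
```

The suite includes `tests/test_acceptance.py` (noise-averaging ratios,
invertibility, SNIP/SG correctness, metric analytics, exhaustive-grid SG
tuning, and an end-to-end LOSO ordering run that trains desk-scale networks —
a few minutes on one CPU).

## CLI

```bash
specrestore simulate   --out runs/sim --n-fov 4 --pixels-per-fov 64 --seed 1
specrestore tune-sg    --data runs/sim --n-trials 60 --out runs/sg.json
specrestore train      --data runs/sim --method cascade --out runs/model
specrestore infer      --model runs/model --input runs/sim/lq.csv --out runs/restored.csv
specrestore evaluate   --data runs/sim --methods input,oracle,traditional,single,cascade --out runs/eval
specrestore report     --results runs/eval
specrestore run        --config config.yaml --out runs/full   # end-to-end pipeline
```

Spectra tables are delimited text (header row = wavenumber axis, optional
leading `sample_label` column); hyperspectral cubes are HDF5 containers with
datasets `axis` (L,), `data` (H, W, L) and optional `mask` (H, W).

## Layout

```
src/specrestore/
  dataset.py     axis / spectrum-set / cube / paired-dataset types
  io.py          delimited-text tables and HDF5 cubes
  synthetic.py   paired LQ/HQ spectra, cubes, noise-ratio simulation
  preprocess.py  Otsu masking, atmospheric correction, trimming, SNV, min–max
  filters.py     SNIP, Savitzky–Golay, supervised SG search
  bridge.py      the deterministic physics bridge
  nn/            numpy autodiff, conv layers, Adadelta
  models.py      U-Net architectures, training loops, checkpoints
  metrics.py     metric suite + LOSO evaluation harness
  cli.py         command-line workflow
```
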