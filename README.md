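# eegscreen

An EEG-based dyslexia-screening pipeline: multichannel EDF recordings are
denoised, cut into 10-second epochs, decomposed into the classic EEG bands
with a level-6 db4 discrete wavelet transform, summarized by ten statistical
descriptors per band and channel, ranked with mRMR and ReliefF, and
classified with shallow/deep neural networks and classical baselines under
segment-level stratified 10-fold cross-validation. A synthetic task-evoked
EEG cohort generator stands in for clinical data.

## Layout

| Module | Role |
|---|---|
| `eegscreen.io_edf` | Classic EDF read/write, canonical 16-channel selection |
| `eegscreen.preprocess` | Band-pass (0.1–70 Hz), moving average (window 9), automated ICA artifact rejection |
| `eegscreen.decomposition` | 10-s epoching, db4 level-6 DWT (`_dwt`), band mapping (literal / frequency-consistent) |
| `eegscreen.features` | Ten descriptors per coefficient vector; epoch × feature matrix (160/640/800 columns) |
| `eegscreen.selection` | Plug-in MI, greedy mRMR, ReliefF (both from scratch), Top-k cuts |
| `eegscreen.evaluation` | Neural specs (numpy `_nn.MLPNet`), classical registry, metrics, stratified CV, benchmark sweeps |
| `eegscreen.band_stats` | Per-feature Welch tests, Cohen's d, Benjamini–Hochberg FDR |
| `eegscreen.synthetic` | Deterministic synthetic cohort: band-limited oscillations, 1/f noise, blink/EMG transients, injectable class effects |
| `eegscreen.cli` / `config` | `eegscreen` command, strict YAML config, seed fan-out |

## CLI

```bash
# synthetic cohort -> EDF files + manifest.csv
eegscreen simulate --out data/ --config config.yaml

# EDFs -> epoch x feature CSV
eegscreen extract --in-dir data/ --out features.csv --config config.yaml

# feature ranking (mrmr | relieff), Top-k
eegscreen select --features features.csv --method relieff --top-k 20 --out ranking.csv

# cross-validated classification (dnn | snn | classical:<name>)
eegscreen evaluate --features features.csv --model dnn --folds 10 --seed 0 --out report.json

# effect sizes + FDR table
eegscreen stats --features features.csv --out stats.csv

# everything into one run directory
eegscreen all --out-dir runs/r1 --config config.yaml
```

A config file is optional; every key has a default. Unknown keys are
rejected. Example:

```yaml
seed: 0
cohort: {n_dyslexic: 26, n_control: 25, duration_s: 340.0}
decomposition: {mapping_mode: table3_literal, bands: 4band}
selection: {method: relieff, top_k: 20}
evaluation: {model: dnn, n_folds: 10}
```

## Notes

- Band mapping has two modes: `table3_literal` (the conventional printed
  level→band table) and `frequency_consistent` (assigns coefficient sets by
  actual Hz overlap at the recording's sampling rate). At 256 Hz the two
  differ; both are provided and logged.
- Cross-validation is stratified at the epoch level by default, which lets
  correlated epochs of one subject span train and test folds; `--grouped`
  switches to subject-wise folds to expose that gap.
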