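# eegproto

Protocol-aware windowed classification pipelines for five-channel wearable
EEG (AF3, T7, Pz, T8, AF4 at 128 Hz), built around two evaluation regimes
for binary session labels (0 = LIE, 1 = TRUTH):

* **Subject-dependent OSW** — one stratified 80/10/10 split over session
  ids, heavily overlapping 2.0 s / 0.25 s windows, a hybrid residual
  temporal CNN (squeeze-and-excitation + attention pooling) fusing raw
  windows with 175-dim db4 DWT statistics and a 167-dim spectral–statistical
  feature vector, and a Youden-J threshold calibrated on validation windows.
* **Cross-subject** — subject-grouped 5-fold cross-validation on 3.0 s /
  0.25 s windows with a compact residual SE CNN, out-of-fold window
  probabilities averaged into per-session scores, and a single global
  Youden-J threshold calibrated on the pooled out-of-fold session scores.

Everything runs on CPU with numpy only: the package ships its own small
reverse-mode autodiff engine (`eegproto.nn`) and a periodized db4
DWT/wavelet-packet implementation (`eegproto.wavelets`), so no deep-learning
framework or wavelet library is required.

## Layout

| Module | Role |
| --- | --- |
| `eegproto.synth` | synthetic five-channel datasets with a tunable class effect and known ground truth |
| `eegproto.io` | per-session CSV + manifest reading/writing, dataset diagnostics |
| `eegproto.preprocess` | zero-phase 50 Hz notch + 1–45 Hz Butterworth band-pass, wavelet-packet soft-threshold artifact reduction |
| `eegproto.windowing` | sliding-window segmentation, per-window channel z-scoring |
| `eegproto.features` | Welch band powers, Hjorth parameters, DESC table (65 columns), DWT-175, FEATS-167, Cliff's delta, quartile summaries |
| `eegproto.nn` | autodiff engine, ResNet-SE and Res-TCN-SE-Attention architectures (plus structural ablation variants), focal/BCE losses, MixUp, Adam, training loop |
| `eegproto.protocol` | splits, ROC/Youden/Wilson/binomial statistics, session aggregation, the two experiment drivers, ablation harness |
| `eegproto.cli` | `eegproto` command-line interface |

## CLI

```bash
# 54-session synthetic dataset (27 subjects x 2 sessions, 75 s each)
eegproto simulate --out data/raw --subjects 27 --class-effect 0.5 --seed 1

# conditioning chain: notch -> band-pass -> artifact reduction
eegproto preprocess --manifest data/raw/manifest.csv --out data/clean

# descriptive band-power summary (quartiles, IQR, Cliff's delta)
eegproto run describe --manifest data/clean/manifest.csv --out out/describe

# the two protocols (use --tiny --epochs N for CPU smoke runs)
eegproto run osw           --manifest data/clean/manifest.csv --out out/osw --tiny --epochs 5
eegproto run cross_subject --manifest data/clean/manifest.csv --out out/xs  --tiny --epochs 2
eegproto run ablation      --manifest data/clean/manifest.csv --out out/abl --tiny --epochs 3

# feature tables and confusion-count reports
eegproto featurize --manifest data/clean/manifest.csv --out out/feat --stream feats
eegproto report --counts 20 7 11 16
```

Every run echoes its configuration (`run_config.yaml`) and seed into the
output directory; identical seeds reproduce identical artifacts on CPU.

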