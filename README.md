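# bppvnet

Multimodal diagnosis of benign paroxysmal positional vertigo (BPPV) from
eye-movement video plus head-position information, with a fully synthetic
videonystagmography simulator so the whole pipeline is exercisable
without clinical data.

The package implements:

- **simulate** — synthetic examination generator: per-case eye-movement
  segments (black background, single rendered eye, sawtooth nystagmus
  with class- and position-dependent onset/direction), six diagnostic
  classes, Fig-2-shaped observation durations, chair-angle pairs per
  segment, PNG/CSV dataset export.
- **preprocess** — clinical-protocol standardization: drop segments
  < 10 s, keep the six longest positions, truncate/zero-pad to the 48 s
  window (1200 frames @ 25 fps), subsample 1-in-4 to 300 frames per
  clip, 1800 frames per case, plus normalized head-position vectors.
- **backbone** — temporal-difference video network: frame-difference
  short-term module with 4x1x1 temporal-stride-4 3D convolution, and a
  big-kernel (13x13 / 7x7) long-term difference-attention module with a
  3x3 baseline mode for ablations.
- **headpos** — head-position autoencoder (3 FC encoder / 2 FC decoder)
  with gaze-coordinate regression pre-training and the reconstruction
  penalty used in joint training.
- **fusion** — scaled dot-product attention, the cross -> self -> cross
  attention stack, and all ablation fusion variants (cross, self,
  concatenation, trainable weighted sum, weighted sum + self-attention,
  unimodal passthrough), followed by a single-FC classifier.
- **train_eval** — joint loss (cross entropy + reconstruction penalty),
  stratified 8:2 splitting, Adam with half-cosine ("sine decay")
  learning-rate schedule, per-class one-vs-rest accuracy / precision /
  sensitivity / specificity, and the 10-configuration ablation driver.

All networks run on a small NumPy reverse-mode autodiff engine
(`bppvnet.nn`) — the environment provides no deep-learning framework.
Large-kernel convolutions are evaluated in frequency space via
`scipy.fft`; correctness is pinned against `scipy.signal` and finite
differences in the test suite.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (preprocessing
exactness, pre-training MAE, equation-level oracles, synthetic class
recovery with the fusion/kernel ablation orderings, and the pre-training
convergence comparison). The training-based criteria run a reduced
`tiny` preset (8x8 frames, d=16) sized for a single CPU; the 64x64
`desk` preset is available via `bppvnet.presets`.

## CLI

```bash
bppvnet simulate --n-per-class 2 --out-dir ds/            # synthetic dataset
bppvnet simulate --preset paper --no-frames --out-dir ds/ # 518-case manifest
bppvnet preprocess --dataset-dir ds/ --out-dir std/       # 6x300-frame inputs
bppvnet pretrain-encoder --curve-out curve.csv            # gaze pre-training
bppvnet train --preset tiny --seed 0                      # train + metrics
bppvnet evaluate --preset tiny                            # per-class metrics
bppvnet ablate --preset tiny --n-runs 5 --out ablation.csv
```

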