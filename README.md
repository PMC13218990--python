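# freqvit

A Fourier-guided attention encoder for histopathology-style image tiles, with
a transferable-feature evaluation protocol. The encoder is a pre-norm vision
transformer whose blocks refine the patch tokens in the frequency domain
before self-attention: the layer-normalized patch tokens are re-laid-out on
their 2-D patch grid, transformed with a per-channel 2-D FFT, recalibrated by
a squeeze-and-excitation sigmoid gate computed from the spectrum's magnitude
summary, inverse-transformed, and added back residually. The final class
token doubles as an exportable feature vector that is scored by seven shallow
downstream classifiers (LR, kNN k=9, Gaussian NB, RF with 10 trees, linear
SVM, RBF SVM, two-hidden-layer MLP) against five handcrafted descriptor
baselines (colour histogram, luminance histogram, HOG, LBP, GLCM).

Everything runs on CPU: the network and its backward passes are implemented
in NumPy, so no deep-learning framework is required. A built-in synthetic
generator produces two-class H&E-like texture tiles whose class signal lives
partly in the spatial frequency spectrum, making the whole pipeline testable
offline.

## Ablation variants

| variant | FFT/IFFT branch | SE gate |
|---------|-----------------|---------|
| B0      | off             | off     |
| B1      | on              | off     |
| B2      | off (spatial gate) | on   |
| full    | on              | on      |

## CLI

```sh
# generate a synthetic dataset (PNG tree + labels.csv)
freqvit synth --out data/ --seed 0 --n-per-class 100

# train the encoder (YAML config for model/train sections)
freqvit train --data data/ --config run.yaml --out run/ --seed 0

# export features from a checkpoint, or from a handcrafted family
freqvit extract --data data/ --checkpoint run/checkpoint.fvz --out features.csv
freqvit extract --data data/ --family hog --out hog.csv

# score features with the seven-classifier protocol
freqvit eval --features features.csv --out metrics.csv --seed 0

# train and score the B0/B1/B2/full variant grid
freqvit ablate --config run.yaml --out ablation.csv --seed 0
```

A YAML run config may contain `model`, `train`, and `synth` sections whose
keys mirror `ModelConfig`, `TrainConfig`, and `SynthSpec` in
`freqvit.config`. Every command writes its resolved configuration next to its
outputs and refuses to overwrite existing files without `--force`.

## Layout

- `src/freqvit/model.py` — encoder, spectral-refinement block, head, checkpointing
- `src/freqvit/spectral.py` — patch-grid relayout, FFT pair, SE gate
- `src/freqvit/nn.py` — NumPy layers with hand-written backward passes, AdamW
- `src/freqvit/training.py` — loss, augmentation, training loop
- `src/freqvit/feature_eval.py` — seven-classifier protocol and metrics
- `src/freqvit/baselines.py` — handcrafted descriptor families
- `src/freqvit/synth.py` — synthetic two-class H&E-like tile generator
- `src/freqvit/ablation.py` — variant grid and the scaled benchmark
- `src/freqvit/cli.py` — command-line entry points
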