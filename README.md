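# copdfusion

Multimodal chest-image classification with randomized feature fusion, plus
airway cross-section quantification — all runnable end-to-end on seeded
synthetic data.

The package implements, from scratch in numpy:

- **`nn_core`** — neural-network primitives (valid convolution, average
  pooling, sigmoid, dense layers, softmax cross-entropy) with exact backward
  passes, verified by brute-force oracles and finite-difference checks.
- **`lenet`** — a small two-stage convolutional network (shape schedule
  28×28 → 6×24×24 → 6×12×12 → 12×8×8 → 12×4×4 → 192 → n_classes) built per
  modality (CT-like / X-ray-like); its 192-d fully-connected sigmoid feature
  is exposed for fusion.
- **`fusion`** — seeded random linear projections map both modalities'
  192-d features into a common dimension (frozen after build), combined and
  classified by a trainable fully-connected + softmax head; backbone
  parameters transfer from the trained single-modal networks and stay
  frozen by default.
- **`training`** — reproducible mini-batch SGD, plus iteration-count and
  batch-size sweep experiments (the batch sweep fixes an epoch budget, so
  larger batches mean fewer updates and less training time).
- **`evaluation`** — confusion counts and recognition / sensitivity /
  specificity (positive class = 1); undefined margins come back as NaN with
  a warning, never a silent zero.
- **`airway_quant`** — threshold + connected-component segmentation of
  annular airway cross-sections and the LA / WA / WA% measurements,
  validated against closed-form phantom ground truth.
- **`synthetic_data`** — seeded paired-modality cohorts (class signal split
  across modalities: wall thickening in the CT channel, global lucency shift
  in the X-ray channel) and annular phantoms with analytic LA/WA%.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (primitive oracles,
metric identities, architecture fidelity, learning capability, fusion
benefit, sweep trends, phantom recovery, bit-reproducibility); the rest are
per-module unit and property tests. Full suite ≈ 2–3 minutes on one CPU.

## CLI

```sh
# make a seeded 60-subject paired-modality dataset
copdfusion generate cohort --n 60 --noise-sd 0.1 --seed 1 --out data/

# train the two single-modal networks, then the fusion model
copdfusion train --data data/ --model ct   --iterations 300 --seed 1 --out runs/ct
copdfusion train --data data/ --model xray --iterations 300 --seed 1 --out runs/xray
copdfusion train --data data/ --model fusion \
    --ct-model runs/ct/ct_model.npz --xray-model runs/xray/xray_model.npz \
    --iterations 300 --seed 1 --out runs/fused

# evaluate on the held-out split
copdfusion evaluate --data data/ --model-file runs/fused/fusion_model.npz \
    --seed 1 --out runs/eval

# iteration / batch sweeps over all three models
copdfusion sweep --data data/ --mode iterations --grid 25,100,400 --seed 1 --out runs/sweep

# airway phantom + LA/WA% measurement
copdfusion generate phantom --lumen-radius 8 --outer-radius 12 --out runs/ph
copdfusion measure --in runs/ph/phantom.npy --pixel-size 1.0 --out runs/meas
```

Every stochastic command takes `--seed` and writes a `run_manifest.json`
recording the full configuration; equal seeds reproduce outputs
bit-identically (datasets stored as `.npy` by default; `--fmt png` stores
8-bit quantized grayscale instead).

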