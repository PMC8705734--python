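# vesselseg

Retinal blood-vessel segmentation with a dense-block U-Net, implemented as a
self-contained scientific Python package:

* **Preprocessing** — green channel → CLAHE → median filter → min–max
  normalization → adaptive gamma correction → multi-scale top-hat
  enhancement (four disk scales).
* **Patch training** — random 48×48 patch amplification (190,000 patches at
  the default DRIVE-style configuration), soft Dice loss with its analytic
  gradient, momentum SGD.
* **Dense-block U-Net** — densely connected BN→ReLU→3×3-conv layers
  (layer ℓ sees `k0 + k·(ℓ−1)` channels), transition-down
  (BN + 1×1 conv + 2×2 average pool), 2×2 transposed-conv transition-up,
  skip concatenation, sigmoid head. The network and its backward pass are
  written in NumPy (no deep-learning framework required) and are verified
  against central-difference gradients.
* **Inference** — overlap-averaged patch stitching with reflect padding and
  FOV masking.
* **Evaluation** — confusion counts, Acc/Sp/Sn/PPV, ROC/AUC with exact
  Mann–Whitney tie handling, restricted to the field of view.
* **Synthetic data** — a fundus-like image generator (branching vessel
  trees, radial illumination, noise, circular FOV, ~10% vessel fraction)
  so the full pipeline is testable without any external download.

## CLI

All stages are exposed through one entry point (see `--help` on each):

```bash
vesselseg make-synthetic --n 20 --seed 7 --out data/training
vesselseg sample   --data data/ --out patches.npz --set sampler.n_total=190000
vesselseg train    --data patches.npz --out runs/model --set train.epochs=20
vesselseg predict  --model runs/model/best.npz --image img.png --fov fov.png \
                   --out seg.png --prob-out prob.tiff
vesselseg evaluate --pred seg.png --prob prob.tiff --gold manual.png \
                   --fov fov.png --out metrics.json
vesselseg run-all  --out runs/full --seed 1      # synthesize → ... → evaluate
```

Configuration is YAML (`--config cfg.yaml`) plus `--set section.key=value`
overrides; every key has a default and unknown keys are rejected. Each run
writes `effective_config.yaml` so it can be reproduced from its log alone.

## DRIVE benchmark (optional, manual)

The reference results on the DRIVE test set (Acc 0.9698, Sp 0.9896,
Sn 0.7931, PPV 0.8946, AUC 0.9738) require downloading DRIVE and a long
training run with hyperparameters that were never published; they are not
part of the automated suite. With DRIVE unpacked as
`DRIVE/{training,test}/{images,1st_manual,mask}`:

```bash
vesselseg run-all --out runs/drive --set pipeline.data_dir=DRIVE
```

## Layout

```
src/vesselseg/
  io.py         image/mask/DRIVE-layout reading & writing, patch caches
  preprocess.py six-stage enhancement pipeline
  sampler.py    random patch amplification and train/val splitting
  nn.py         NumPy layers with explicit backward passes + SGD
  model.py      dense-block U-Net construction & channel-algebra introspection
  losses.py     Dice coefficient / analytic gradient / loss
  train.py      mini-batch training loop, checkpoints, logs
  infer.py      overlap-averaged whole-image prediction, thresholding
  metrics.py    confusion counts, Acc/Sp/Sn/PPV, ROC/AUC
  synthetic.py  fundus-like generator with exact ground truth
  config.py     strict YAML config, seed derivation
  pipeline.py   run-all orchestration
  cli.py        click CLI
```
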