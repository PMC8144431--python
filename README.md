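# eegstage

Movement-stage decoding from multichannel EEG with 3D spatial-temporal
representations, multi-branch 3D convolutional networks, class-balanced
cropped training and the focal loss.

## What this is for

In grasp-and-lift style BCI paradigms, a trial's EEG is segmented by
behavioral events (hand movement onset `tHandStart`, load-force onset
`tBothStartLoadPhase`, `LEDOff`, `tReplace`, `tHandStop`) into four movement
stages, and the task is to tell consecutive stages apart from short EEG
windows.  Two practical obstacles dominate: the classes are heavily
imbalanced (the load phase yields far more data than the others), and they
are unequally difficult (some stages are intrinsically harder to recognize,
the "easy-hard example" problem).  This package implements an end-to-end
pipeline addressing both, exercisable entirely on synthetic EEG:

* **3D representation** — channels x time windows are embedded on a sparse
  7 x 11 grid following the 10-20 electrode arrangement, giving
  `rows x cols x samples` volumes (empty cells zero; the only preprocessing
  is per-channel mean subtraction).
* **Balanced cropped training** — each stage window (500 samples) is cut
  into sliding 480-sample crops; per-class cropping strides
  `step = round(num_big/num_small)` (one class under the count threshold) or
  `step_k = round(num_ck/3000)` (both over) equalize class counts by
  thinning, never by oversampling.
* **Multi-branch 3D CNN** — parallel branches of valid strided 3D
  convolutions with small/medium/large temporal receptive fields, flattened
  and concatenated into a dropout-0.4 fully-connected head with a 2-way
  softmax.  Printed two- and four-conv-layer variants (`shallow2`, `deep4`)
  and two-/three-/four-branch variants are available as presets.
* **Focal loss** — `FL(p_t) = -alpha_t (1 - p_t)^gamma log(p_t) x 1000`,
  with `alpha` computed from class counts; `gamma = 0` recovers
  cross-entropy.  When CE training leaves a per-class accuracy gap above
  0.3, a sweep over `gamma` (0-11, step 0.5) retrains with focal loss and
  keeps the best-balanced result.
* **Protocol** — Adam (lr 0.01), normalized initialization, patience-20
  early stopping with best-weight restore, nine-fold cross-validation,
  per-class accuracy / gap / Cohen's kappa, averaging over repeated runs.

The network engine (3D convolution with exact backprop, Adam, dropout) is
implemented in numpy and fully deterministic per seed.

## Worked example

```python
import numpy as np
from eegstage import (get_preset, balanced_crop, preset, run_cv,
                      TrainConfig)

pp = get_preset("imbalanced-easy", seed=1)     # 60 vs 20 synthetic trials
crops = balanced_crop(pp.make_dataset(), window=pp.crop_window,
                      threshold=pp.threshold, divisor=pp.divisor)
print(crops.counts)                            # -> num_c1=420, num_c2=420

model_cfg = preset("default3", feature_maps=pp.feature_maps,
                   fc_sizes=pp.fc_sizes)
report = run_cv(crops, pp.synth.layout, model_cfg,
                TrainConfig(max_epochs=3, seed=1), n_folds=9)
print(f"mean accuracy {report.mean_accuracy:.3f}  "
      f"kappa {report.mean_kappa:.3f}")
```

Output:

```
ClassCounts(num_c1=420, num_c2=420)
mean accuracy 1.000  kappa 1.000
```

The 3:1 trial imbalance produces 1260 vs 420 stride-1 crops; the balancing
formulas assign strides (3, 1), equalizing the classes at 420 crops each,
and the three-branch network separates the two synthetic movement stages
essentially perfectly under nine-fold cross-validation.

The same flow is available from the shell:

```
eegstage simulate --preset balanced-easy --seed 7 --out data/
eegstage crop --preset imbalanced-easy --out crops.jsonl
eegstage train --preset imbalanced-easy --out run/
eegstage sweep-gamma --preset imbalanced-hard --gamma-min 0 --gamma-max 10 \
    --gamma-step 2.5 --trigger-gap 0.3 --out sweep.json
```

(The full protocol sweeps gamma from 0 to 11 in steps of 0.5 —
`--gamma-step 0.5` — which takes proportionally longer; coarse grids are
fine for a first look.)

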