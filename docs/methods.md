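# Methods

## Problem setting

`eegstage` decodes *movement stages* from multichannel EEG in a
grasp-and-lift style paradigm.  A trial's timeline is segmented by five
behavioral event markers (hand movement onset, load-force onset, LED off,
object replaced, hand at rest) into four stages, and the task is a set of
binary classifications between consecutive stages.  The same machinery
applies to conventional motor-imagery decoding (e.g. 22-channel, 250 Hz
cue-based paradigms) through the configurable electrode layout and input
shape.

## 3D representation

Each EEG window (channels x samples, microvolts) is embedded on a sparse
spatial grid derived from the 10-20 electrode arrangement: 32 channels on a
7 x 11 grid by default, giving a `7 x 11 x T` volume in which grid cells
without an electrode are exactly zero.  The embedding preserves spatial
adjacency (lost by flat channel-by-time matrices) and temporal order
simultaneously.  The only preprocessing is per-channel mean subtraction of
each window; no filtering, re-referencing, interpolation into empty cells,
or artifact handling is applied, deliberately — the network is expected to
cope with broadband input.

Two open conventions had to be fixed: the mean is removed per channel (not
globally), and grid coordinates are 0-based `(row, col)` with row 0 at the
frontal edge.  The exact 32-channel cell assignment is packaged as a
documented default and fully overridable through a JSON layout file
(`{"grid": [rows, cols], "placements": {"Cz": [3, 5], ...}}`).

## Stage extraction and balanced cropped training

From each stage interval one onset-locked window of 500 samples is
extracted (intervals shorter than the window are skipped with a warning).
Sliding 480-sample crops inside each window augment the data: a 500-sample
window yields 21 stride-1 crops.  Crops inherit their window's stage label.

Because stage durations differ systematically (the load phase is typically
the longest), stride-1 crop counts are heavily imbalanced across classes.
Balancing is by *stride thinning*, never oversampling: with per-class
stride-1 counts `num_c1`, `num_c2`, a count threshold (default 6000) and a
divisor (default 3000),

* both counts below the threshold: both classes keep stride 1;
* exactly one below: it keeps stride 1, the other is thinned with
  `step = round(num_big / num_small)`;
* both at or above: each class is thinned with `step_k = round(num_ck / 3000)`.

Steps are rounded to the nearest integer (ties away from zero) and clamped
to >= 1; this keeps per-class counts approximately — not exactly — equal
(max/min ratio <= 1.5 in practice).  The desk-scale synthetic presets scale
the threshold/divisor pair down in proportion to their trial counts so the
same formulas engage at a few hundred crops per class.

Cross-validation folds operate on crops but are grouped by source trial by
default, so crops of one trial never straddle a train/test boundary; the
ungrouped crop-level mode is available as an option.

## The multi-branch 3D CNN

The classifier is a parallel multi-branch 3D CNN over the grid volume.
Each branch stacks valid (unpadded) strided 3D convolutions with ReLU;
branches share the input but hold independent weights and differ in the
temporal extent of their kernels — small, medium and large receptive fields
(SRF/MRF/LRF), plus an extra-large branch (XLRF) in the four-branch
variant.  Branch outputs are flattened, concatenated, passed through
fully-connected layers with dropout 0.4, and end in a 2-node softmax.

The two-conv-layer variant (`shallow2`) and the four-conv-layer variant
(`deep4`) are fixed kernel/stride tables shipped as presets.  The
three-layer network (`default3`) is a documented reconstruction, using the
shared first two layers of the deep variant and a per-branch collapsing
third layer; it is fully overridable from a JSON model config.  Feature-map
counts (default 32) and hidden widths (default 64, 32) are likewise
reconstructions, configurable everywhere.  A genuine corollary of the
preset tables: `deep4` cannot run on the default `7 x 11 x 480` input
under valid convolution (the height extent collapses to 1 before its
height-2 fourth-layer kernel); shape validation reports the offending
layer, and the preset works on grids with at least 8 rows.

The network engine is written in numpy: convolutions are lowered to BLAS
matrix multiplications through sliding-window views (channels-last layout so
patch gathers move contiguous blocks; branches with identical first-layer
geometry share one patch extraction), gradients are exact (checked against
central finite differences), initialization is normalized (Glorot) uniform
from a seed, and optimization is Adam with the customary defaults.  Same
seed, same data — bitwise-identical results on one thread.

## Loss functions

With `p` the softmax probability of the y=1 class and `p_t = p` if `y = 1`
else `1 - p`:

* cross-entropy: `CE = -log(p_t)`;
* focal loss: `FL = -alpha_t (1 - p_t)^gamma log(p_t) * scale`.

The modulating factor `(1 - p_t)^gamma` suppresses well-classified examples
(at `gamma = 2`: 100x at `p_t = 0.9`, only 0.25x at `p_t = 0.5`, 1000x at
`p_t ~ 0.968`), refocusing training on hard ones; `gamma = 0`,
`alpha_t = 1`, `scale = 1` recovers CE exactly.  The class weight is
derivable from crop counts, `alpha = num_c2 / (num_c1 + num_c2)` applied to
the y=1 class and `1 - alpha` to the other, so the rarer class weighs more.
The scale factor (default 1000 when focusing is enabled) keeps the
down-weighted loss from becoming so small that cost-based early stopping
fires prematurely.  Probabilities are clamped at `1e-12` inside logarithms.
Batch reduction is the mean, so the scale is batch-size independent.
Class 1 of a binary task is coded y=1; the convention is documented and
swappable.

## Training and evaluation protocol

Adam at learning rate 0.01, batch size 64.  The monitored cost is the
epoch-mean training loss by default (a held-out monitor set is an option);
if it fails to decrease for `patience` (default 20) consecutive epochs,
training stops and the weights of the minimum-cost epoch are restored.
Divergence (non-finite cost) aborts with a diagnostic.

Evaluation uses nine-fold cross-validation: random equal-size folds,
stratified and trial-grouped by default, eight folds training and one
testing per run.  Reported metrics are per-class accuracies (with their
absolute gap), overall accuracy and Cohen's kappa
`(P0 - Pe) / (1 - Pe)` computed from the 2 x 2 confusion table (P0 =
diagonal proportion, Pe = chance agreement from the marginal products).
Repeated runs with different seeds are averaged elementwise.

The focal-loss protocol follows the two-step rule: train with CE; if the
per-class accuracy gap exceeds 0.3, sweep the focusing parameter (full grid
0 to 11 in steps of 0.5; the scaled-down experiments use {0, 2, 5, 10}),
pick the gamma maximizing balanced accuracy (a max-min-class criterion is
available), and average repeated runs at the chosen gamma.

## Synthetic data

The generator emulates the *statistical* structure the pipeline exploits,
not EEG biophysics.  Each trial is white Gaussian sensor noise (default
1.0-1.5 uV r.m.s.) over all channels plus stage-specific band-limited
oscillations ("signatures") at central-row electrodes (C3/Cz/C4 — a
motor-area analog), mimicking ERS/ERD band-power modulation: amplitudes of
2.5-4 uV at mu/beta-band frequencies (7-22 Hz), random phase, log-normal
trial-to-trial amplitude jitter, optional per-trial presence probability.
Event times follow the four-stage schedule (1.2 s per stage +-0.08 s
jitter, always >= 500 samples at 500 Hz) so the stage extractor runs on
realistic timelines.

A `transition_lag_s` range adds the feature that makes decoding genuinely
hard: at each stage boundary the outgoing stage's rhythm persists past the
behavioral event and the incoming stage's rhythm starts late, by a per-trial
uniform lag.  Early crops of a stage then look like the *previous* stage,
producing a continuum from unrecoverable mimics to clearly separable crops —
the "easy-hard example" structure that motivates the focal loss, expressed
through timing rather than an arbitrary label flip.

What the generator does **not** emulate: 1/f background spectra, spatial
correlation of noise across electrodes, artifacts (EMG/EOG), non-stationary
rhythms, or volume conduction.  Passing tests therefore demonstrate that
the pipeline's mechanics (representation, balancing, optimization, the
focal-loss effect) work as specified — not that the architecture reaches
any particular accuracy on real EEG.

### Study conditions (presets)

* `balanced-easy`: 24 + 24 trials, strong distinct signatures, noise 1.0.
* `imbalanced-easy`: 60 vs 20 trials (3:1), strong distinct signatures;
  stride balancing (threshold 800, divisor 400) equalizes the classes at
  420 crops each.
* `imbalanced-hard`: 20 vs 14 trials (1.43:1, at the edge of what stride
  balancing evens out, so a residual count prior survives), noise 1.2,
  stage-2 signature weaker than stage 1's (2.5 uV beta at Cz vs 4 uV mu at
  C3/C4), transition lags of 0.6-1.35 s.  Lags beyond the 0.96 s crop
  window leave roughly half the stage-2 windows with no stage-2 rhythm at
  all — pure stage-1 mimics — and most of the rest with only a short burst.
  Cross-entropy training consequently favors the easy class (sometimes
  degenerating to near-total neglect of the hard one) and leaves a large
  per-class accuracy gap, the trigger condition for the gamma sweep.  The
  "hard" class in reports is whichever class the CE baseline disfavors,
  since the direction of the degeneracy is seed-dependent.  Hard-condition
  runs are scored on an independently generated balanced test set (30
  trials per class, three crops per window) rather than a held-out fold, to
  keep evaluation variance well below the effects being measured.

## Problem sizes and numerical choices

The shipped experiments are scaled to desk size as the package's own
defaults: feature maps 8 and hidden widths (32, 16) in the preset pipelines,
3-8 training epochs (the easy condition converges in 2-3), nine-fold CV for
the easy condition, and — inside the gamma sweep — training each candidate
on the full balanced crop set and scoring it on the fresh test trials
described above.  Full-scale settings (feature maps 32, patience-20 training to
convergence, 30-50 averaged runs) are available through the same
configuration objects.

Numerical details: float32 parameters and activations (float64 in the
gradient-check tests); probability clamp `1e-12`; stride rounding ties away
from zero; fold seeds derived from the run seed; dropout, shuffling and
initialization all drawn from explicitly passed generators.

## Known limitations

* No padding/pooling/batch-norm options — the preset architectures use
  none, so the engine implements none.
* Binary heads only; the four-class problem is handled as consecutive
  binary tasks by design.
* The numpy engine targets CPU determinism and small experiments, not
  large-scale training throughput.
* Real-EEG ingestion is limited to the generic CSV/array interfaces; no
  native readers for distribution-specific formats.
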