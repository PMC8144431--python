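"""Synthetic multichannel EEG with class-dependent spatial-spectral structure.

Each synthetic trial is a continuous recording spanning the four movement
stages delimited by five event timestamps.  Within a stage, the electrodes of
that stage's "signature" carry a band-limited oscillation (an ERS-like power
increase or, with a lower active than baseline amplitude, an ERD-like
decrease) on top of white Gaussian sensor noise; all amplitudes are in
microvolts.  Signatures sit at central-row grid positions as a motor-area
analog.  The generator emulates the statistical structure the decoding
pipeline exploits — band-power modulation at known electrodes, trial-to-trial
amplitude variability, class imbalance and unequal class difficulty — not
the biophysics of EEG.

Three pipeline presets map onto the decoding regimes of interest:

* ``balanced-easy``     equal class counts, strong distinct signatures;
* ``imbalanced-easy``   3:1 trial imbalance, strong distinct signatures,
                        rebalanced by stride cropping;
* ``imbalanced-hard``   residual count imbalance plus unequal class
                        difficulty from sluggish stage transitions: the
                        stage-1 rhythm persists past the behavioral event
                        and the stage-2 rhythm starts late by a per-trial
                        lag, so many stage-2 windows mimic stage 1 and
                        cross-entropy training favors the easy class with a
                        large per-class accuracy gap — the regime that
                        triggers the focal-loss gamma sweep.

Preset crop-balancing thresholds scale with the preset's trial counts so the
stride formulas engage at desk scale; the full-scale defaults (6000/3000)
live in :mod:`eegstage.cropping`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .cropping import EventTimes, StageSegment, extract_stage_windows
from .grid_repr import ElectrodeLayout, EEGSegment, mean_subtract


@dataclass(frozen=True)
class Signature:
    """A class-specific oscillation at one electrode.

    ``active_amp`` applies during the stage, ``baseline_amp`` outside it
    (ERS-like if active > baseline, ERD-like if active < baseline).
    ``presence`` is the per-trial probability that the signature is expressed
    at all; ``amp_jitter`` is the s.d. of a multiplicative log-normal
    trial-to-trial amplitude factor.
    """

    channel: str
    freq_hz: float
    active_amp: float
    baseline_amp: float = 0.0
    presence: float = 1.0
    amp_jitter: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.presence <= 1:
            raise ValueError("presence must lie in [0, 1]")
        if self.active_amp < 0 or self.baseline_amp < 0:
            raise ValueError("amplitudes must be non-negative")


#: Default stage signatures at motor-area analog electrodes (central row):
#: distinct channel/frequency combinations make all four stages separable.
DEFAULT_SIGNATURES: dict[int, tuple[Signature, ...]] = {
    1: (Signature("C3", 10.0, 4.0), Signature("C4", 10.0, 4.0)),
    2: (Signature("Cz", 22.0, 4.0),),
    3: (Signature("C3", 7.0, 4.0),),
    4: (Signature("C4", 15.0, 4.0),),
}


@dataclass(frozen=True)
class SynthConfig:
    """Recording-level generator settings."""

    sample_rate: float = 500.0
    layout: ElectrodeLayout = field(default_factory=ElectrodeLayout.default)
    stage_duration_s: float = 1.2
    padding_s: float = 0.5
    event_jitter_s: float = 0.08
    noise_sd: float = 1.0
    signatures: Mapping[int, tuple[Signature, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SIGNATURES))
    #: Per-trial uniform range (s) of the neural lag at each stage boundary:
    #: the outgoing stage's rhythm persists and the incoming stage's rhythm
    #: starts late relative to the behavioral event marker, so early crops of
    #: a stage look like the previous stage.  (0, 0) = crisp transitions.
    transition_lag_s: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.event_jitter_s < 0:
            raise ValueError("event_jitter_s must be >= 0")
        lo, hi = self.transition_lag_s
        if not (0 <= lo <= hi):
            raise ValueError("transition_lag_s must be an ordered "
                             "non-negative range")
        nyquist = self.sample_rate / 2
        for sigs in self.signatures.values():
            for s in sigs:
                if not s.freq_hz < nyquist:
                    raise ValueError(
                        f"signature at {s.freq_hz} Hz exceeds Nyquist")
                if s.channel not in self.layout.placements:
                    raise ValueError(f"signature channel {s.channel!r} "
                                     "not in layout")
        min_stage = self.stage_duration_s - self.event_jitter_s
        if min_stage * self.sample_rate < 500:
            raise ValueError("stage intervals may fall below 500 samples")

    @property
    def n_channels(self) -> int:
        return self.layout.n_channels


def generate_recording(
    config: SynthConfig, trial_index: int
) -> tuple[EEGSegment, EventTimes, dict[int, tuple[int, int]]]:
    """One continuous four-stage trial.

    Returns the recording, its five event timestamps (strictly increasing by
    construction) and the per-stage sample spans.  Deterministic in
    ``(config.seed, trial_index)``.
    """
    rng = np.random.default_rng([config.seed, trial_index])
    rate = config.sample_rate

    bounds_s = [config.padding_s]
    for _ in range(4):
        jit = rng.uniform(-config.event_jitter_s, config.event_jitter_s)
        bounds_s.append(bounds_s[-1] + config.stage_duration_s + jit)
    events = EventTimes(*bounds_s)
    n_samples = int(round((bounds_s[-1] + config.padding_s) * rate))

    names = config.layout.channel_names
    values = rng.normal(0.0, config.noise_sd,
                        size=(len(names), n_samples)) if config.noise_sd > 0 \
        else np.zeros((len(names), n_samples))
    t = np.arange(n_samples) / rate
    row_of = {name: i for i, name in enumerate(names)}

    spans: dict[int, tuple[int, int]] = {}
    for k in range(4):
        spans[k + 1] = (int(round(bounds_s[k] * rate)),
                        int(round(bounds_s[k + 1] * rate)))

    # neural lag at each of the three stage boundaries: the outgoing rhythm
    # persists past the event marker and the incoming rhythm starts late
    lag_lo, lag_hi = config.transition_lag_s
    lags = [0] + [int(round(rng.uniform(lag_lo, lag_hi) * rate))
                  for _ in range(3)] + [0]

    for stage, sigs in config.signatures.items():
        lo = spans[stage][0] + lags[stage - 1]
        hi = min(spans[stage][1] + lags[stage], n_samples)
        for sig in sigs:
            expressed = rng.random() < sig.presence
            factor = float(np.exp(rng.normal(0.0, sig.amp_jitter))) \
                if sig.amp_jitter > 0 else 1.0
            envelope = np.full(n_samples, sig.baseline_amp)
            if expressed:
                envelope[lo:hi] = sig.active_amp * factor
            if envelope.any():
                phase = rng.uniform(0, 2 * np.pi)
                values[row_of[sig.channel]] += envelope * np.sin(
                    2 * np.pi * sig.freq_hz * t + phase)

    return EEGSegment(values, rate, list(names)), events, spans


def generate_binary_dataset(
    config: SynthConfig,
    stage_pair: tuple[int, int] = (1, 2),
    n_class1: int = 40,
    imbalance_ratio: float = 1.0,
    extract_length: int = 500,
    center: bool = True,
) -> dict[int, list[StageSegment]]:
    """Stage windows for a binary task, grouped by class.

    ``n_class1`` trials feed class 1 (the first stage of the pair) and
    ``round(n_class1 / imbalance_ratio)`` independent trials feed class 2, so
    per-class segment counts follow the requested ratio exactly.  Windows are
    mean-subtracted per channel unless ``center=False``.
    """
    if imbalance_ratio <= 0:
        raise ValueError("imbalance_ratio must be positive")
    if n_class1 < 1:
        raise ValueError("at least one class-1 trial required")
    n_class2 = max(1, int(round(n_class1 / imbalance_ratio)))

    dataset: dict[int, list[StageSegment]] = {stage_pair[0]: [],
                                              stage_pair[1]: []}
    trial = 0
    for stage, count in zip(stage_pair, (n_class1, n_class2)):
        for _ in range(count):
            recording, events, _ = generate_recording(config, trial)
            windows = extract_stage_windows(recording, events, extract_length)
            seg = windows[stage].segment
            if center:
                seg = mean_subtract(seg)
            dataset[stage].append(StageSegment(stage, seg, trial_id=trial))
            trial += 1
    return dataset


# -- pipeline presets -------------------------------------------------------


@dataclass(frozen=True)
class PipelinePreset:
    """A full desk-scale study condition: generator + cropping + model size."""

    name: str
    synth: SynthConfig
    stage_pair: tuple[int, int]
    n_class1: int
    imbalance_ratio: float
    crop_window: int = 480
    extract_length: int = 500
    threshold: int = 6000
    divisor: int = 3000
    model_preset: str = "default3"
    feature_maps: int = 8
    fc_sizes: tuple[int, ...] = (32, 16)

    def make_dataset(self, seed: int | None = None):
        synth = self.synth if seed is None else replace(self.synth, seed=seed)
        return generate_binary_dataset(
            synth, self.stage_pair, self.n_class1, self.imbalance_ratio,
            self.extract_length)

    def make_test_dataset(self, n_per_class: int = 30):
        """Balanced, independently seeded trials for held-out evaluation."""
        synth = replace(self.synth, seed=self.synth.seed + 900_001)
        return generate_binary_dataset(
            synth, self.stage_pair, n_per_class, 1.0, self.extract_length)


def _hard_signatures() -> dict[int, tuple[Signature, ...]]:
    # Stage 1 carries a strong mu rhythm; stage 2 a beta rhythm of similar
    # strength.  Difficulty comes from the transition lag: stage-2 windows
    # open with a variable stretch of persisting stage-1 rhythm before the
    # stage-2 rhythm starts, forming a continuum from class-1 mimics to
    # clearly class-2 crops.
    return {
        1: (Signature("C3", 10.0, 4.0, amp_jitter=0.2),
            Signature("C4", 10.0, 4.0, amp_jitter=0.2)),
        2: (Signature("Cz", 22.0, 2.5, amp_jitter=0.25),),
        3: (Signature("C3", 7.0, 4.0, amp_jitter=0.2),),
        4: (Signature("C4", 15.0, 4.0, amp_jitter=0.2),),
    }


def get_preset(name: str, seed: int = 0) -> PipelinePreset:
    """Named desk-scale study conditions (see module docstring)."""
    if name == "balanced-easy":
        return PipelinePreset(
            name, SynthConfig(noise_sd=1.0, seed=seed), stage_pair=(1, 2),
            n_class1=24, imbalance_ratio=1.0, threshold=800, divisor=400)
    if name == "imbalanced-easy":
        return PipelinePreset(
            name, SynthConfig(noise_sd=1.0, seed=seed), stage_pair=(1, 2),
            n_class1=60, imbalance_ratio=3.0, threshold=800, divisor=400)
    if name == "imbalanced-hard":
        return PipelinePreset(
            name,
            SynthConfig(noise_sd=1.2, signatures=_hard_signatures(),
                        transition_lag_s=(0.6, 1.35), seed=seed),
            stage_pair=(1, 2), n_class1=20, imbalance_ratio=1.43,
            threshold=350, divisor=175, model_preset="two_branch")
    raise ValueError(f"unknown preset {name!r}; choose from "
                     "'balanced-easy', 'imbalanced-easy', 'imbalanced-hard'")
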