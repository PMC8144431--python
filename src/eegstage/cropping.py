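"""Stage extraction and class-balanced cropped training.

A grasp-and-lift trial is segmented into four movement stages by five event
timestamps (hand starts moving, load force onset, LED off, object replaced,
hand stops).  From each stage interval a fixed-length window (default 500
samples) is taken from stage onset, and sliding 480-sample crops inside it
multiply the training data.

Class imbalance between the two stages of a binary task is handled by
thinning the crop grid with per-class strides:

* both classes below the count threshold -> both keep stride 1;
* exactly one class below the threshold -> it keeps stride 1 and the larger
  class is thinned with ``step = round(num_big / num_small)``;
* both at or above the threshold -> each class is thinned with
  ``step_k = round(num_ck / divisor)``.

With the default threshold 6000 and divisor 3000 this keeps each class at
roughly 3000-6000 crops.  Rounding is to the nearest integer (ties away from
zero) and strides are clamped to >= 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import numpy as np

from .grid_repr import EEGSegment, SegmentError


class EventOrderError(ValueError):
    """Raised when the five trial events are not strictly increasing."""


class CropError(ValueError):
    """Raised for impossible cropping requests."""


class StageSkippedWarning(UserWarning):
    """Emitted when a stage interval is too short to hold a full window."""


EVENT_ORDER = ("tHandStart", "tBothStartLoadPhase", "LEDOff", "tReplace", "tHandStop")

#: Stage k spans [start event, end event) of the trial timeline:
#: 1 hands start to move; 2 fingers apply load force; 3 load held and object
#: returned; 4 hand returns to rest.
STAGE_BOUNDS: dict[int, tuple[str, str]] = {
    1: ("tHandStart", "tBothStartLoadPhase"),
    2: ("tBothStartLoadPhase", "LEDOff"),
    3: ("LEDOff", "tReplace"),
    4: ("tReplace", "tHandStop"),
}

DEFAULT_EXTRACT_LENGTH = 500
DEFAULT_CROP_WINDOW = 480
DEFAULT_THRESHOLD = 6000
DEFAULT_DIVISOR = 3000


@dataclass(frozen=True)
class EventTimes:
    """The five trial event timestamps, in seconds from recording start."""

    tHandStart: float
    tBothStartLoadPhase: float
    LEDOff: float
    tReplace: float
    tHandStop: float

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        if not all(a < b for a, b in zip(vals, vals[1:])):
            raise EventOrderError(
                f"event times must be strictly increasing, got {vals}"
            )

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in EVENT_ORDER)

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in EVENT_ORDER}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "EventTimes":
        return cls(**{name: float(d[name]) for name in EVENT_ORDER})


@dataclass
class StageSegment:
    """A fixed-length window drawn from one movement stage of one trial."""

    stage: int
    segment: EEGSegment
    trial_id: Hashable

    def __post_init__(self) -> None:
        if self.stage not in STAGE_BOUNDS:
            raise ValueError(f"stage must be one of {sorted(STAGE_BOUNDS)}")


@dataclass(frozen=True)
class ClassCounts:
    """Stride-1 crop counts for the two classes of a binary task."""

    num_c1: int
    num_c2: int

    def __post_init__(self) -> None:
        if self.num_c1 < 0 or self.num_c2 < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.num_c1 + self.num_c2


@dataclass(frozen=True)
class CropPlan:
    """Per-class cropping strides produced by :func:`plan_balance`."""

    step_c1: int
    step_c2: int

    def __post_init__(self) -> None:
        if self.step_c1 < 1 or self.step_c2 < 1:
            raise ValueError("strides must be >= 1")


def extract_stage_windows(
    recording: EEGSegment,
    events: EventTimes,
    length: int = DEFAULT_EXTRACT_LENGTH,
) -> dict[int, StageSegment]:
    """Cut one onset-locked window of ``length`` samples per movement stage.

    Stages whose interval is shorter than ``length`` samples are skipped with
    a :class:`StageSkippedWarning`.  Returns a mapping stage -> window.
    """
    rate = recording.sample_rate
    windows: dict[int, StageSegment] = {}
    for stage, (start_ev, end_ev) in STAGE_BOUNDS.items():
        start = int(round(getattr(events, start_ev) * rate))
        end = int(round(getattr(events, end_ev) * rate))
        end = min(end, recording.n_samples)
        if end - start < length:
            warnings.warn(
                f"stage {stage} interval [{start}, {end}) holds fewer than "
                f"{length} samples; stage skipped",
                StageSkippedWarning,
                stacklevel=2,
            )
            continue
        windows[stage] = StageSegment(
            stage, recording.slice_samples(start, start + length), trial_id=None
        )
    return windows


def crop_starts(length: int, window: int, stride: int) -> np.ndarray:
    """Start offsets of all full windows: 0, stride, ... <= length - window."""
    if window > length:
        raise CropError(f"window {window} longer than segment {length}")
    if stride < 1:
        raise CropError("stride must be >= 1")
    return np.arange(0, length - window + 1, stride)


def stride1_count(length: int, window: int) -> int:
    """Number of stride-1 crops a segment of ``length`` yields."""
    return max(0, length - window + 1)


def crop_windows(
    segment: StageSegment | EEGSegment,
    window: int = DEFAULT_CROP_WINDOW,
    stride: int = 1,
) -> list[EEGSegment]:
    """Slide a fixed-length window over a segment with the given stride."""
    seg = segment.segment if isinstance(segment, StageSegment) else segment
    starts = crop_starts(seg.n_samples, window, stride)
    return [seg.slice_samples(int(s), int(s) + window) for s in starts]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def plan_balance(
    counts: ClassCounts,
    threshold: int = DEFAULT_THRESHOLD,
    divisor: int = DEFAULT_DIVISOR,
) -> CropPlan:
    """Choose per-class cropping strides that approximately balance classes."""
    n1, n2 = counts.num_c1, counts.num_c2
    if n1 == 0 and n2 == 0:
        raise CropError("both class counts are zero")
    if n1 < threshold and n2 < threshold:
        return CropPlan(1, 1)
    if n1 >= threshold and n2 >= threshold:
        s1 = max(1, _round_half_up(n1 / divisor))
        s2 = max(1, _round_half_up(n2 / divisor))
        return CropPlan(s1, s2)
    if n1 >= threshold:  # only class 1 large
        return CropPlan(max(1, _round_half_up(n1 / max(n2, 1))), 1)
    return CropPlan(1, max(1, _round_half_up(n2 / max(n1, 1))))


@dataclass
class CropSet:
    """A collection of equal-length crops with binary labels.

    ``labels`` uses the convention y = 1 for class 1 (the first stage of the
    binary pair) and y = 0 for class 2, matching the loss-side convention that
    ``alpha = num_c2 / (num_c1 + num_c2)`` weights the y = 1 class.
    """

    windows: np.ndarray  # (n, channels, window_samples)
    labels: np.ndarray  # (n,) in {0, 1}; 1 <-> class 1
    trial_ids: np.ndarray  # (n,) source trial of each crop
    start_offsets: np.ndarray  # (n,) crop start within its source segment
    channel_names: list[str]
    sample_rate: float
    class_names: tuple[Hashable, Hashable]  # (class 1, class 2)

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.windows.ndim != 3:
            raise SegmentError("windows must have shape (n, channels, samples)")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be 0/1")

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def counts(self) -> ClassCounts:
        return ClassCounts(int((self.labels == 1).sum()),
                           int((self.labels == 0).sum()))

    def subset(self, idx: np.ndarray) -> "CropSet":
        return CropSet(
            self.windows[idx], self.labels[idx], self.trial_ids[idx],
            self.start_offsets[idx], list(self.channel_names),
            self.sample_rate, self.class_names,
        )

    def write_manifest(self, path: str | Path) -> None:
        """Crop manifest as JSON lines: source trial, start offset, label."""
        with open(path, "w") as fh:
            for trial, start, y in zip(self.trial_ids, self.start_offsets,
                                       self.labels):
                name = self.class_names[0] if y == 1 else self.class_names[1]
                fh.write(json.dumps({"trial": str(trial), "start": int(start),
                                     "label": str(name)}) + "\n")


def balanced_crop(
    segments_by_class: Mapping[Hashable, Sequence[StageSegment]],
    window: int = DEFAULT_CROP_WINDOW,
    threshold: int = DEFAULT_THRESHOLD,
    divisor: int = DEFAULT_DIVISOR,
    balance: bool = True,
) -> CropSet:
    """Crop both classes of a binary task with class-balancing strides.

    ``segments_by_class`` maps exactly two class keys (insertion order gives
    class 1, class 2) to their stage windows.  Per-class stride-1 crop counts
    feed :func:`plan_balance`; each class is then cropped at its stride.
    """
    keys = list(segments_by_class)
    if len(keys) != 2:
        raise CropError(f"binary task needs exactly 2 classes, got {len(keys)}")
    for k in keys:
        if len(segments_by_class[k]) == 0:
            raise CropError(f"class {k!r} has no segments")

    counts = ClassCounts(
        sum(stride1_count(s.segment.n_samples, window)
            for s in segments_by_class[keys[0]]),
        sum(stride1_count(s.segment.n_samples, window)
            for s in segments_by_class[keys[1]]),
    )
    plan = plan_balance(counts, threshold, divisor) if balance else CropPlan(1, 1)

    first = segments_by_class[keys[0]][0].segment
    windows_list, labels, trials, offsets = [], [], [], []
    for key, y, stride in ((keys[0], 1, plan.step_c1), (keys[1], 0, plan.step_c2)):
        for seg in segments_by_class[key]:
            for s in crop_starts(seg.segment.n_samples, window, stride):
                windows_list.append(seg.segment.values[:, s:s + window])
                labels.append(y)
                trials.append(seg.trial_id)
                offsets.append(int(s))
    return CropSet(
        np.asarray(windows_list), np.asarray(labels), np.asarray(trials),
        np.asarray(offsets), list(first.channel_names), first.sample_rate,
        (keys[0], keys[1]),
    )
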