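"""3D grid embedding of multichannel EEG.

Scalp electrodes placed according to the international 10-20 system are mapped
onto a sparse ``rows x cols`` grid so that physically adjacent electrodes end
up in adjacent grid cells.  A ``channels x samples`` segment then becomes a
``rows x cols x samples`` volume: each electrode's time series sits at its
grid cell and cells without an electrode are zero at every time step.  This
representation preserves both the spatial adjacency and the temporal order of
the recording, which is what the 3D convolutional branches exploit.

The only signal preprocessing applied anywhere in this package is per-channel
mean subtraction; no filtering, re-referencing or artifact rejection is done.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np


def _read_maybe_path(source) -> str:
    """Accept either a path to a JSON file or the JSON text itself."""
    if isinstance(source, Path):
        return source.read_text()
    text = str(source)
    if "\n" not in text and len(text) < 4096:
        p = Path(text)
        if p.exists():
            return p.read_text()
    return text


class LayoutError(ValueError):
    """Raised for an invalid electrode layout (out of bounds, duplicates...)."""


class SegmentError(ValueError):
    """Raised for an invalid or incompatible EEG segment."""


#: Default grid shape: 7 rows (frontal to occipital) x 11 columns (left to
#: right).  Row 0 is the frontal edge; coordinates are 0-based (row, col).
DEFAULT_GRID_SHAPE = (7, 11)

#: Default placement of the 32-channel 10-20 montage used by grasp-and-lift
#: EEG caps on the 7 x 11 grid.  Rows group the standard coronal lines
#: (Fp / F / FC / C / CP / P / O) and columns run left to right.
DEFAULT_PLACEMENTS_32: dict[str, tuple[int, int]] = {
    "Fp1": (0, 4), "Fp2": (0, 6),
    "F7": (1, 1), "F3": (1, 3), "Fz": (1, 5), "F4": (1, 7), "F8": (1, 9),
    "FC5": (2, 2), "FC1": (2, 4), "FC2": (2, 6), "FC6": (2, 8),
    "T7": (3, 0), "C3": (3, 3), "Cz": (3, 5), "C4": (3, 7), "T8": (3, 10),
    "TP9": (4, 0), "CP5": (4, 2), "CP1": (4, 4), "CP2": (4, 6),
    "CP6": (4, 8), "TP10": (4, 10),
    "P7": (5, 1), "P3": (5, 3), "Pz": (5, 5), "P4": (5, 7), "P8": (5, 9),
    "PO9": (6, 1), "O1": (6, 4), "Oz": (6, 5), "O2": (6, 6), "PO10": (6, 9),
}


@dataclass(frozen=True)
class ElectrodeLayout:
    """Mapping from channel names to 0-based (row, col) grid cells.

    Every placement must lie inside the grid and no two channels may share a
    cell.  Channel order follows the insertion order of ``placements``.
    """

    grid_rows: int
    grid_cols: int
    placements: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise LayoutError("grid shape must be positive")
        if not self.placements:
            raise LayoutError("placement map is empty")
        seen: dict[tuple[int, int], str] = {}
        for name, (r, c) in self.placements.items():
            if not (0 <= r < self.grid_rows and 0 <= c < self.grid_cols):
                raise LayoutError(
                    f"channel {name!r} placed at ({r}, {c}) outside "
                    f"{self.grid_rows}x{self.grid_cols} grid"
                )
            if (r, c) in seen:
                raise LayoutError(
                    f"channels {seen[(r, c)]!r} and {name!r} share cell ({r}, {c})"
                )
            seen[(r, c)] = name

    @property
    def channel_names(self) -> list[str]:
        return list(self.placements)

    @property
    def n_channels(self) -> int:
        return len(self.placements)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (self.grid_rows, self.grid_cols)

    @classmethod
    def default(cls) -> "ElectrodeLayout":
        """The packaged 32-channel 10-20 layout on a 7 x 11 grid."""
        return cls(*DEFAULT_GRID_SHAPE, dict(DEFAULT_PLACEMENTS_32))

    # -- layout file round trip: {"grid": [rows, cols], "placements": {...}} --

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "grid": [self.grid_rows, self.grid_cols],
            "placements": {k: list(v) for k, v in self.placements.items()},
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ElectrodeLayout":
        doc = json.loads(_read_maybe_path(source))
        rows, cols = doc["grid"]
        placements = {k: (int(r), int(c)) for k, (r, c) in doc["placements"].items()}
        return cls(int(rows), int(cols), placements)


def build_layout(
    placements: Mapping[str, Sequence[int]], grid_rows: int, grid_cols: int
) -> ElectrodeLayout:
    """Validate and construct an :class:`ElectrodeLayout`."""
    coerced = {name: (int(rc[0]), int(rc[1])) for name, rc in placements.items()}
    return ElectrodeLayout(grid_rows, grid_cols, coerced)


@dataclass
class EEGSegment:
    """A channels x samples block of EEG (microvolts) at a fixed sample rate."""

    values: np.ndarray
    sample_rate: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise SegmentError("segment values must be a channels x samples matrix")
        if len(self.channel_names) != self.values.shape[0]:
            raise SegmentError(
                f"{len(self.channel_names)} channel names for "
                f"{self.values.shape[0]} rows"
            )
        if not self.sample_rate > 0:
            raise SegmentError("sample_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def slice_samples(self, start: int, stop: int) -> "EEGSegment":
        return EEGSegment(self.values[:, start:stop], self.sample_rate,
                          list(self.channel_names))

    # -- CSV: one row per channel, optional leading header of channel names --

    def to_csv(self, path: str | Path, header: bool = True) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(",".join(self.channel_names) + "\n")
            for row in self.values:
                fh.write(",".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        sample_rate: float,
        channel_names: Sequence[str] | None = None,
    ) -> "EEGSegment":
        with open(path) as fh:
            first = fh.readline().strip()
            tokens = first.split(",")
            try:
                [float(t) for t in tokens]
                has_header = False
            except ValueError:
                has_header = True
            rows = [] if has_header else [[float(t) for t in tokens]]
            for line in fh:
                line = line.strip()
                if line:
                    rows.append([float(t) for t in line.split(",")])
        names = tokens if has_header else None
        if channel_names is not None:
            names = list(channel_names)
        if names is None:
            names = [f"ch{i}" for i in range(len(rows))]
        return cls(np.asarray(rows, dtype=np.float64), sample_rate, list(names))

    # -- binary container of named arrays (one channels x samples matrix
    #    per key, written with numpy.savez) --------------------------------

    def to_npz(self, path: str | Path, key: str = "segment") -> None:
        np.savez(path, **{key: self.values,
                          f"{key}__channels": np.array(self.channel_names),
                          f"{key}__rate": np.array(self.sample_rate)})

    @classmethod
    def from_npz(cls, path: str | Path, key: str = "segment",
                 sample_rate: float | None = None,
                 channel_names: Sequence[str] | None = None) -> "EEGSegment":
        with np.load(path, allow_pickle=False) as data:
            values = data[key]
            if channel_names is None and f"{key}__channels" in data:
                channel_names = [str(n) for n in data[f"{key}__channels"]]
            if sample_rate is None and f"{key}__rate" in data:
                sample_rate = float(data[f"{key}__rate"])
        if sample_rate is None:
            raise SegmentError("sample_rate not stored in container and "
                               "not provided")
        if channel_names is None:
            channel_names = [f"ch{i}" for i in range(values.shape[0])]
        return cls(values, sample_rate, list(channel_names))


@dataclass
class Volume3D:
    """A grid_rows x grid_cols x samples volume with zeros at empty cells."""

    values: np.ndarray
    layout: ElectrodeLayout

    @property
    def n_samples(self) -> int:
        return self.values.shape[2]


def mean_subtract(segment: EEGSegment) -> EEGSegment:
    """Remove each channel's mean over the segment (the only preprocessing)."""
    if segment.n_samples == 0:
        raise SegmentError("cannot mean-subtract a zero-length segment")
    centered = segment.values - segment.values.mean(axis=1, keepdims=True)
    return EEGSegment(centered, segment.sample_rate, list(segment.channel_names))


def to_volume(segment: EEGSegment, layout: ElectrodeLayout) -> Volume3D:
    """Embed a segment on the electrode grid, zero-filling empty cells."""
    if segment.n_samples == 0:
        raise SegmentError("segment has no samples")
    unknown = [n for n in segment.channel_names if n not in layout.placements]
    if unknown:
        raise LayoutError(f"channels not in layout: {unknown}")
    vol = np.zeros((layout.grid_rows, layout.grid_cols, segment.n_samples))
    for i, name in enumerate(segment.channel_names):
        r, c = layout.placements[name]
        vol[r, c, :] = segment.values[i]
    return Volume3D(vol, layout)


def extract_channels(volume: Volume3D, channel_names: Sequence[str]) -> np.ndarray:
    """Read placed cells back out of a volume (inverse of :func:`to_volume`)."""
    rows = [volume.values[volume.layout.placements[n]] for n in channel_names]
    return np.stack(rows, axis=0)


def segments_to_batch(
    windows: np.ndarray,
    channel_names: Sequence[str],
    layout: ElectrodeLayout,
    dtype=np.float32,
) -> np.ndarray:
    """Embed a stack of windows into a network input batch.

    ``windows`` has shape ``(n, channels, samples)``; the result is a
    channels-last batch ``(n, grid_rows, grid_cols, samples, 1)`` with zeros
    at empty grid cells.
    """
    windows = np.asarray(windows)
    n, n_ch, n_samp = windows.shape
    if n_ch != len(channel_names):
        raise SegmentError("window channel count does not match channel names")
    batch = np.zeros((n, layout.grid_rows, layout.grid_cols, n_samp, 1), dtype=dtype)
    for i, name in enumerate(channel_names):
        r, c = layout.placements[name]
        batch[:, r, c, :, 0] = windows[:, i, :]
    return batch
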