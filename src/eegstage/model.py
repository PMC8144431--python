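"""Configurable multi-branch 3D CNN for binary movement-stage decoding.

Each branch is a stack of valid (unpadded) strided 3D convolutions with ReLU
activations; branches differ in the temporal extent of their kernels and thus
in receptive field: SRF / MRF / LRF (small / medium / large), plus an XLRF
branch in the four-branch variant.  Branch outputs are flattened,
concatenated and fed through dropout-regularized fully-connected layers into
a 2-node softmax.

Presets
-------
``shallow2``   three branches, two conv layers each (shallow depth variant).
``default3``   the reference three-branch, three-conv-layer network.  Its
               third-layer kernels are a documented reconstruction: layers
               1-2 shared across branches as in the four-layer variant,
               layer 3 collapses the spatial extent per branch.  Fully
               overridable.
``deep4``      three branches, four conv layers each (deep depth variant).
               Note: on the default 7x11x480 input its fourth layer is
               geometrically infeasible under valid convolution (the height
               extent collapses to 1 before a height-2 kernel); validation
               reports this.  It builds on grids with more rows.
``two_branch`` default3 restricted to SRF + MRF.
``four_branch`` default3 plus an extra-large-receptive-field branch.

Feature-map counts (default 32) and hidden fully-connected widths (default
64, 32) are not fixed by the preset tables and are configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .grid_repr import ElectrodeLayout, segments_to_batch


class ConfigurationError(ValueError):
    """Raised when a model configuration cannot run on its input shape."""


DEFAULT_INPUT_SHAPE = (7, 11, 480)
DEFAULT_FEATURE_MAPS = 32
DEFAULT_FC_SIZES = (64, 32)
DEFAULT_DROPOUT = 0.4

PRESET_NAMES = ("shallow2", "default3", "deep4", "two_branch", "four_branch")


@dataclass(frozen=True)
class ConvSpec:
    """One 3D conv layer: kernel (h, w, t), stride (h, w, t), feature maps."""

    kernel: tuple[int, int, int]
    stride: tuple[int, int, int]
    feature_maps: int = DEFAULT_FEATURE_MAPS

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.kernel) or any(s < 1 for s in self.stride):
            raise ConfigurationError("kernel and stride must be >= 1 per axis")
        if self.feature_maps < 1:
            raise ConfigurationError("feature_maps must be positive")


@dataclass(frozen=True)
class BranchSpec:
    """A named branch (SRF/MRF/LRF/XLRF) as an ordered conv-layer stack."""

    name: str
    layers: tuple[ConvSpec, ...]

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ConfigurationError(f"branch {self.name} has no layers")


@dataclass(frozen=True)
class ModelConfig:
    """Full architectural description of a multi-branch 3D CNN."""

    branches: tuple[BranchSpec, ...]
    fc_sizes: tuple[int, ...] = DEFAULT_FC_SIZES
    n_classes: int = 2
    dropout: float = DEFAULT_DROPOUT
    input_shape: tuple[int, int, int] = DEFAULT_INPUT_SHAPE

    def __post_init__(self) -> None:
        if not 2 <= len(self.branches) <= 4:
            raise ConfigurationError("model needs 2-4 branches")
        depths = {len(b.layers) for b in self.branches}
        if len(depths) != 1:
            raise ConfigurationError("all branches must have equal depth")
        if not 0 <= self.dropout < 1:
            raise ConfigurationError("dropout must lie in [0, 1)")
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")

    # -- JSON round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "branches": [
                {"name": b.name,
                 "layers": [{"kernel": list(l.kernel), "stride": list(l.stride),
                             "feature_maps": l.feature_maps} for l in b.layers]}
                for b in self.branches
            ],
            "fc_sizes": list(self.fc_sizes),
            "n_classes": self.n_classes,
            "dropout": self.dropout,
            "input_shape": list(self.input_shape),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        branches = tuple(
            BranchSpec(b["name"], tuple(
                ConvSpec(tuple(l["kernel"]), tuple(l["stride"]),
                         l.get("feature_maps", DEFAULT_FEATURE_MAPS))
                for l in b["layers"]))
            for b in d["branches"]
        )
        return cls(branches, tuple(d.get("fc_sizes", DEFAULT_FC_SIZES)),
                   d.get("n_classes", 2), d.get("dropout", DEFAULT_DROPOUT),
                   tuple(d.get("input_shape", DEFAULT_INPUT_SHAPE)))

    @classmethod
    def from_json(cls, source: str | Path) -> "ModelConfig":
        from .grid_repr import _read_maybe_path

        return cls.from_dict(json.loads(_read_maybe_path(source)))


# -- preset kernel tables ---------------------------------------------------

# Two-conv-layer variant: layer 1 shared, layer 2 widens temporally per branch.
_SHALLOW2 = {
    "SRF": [((2, 2, 3), (1, 1, 2)), ((3, 4, 5), (2, 3, 4))],
    "MRF": [((2, 2, 3), (1, 1, 2)), ((3, 4, 7), (2, 3, 6))],
    "LRF": [((2, 2, 3), (1, 1, 2)), ((3, 4, 9), (2, 3, 8))],
}

# Four-conv-layer variant.
_DEEP4 = {
    "SRF": [((2, 2, 3), (1, 1, 2)), ((3, 3, 5), (2, 2, 4)),
            ((2, 2, 1), (1, 1, 1)), ((2, 3, 1), (2, 3, 1))],
    "MRF": [((2, 2, 3), (1, 1, 2)), ((3, 3, 5), (2, 2, 4)),
            ((2, 2, 3), (1, 1, 2)), ((2, 3, 3), (2, 3, 2))],
    "LRF": [((2, 2, 3), (1, 1, 2)), ((3, 3, 5), (2, 2, 4)),
            ((2, 2, 5), (1, 1, 4)), ((2, 3, 5), (2, 3, 4))],
}

# Three-conv-layer reconstruction: layers 1-2 as in the four-layer variant,
# layer 3 collapses the remaining spatial extent with per-branch temporal
# receptive fields.
_DEFAULT3 = {
    "SRF": [((2, 2, 3), (1, 1, 2)), ((3, 3, 5), (2, 2, 4)),
            ((2, 3, 1), (2, 3, 1))],
    "MRF": [((2, 2, 3), (1, 1, 2)), ((3, 3, 5), (2, 2, 4)),
            ((2, 3, 3), (2, 3, 2))],
    "LRF": [((2, 2, 3), (1, 1, 2)), ((3, 3, 5), (2, 2, 4)),
            ((2, 3, 5), (2, 3, 4))],
}

# Fourth branch for the four-branch variant: still larger temporal field.
_XLRF3 = [((2, 2, 3), (1, 1, 2)), ((3, 3, 5), (2, 2, 4)),
          ((2, 3, 7), (2, 3, 6))]

_PRESET_TABLES: dict[str, dict[str, list]] = {
    "shallow2": _SHALLOW2,
    "default3": _DEFAULT3,
    "deep4": _DEEP4,
    "two_branch": {k: _DEFAULT3[k] for k in ("SRF", "MRF")},
    "four_branch": {**_DEFAULT3, "XLRF": _XLRF3},
}


def preset(
    name: str,
    feature_maps: int = DEFAULT_FEATURE_MAPS,
    fc_sizes: Sequence[int] = DEFAULT_FC_SIZES,
    dropout: float = DEFAULT_DROPOUT,
    input_shape: Sequence[int] = DEFAULT_INPUT_SHAPE,
) -> ModelConfig:
    """A named architecture preset (see module docstring)."""
    if name not in _PRESET_TABLES:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    branches = tuple(
        BranchSpec(bname, tuple(ConvSpec(k, s, feature_maps)
                                for k, s in layers))
        for bname, layers in _PRESET_TABLES[name].items()
    )
    return ModelConfig(branches, tuple(fc_sizes), 2, dropout,
                       tuple(input_shape))


def output_shapes(config: ModelConfig) -> dict[str, list[tuple[int, int, int]]]:
    """Per-branch, per-layer valid-convolution output extents.

    Raises :class:`ConfigurationError` naming the first layer whose kernel
    no longer fits its input.
    """
    result: dict[str, list[tuple[int, int, int]]] = {}
    for branch in config.branches:
        shape = tuple(config.input_shape)
        shapes = []
        for i, spec in enumerate(branch.layers):
            out = tuple(
                nn.conv_output_extent(e, k, s)
                for e, k, s in zip(shape, spec.kernel, spec.stride)
            )
            if any(o < 1 for o in out):
                raise ConfigurationError(
                    f"branch {branch.name} layer {i + 1}: kernel "
                    f"{spec.kernel} does not fit input extent {shape}"
                )
            shapes.append(out)
            shape = out
        result[branch.name] = shapes
    return result


class Model:
    """A built multi-branch 3D CNN bound to its configuration."""

    def __init__(self, config: ModelConfig, net: nn.MultiBranchNet, seed: int):
        self.config = config
        self.net = net
        self.seed = seed

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters

    def forward(self, batch: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        self._check_batch(batch)
        return self.net.forward(batch, training, rng)

    def predict_proba(self, batch: np.ndarray,
                      batch_size: int = 64) -> np.ndarray:
        """Class probabilities, columns ordered (y = 0, y = 1)."""
        from .losses import softmax  # local import avoids a cycle

        self._check_batch(batch)
        out = []
        for i in range(0, batch.shape[0], batch_size):
            logits = self.net.forward(batch[i:i + batch_size], training=False)
            out.append(softmax(logits))
        return np.concatenate(out, axis=0)

    def predict(self, batch: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return np.argmax(self.predict_proba(batch, batch_size), axis=1)

    def predict_proba_windows(self, windows: np.ndarray,
                              channel_names: Sequence[str],
                              layout: ElectrodeLayout) -> np.ndarray:
        batch = segments_to_batch(windows, channel_names, layout)
        return self.predict_proba(batch)

    def _check_batch(self, batch: np.ndarray) -> None:
        expected = (*self.config.input_shape, 1)
        if batch.ndim != 5 or batch.shape[1:] != expected:
            raise ConfigurationError(
                f"batch shape {batch.shape} does not match (n, {expected})")

    # -- checkpointing ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint with the config embedded."""
        arrays = {f"param_{i}": p for i, p in enumerate(self.net.parameters())}
        np.savez(path, config=self.config.to_json(), seed=self.seed, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Model":
        with np.load(path, allow_pickle=False) as data:
            config = ModelConfig.from_json(str(data["config"]))
            seed = int(data["seed"])
            model = build(config, seed)
            n = len(model.net.parameters())
            model.net.set_weights([data[f"param_{i}"] for i in range(n)])
        return model


def build(config: ModelConfig, seed: int, dtype=nn.DEFAULT_DTYPE) -> Model:
    """Construct a trainable model with Glorot-initialized weights.

    The same seed always yields bitwise-identical initial parameters.
    """
    shapes = output_shapes(config)  # validates conv arithmetic
    rng = np.random.default_rng(seed)
    branches = []
    flat_total = 0
    for branch in config.branches:
        layers: list[nn.Layer] = []
        c_in = 1
        for spec in branch.layers:
            layers.append(nn.Conv3D(c_in, spec.feature_maps, spec.kernel,
                                    spec.stride, rng, dtype=dtype))
            layers.append(nn.ReLU())
            c_in = spec.feature_maps
        branches.append(layers)
        flat_total += c_in * int(np.prod(shapes[branch.name][-1]))
    head: list[nn.Layer] = []
    n_in = flat_total
    for width in config.fc_sizes:
        head.append(nn.Dense(n_in, width, rng, dtype=dtype))
        head.append(nn.ReLU())
        head.append(nn.Dropout(config.dropout))
        n_in = width
    head.append(nn.Dense(n_in, config.n_classes, rng, dtype=dtype))
    return Model(config, nn.MultiBranchNet(branches, head), seed)


def predict_proba(model: Model, batch: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`Model.predict_proba`."""
    return model.predict_proba(batch)
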