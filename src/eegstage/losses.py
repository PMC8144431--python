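"""Binary cross-entropy and the alpha-balanced, scaled focal loss.

With p the model's probability for the y = 1 class and

    p_t = p        if y = 1
        = 1 - p    otherwise,

cross-entropy is CE(p_t) = -log(p_t) and the focal loss is

    FL(p_t) = -alpha_t (1 - p_t)^gamma log(p_t) * scale.

The modulating factor ``(1 - p_t)^gamma`` down-weights well-classified
("easy") examples so training concentrates on hard ones; ``gamma >= 0`` is
the focusing parameter and gamma = 0, alpha_t = 1, scale = 1 recovers CE
exactly.  ``alpha`` balances class frequencies and can be derived from crop
counts as alpha = num_c2 / (num_c1 + num_c2) with alpha_t = alpha when y = 1
and 1 - alpha when y = 0.  The scale factor (default 1000 when focusing is
on) keeps the down-weighted loss large enough that early stopping does not
fire on a numerically tiny but still-decreasing cost.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np

from .cropping import ClassCounts

#: Probabilities are clamped to [EPS, 1] inside logs to avoid -log(0).
EPS = 1e-12


@dataclass(frozen=True)
class LossParams:
    """Focal-loss configuration.

    alpha may be a number in [0, 1], the string "auto" (derive from the
    training-set class counts), or None (alpha_t = 1, no class weighting).
    """

    gamma: float = 0.0
    alpha: Union[float, str, None] = None
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if isinstance(self.alpha, (int, float)) and not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if isinstance(self.alpha, str) and self.alpha != "auto":
            raise ValueError("alpha must be a number, 'auto', or None")
        if not self.scale > 0:
            raise ValueError("scale must be positive")

    @classmethod
    def ce(cls) -> "LossParams":
        """Plain cross-entropy."""
        return cls(gamma=0.0, alpha=None, scale=1.0)

    @classmethod
    def focal(cls, gamma: float, alpha: Union[float, str, None] = "auto",
              scale: float = 1000.0) -> "LossParams":
        return cls(gamma=gamma, alpha=alpha, scale=scale)

    def resolve_alpha(self, counts: ClassCounts | None = None) -> "LossParams":
        """Replace alpha='auto' with the numeric value from class counts."""
        if self.alpha == "auto":
            if counts is None:
                raise ValueError("alpha='auto' needs class counts")
            return replace(self, alpha=alpha_from_counts(counts))
        return self

    def to_dict(self) -> dict:
        return {"gamma": self.gamma, "alpha": self.alpha, "scale": self.scale}

    @classmethod
    def from_dict(cls, d: dict) -> "LossParams":
        return cls(**d)


def p_t(p, y):
    """Probability assigned to the true class: p if y = 1 else 1 - p."""
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p must lie in [0, 1]")
    return np.where(y == 1, p, 1.0 - p)


def cross_entropy(p, y):
    """Binary cross-entropy -log(p_t), clamped at EPS."""
    pt = np.clip(p_t(p, y), EPS, 1.0)
    return -np.log(pt)


def alpha_from_counts(counts: ClassCounts) -> float:
    """alpha = num_c2 / (num_c1 + num_c2): the y = 1 class's weight equals
    the other class's share, so the rarer class is weighted up."""
    if counts.total == 0:
        raise ValueError("both class counts are zero")
    return counts.num_c2 / counts.total


def alpha_t(alpha: Union[float, None], y):
    """Per-example class weight: alpha when y = 1, 1 - alpha when y = 0."""
    if alpha is None:
        return np.ones_like(np.asarray(y, dtype=np.float64))
    return np.where(np.asarray(y) == 1, alpha, 1.0 - alpha)


def modulating_factor(pt, gamma: float):
    """(1 - p_t)^gamma, the easy-example down-weighting factor."""
    return np.power(np.clip(1.0 - np.asarray(pt, dtype=np.float64), 0.0, 1.0),
                    gamma)


def focal_loss(p, y, params: LossParams, counts: ClassCounts | None = None):
    """Per-example focal loss -alpha_t (1-p_t)^gamma log(p_t) * scale."""
    params = params.resolve_alpha(counts)
    pt = np.clip(p_t(p, y), EPS, 1.0)
    a = alpha_t(params.alpha, y)
    return params.scale * a * modulating_factor(pt, params.gamma) * -np.log(pt)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def loss_and_grad(
    logits: np.ndarray, y: np.ndarray, params: LossParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-example losses and gradient w.r.t. the two output logits.

    The network's two softmax nodes are ordered (class 2, class 1) = (y = 0,
    y = 1), i.e. column 1 holds p, the probability of the y = 1 class.
    ``params.alpha`` must already be numeric (see ``resolve_alpha``).

    For FL(p_t) with g = dFL/dp_t, the chain rule through the softmax gives
    dFL/dz_j = g * p_t * (delta_{j,y-node} - p_j).
    """
    if params.alpha == "auto":
        raise ValueError("resolve alpha before computing gradients")
    probs = softmax(logits)
    y = np.asarray(y)
    n = probs.shape[0]
    pt = np.clip(probs[np.arange(n), y], EPS, 1.0 - EPS)
    a = alpha_t(params.alpha, y)
    one_m = np.clip(1.0 - pt, EPS, 1.0)
    mod = one_m ** params.gamma
    losses = params.scale * a * mod * -np.log(pt)

    # g = dFL/dp_t = alpha_t*scale * [gamma (1-pt)^(g-1) log(pt) - (1-pt)^g / pt]
    if params.gamma == 0:
        g = params.scale * a * (-1.0 / pt)
    else:
        g = params.scale * a * (
            params.gamma * one_m ** (params.gamma - 1.0) * np.log(pt)
            - mod / pt
        )
    delta = np.zeros_like(probs)
    delta[np.arange(n), y] = 1.0
    dlogits = (g * pt)[:, None] * (delta - probs)
    return losses, dlogits
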