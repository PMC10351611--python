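"""The four image-level-label losses and their weighted combination.

All four are driven only by the image-level label ``y``:

* foreground loss: mean over pixels of ``(1 - m_s) * m_p`` - wherever the
  spatial attention is low, the probability map is pushed towards zero, so
  probability mass can survive only under high spatial attention;
* background loss: mean over pixels of ``(1 - y) * m_p`` - on normal images
  the probability map is pushed to zero everywhere (positives contribute
  exactly zero, so stones are never learned as background);
* consistency loss: binary cross-entropy between ``y`` and the global
  average of ``m_p`` (its "dominant response");
* classification loss: binary cross-entropy between ``y`` and the
  classifier's stone probability.

The source formulation prints the two cross-entropies with a ``+`` on the
negative-class term, which is unbounded below; the standard (sign-corrected)
binary cross-entropy is used by default and the literal printed form is kept
behind ``literal_sign=True`` for audit.

Functions accept plain arrays or autodiff tensors and return scalars of the
same flavour; maps may be a single image or a batch (leading axis), and a
batch reduces by the mean of per-image losses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, as_tensor
from .errors import ValidationError

__all__ = [
    "EPS",
    "LossWeights",
    "LossBundle",
    "foreground_loss",
    "background_loss",
    "consistency_loss",
    "classification_loss",
    "total_loss",
]

EPS = 1e-7  # clamp for the logarithms


@dataclass(frozen=True)
class LossWeights:
    """Weights of the combined objective; defaults down-weight background."""

    fg: float = 1.0
    bg: float = 0.5
    con: float = 1.0
    cls: float = 1.0

    def __post_init__(self):
        if min(self.fg, self.bg, self.con, self.cls) < 0:
            raise ValidationError("loss weights must be non-negative")


@dataclass
class LossBundle:
    fg: float
    bg: float
    con: float
    cls: float
    total: float
    weights: LossWeights

    def as_dict(self) -> dict[str, float]:
        return {
            "loss_fg": self.fg,
            "loss_bg": self.bg,
            "loss_con": self.con,
            "loss_cls": self.cls,
            "loss_total": self.total,
        }


def _per_image_mean(x: Tensor) -> Tensor:
    """Per-image pixel mean.

    0-d/1-d inputs are already per-image scalars and pass through; a 2-d
    input is one map (scalar mean); 3-d/4-d inputs are batches with a
    leading image axis -> (N,).
    """
    if x.ndim <= 1:
        return x
    if x.ndim == 2:
        return ad.reduce_mean(x)
    return ad.reduce_mean(ad.reshape(x, (x.shape[0], -1)), axis=1)


def _as_label_array(y, n: int) -> np.ndarray:
    arr = np.asarray(y.data if isinstance(y, Tensor) else y, dtype=float)
    if not np.all(np.isin(arr, (0.0, 1.0))):
        raise ValidationError(f"labels must be 0 or 1, got {arr!r}")
    if arr.ndim == 0:
        arr = np.full((n,), float(arr)) if n > 1 else arr
    return arr


def _batch_mean(x: Tensor) -> Tensor:
    return ad.reduce_mean(x) if x.ndim else x


def foreground_loss(m_s, m_p) -> Tensor:
    """Mean over pixels of (1 - m_s) * m_p."""
    m_s, m_p = as_tensor(m_s), as_tensor(m_p)
    if m_s.shape != m_p.shape:
        raise ValidationError(f"shape mismatch: m_s {m_s.shape} vs m_p {m_p.shape}")
    return _batch_mean(_per_image_mean((1.0 - m_s) * m_p))


def background_loss(m_p, y) -> Tensor:
    """Mean over pixels of (1 - y) * m_p; exactly zero for stone images."""
    m_p = as_tensor(m_p)
    per = _per_image_mean(m_p)
    n = per.shape[0] if per.ndim else 1
    yv = _as_label_array(y, n)
    return _batch_mean(per * (1.0 - yv))


def _bce(p: Tensor, y: np.ndarray, literal_sign: bool) -> Tensor:
    p = ad.clip(p, EPS, 1.0 - EPS)
    neg_term = (1.0 - y) * ad.log(1.0 - p)
    if literal_sign:
        return -(y * ad.log(p)) + neg_term
    return -(y * ad.log(p)) - neg_term


def consistency_loss(m_p, y, literal_sign: bool = False) -> Tensor:
    """BCE between y and the global average pooling of m_p."""
    m_p = as_tensor(m_p)
    pbar = _per_image_mean(m_p)
    n = pbar.shape[0] if pbar.ndim else 1
    yv = _as_label_array(y, n)
    return _batch_mean(_bce(pbar, yv, literal_sign))


def classification_loss(y_hat, y, literal_sign: bool = False) -> Tensor:
    """BCE between y and the classifier's stone probability."""
    y_hat = as_tensor(y_hat)
    n = y_hat.shape[0] if y_hat.ndim else 1
    yv = _as_label_array(y, n)
    return _batch_mean(_bce(y_hat, yv, literal_sign))


def total_loss(fg, bg, con, cls, weights: LossWeights = LossWeights()) -> Tensor:
    """Weighted sum of the four components."""
    return (
        weights.fg * as_tensor(fg)
        + weights.bg * as_tensor(bg)
        + weights.con * as_tensor(con)
        + weights.cls * as_tensor(cls)
    )


def compute_losses(outputs, y, weights: LossWeights = LossWeights(),
                   literal_sign: bool = False) -> tuple[Tensor, LossBundle]:
    """All four losses from a model's outputs; returns the differentiable
    total and a float bundle for logging."""
    m_s, m_p, y_hat = outputs.m_s, outputs.m_p, outputs.y_hat
    fg = foreground_loss(m_s, m_p)
    bg = background_loss(m_p, y)
    con = consistency_loss(m_p, y, literal_sign)
    cls = classification_loss(y_hat, y, literal_sign)
    total = total_loss(fg, bg, con, cls, weights)
    bundle = LossBundle(fg.item(), bg.item(), con.item(), cls.item(),
                        total.item(), weights)
    return total, bundle
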