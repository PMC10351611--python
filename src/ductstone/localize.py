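"""Inference-time stone localization from the attention maps.

The stone attention map is the channel-wise average of the attended decoder
feature ``m_s * (m_c * f_U)``, gated elementwise by the probability map.
Two polarities of the gate exist because the source formulation multiplies
by ``(1 - m_p)`` while its own losses make ``m_p`` a stone-evidence map:

* ``"one_minus_p"`` (default): multiply by ``1 - m_p``;
* ``"p"``: multiply by ``m_p`` (the polarity the turnkey experiment uses).

The map is normalized by its maximum, thresholded (default 0.6), and the
largest 8-connected component's tight half-open bounding box is returned -
but only when the classifier also votes positive (score >= 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .autodiff import Tensor
from .errors import ConfigError, ValidationError
from .io import BoundingBox, DetectionRecord
from .network import ModelOutputs, StoneDetector

__all__ = [
    "LocalizerConfig",
    "stone_attention_map",
    "normalize_map",
    "extract_box",
    "detect",
]

_POLARITIES = ("one_minus_p", "p")


@dataclass(frozen=True)
class LocalizerConfig:
    threshold: float = 0.6
    decision_threshold: float = 0.5
    polarity: str = "one_minus_p"

    def __post_init__(self):
        if not (0 < self.threshold < 1) or not (0 < self.decision_threshold < 1):
            raise ConfigError("thresholds must lie in (0, 1)")
        if self.polarity not in _POLARITIES:
            raise ConfigError(f"polarity must be one of {_POLARITIES}")


def _arr(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def stone_attention_map(f_U, m_c, m_s, m_p, polarity: str = "one_minus_p") -> np.ndarray:
    """Channel mean of m_s*(m_c*f_U), gated by (1-m_p) or m_p; one image.

    f_U: (C, H, W); m_c: (C,); m_s, m_p: (H, W) or (1, H, W).
    """
    if polarity not in _POLARITIES:
        raise ConfigError(f"polarity must be one of {_POLARITIES}")
    f_U, m_c, m_s, m_p = (_arr(v).astype(float) for v in (f_U, m_c, m_s, m_p))
    m_s = m_s.reshape(f_U.shape[1:])
    m_p = m_p.reshape(f_U.shape[1:])
    attended = m_s[None] * (m_c[:, None, None] * f_U)
    gate = (1.0 - m_p) if polarity == "one_minus_p" else m_p
    return attended.mean(axis=0) * gate


def normalize_map(m_a) -> np.ndarray:
    """Divide by the maximum; an all-zero map passes through unchanged."""
    m_a = _arr(m_a).astype(float)
    if not np.all(np.isfinite(m_a)):
        raise ValidationError("attention map contains non-finite values")
    if m_a.min() < 0:
        raise ValidationError("attention map has negative entries (polarity misuse?)")
    peak = m_a.max()
    return m_a if peak == 0 else m_a / peak


def extract_box(
    m_a_norm: np.ndarray,
    threshold: float = 0.6,
    score: float | None = None,
    decision_threshold: float = 0.5,
) -> BoundingBox | None:
    """Largest 8-connected supra-threshold component's tight bounding box.

    Returns None when the classifier score is below the decision threshold
    or no pixel exceeds ``threshold``. Ties between equal-sized components
    break towards the higher attention peak.
    """
    m = np.asarray(m_a_norm, dtype=float)
    if m.min() < 0 or m.max() > 1 + 1e-9:
        raise ValidationError("extract_box expects a normalized map in [0, 1]")
    if score is not None and score < decision_threshold:
        return None
    mask = m > threshold
    if not mask.any():
        return None
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    sizes = np.bincount(labels.ravel())[1:]
    best_size = sizes.max()
    candidates = np.nonzero(sizes == best_size)[0] + 1
    if len(candidates) > 1:
        peaks = ndimage.maximum(m, labels=labels, index=candidates)
        best = candidates[int(np.argmax(peaks))]
    else:
        best = candidates[0]
    rows, cols = np.nonzero(labels == best)
    return BoundingBox(int(cols.min()), int(rows.min()),
                       int(cols.max()) + 1, int(rows.max()) + 1)


def detect(image, model: StoneDetector, config: LocalizerConfig = LocalizerConfig(),
           image_id: str = "", outputs: ModelOutputs | None = None) -> DetectionRecord:
    """Classify one image and, if positive, localize the stone."""
    if outputs is None:
        model.eval()
        outputs = model.forward(np.asarray(image)[None] if np.asarray(image).ndim == 2 else image)
    score = float(outputs.y_hat.data.reshape(-1)[0])
    m_a = stone_attention_map(
        outputs.f_U.data[0], outputs.m_c.data[0], outputs.m_s.data[0],
        outputs.m_p.data[0], polarity=config.polarity,
    )
    box = extract_box(normalize_map(m_a), config.threshold, score,
                      config.decision_threshold)
    return DetectionRecord(image_id, score, box)
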