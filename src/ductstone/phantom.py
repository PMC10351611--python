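"""Synthetic abdominal-slice phantoms for the weakly-supervised stone task.

Real common-bile-duct stone CT data is private; this module produces 2-D
grayscale phantoms with the statistical structure the detector exploits and
the structure that defeats naive saliency baselines:

* a smooth low-frequency tissue background plus i.i.d. Gaussian noise,
* bright bone-like distractors (discs/rings) in *every* image, placed
  outside the duct region, brighter than any stone, and
* on positive images only, one small moderately bright ellipse (the stone)
  with a Gaussian-smoothed edge, confined to a restricted duct region.

Because the distractors are the brightest structures, a detector that just
chases high intensity localizes bone, not stones - the failure mode the
attention losses are designed to avoid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigError, ValidationError
from .io import (
    BoundingBox,
    DatasetManifest,
    ManifestRecord,
    write_boxes,
    write_image,
    write_manifest,
)

__all__ = [
    "PhantomConfig",
    "LabeledSlice",
    "generate_phantom",
    "generate_dataset",
    "split_dataset",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and intensity statistics of the synthetic slices.

    duct_region is a normalized (x0, y0, x1, y1) rectangle in which stones
    may appear; stone_contrast is the intensity uplift of the stone over its
    local background (intensity units on the [0, 1] scale).
    """

    width: int = 96
    height: int = 96
    stone_radius_range: tuple[float, float] = (2.0, 6.0)
    stone_contrast: float = 0.35
    duct_region: tuple[float, float, float, float] = (0.32, 0.32, 0.68, 0.68)
    n_distractors: int = 3
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.width < 32 or self.height < 32:
            raise ConfigError("phantom size must be at least 32x32")
        rmin, rmax = self.stone_radius_range
        if rmin < 1 or rmax < rmin:
            raise ConfigError(f"invalid stone_radius_range {self.stone_radius_range}")
        if rmax >= min(self.width, self.height) / 4:
            raise ConfigError("max stone radius must be < min(width, height)/4")
        if self.stone_contrast <= 0:
            raise ConfigError("stone_contrast must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        x0, y0, x1, y1 = self.duct_region
        if not (0 <= x0 < x1 <= 1 and 0 <= y0 < y1 <= 1):
            raise ConfigError(f"invalid duct_region {self.duct_region}")
        if self.n_distractors < 0:
            raise ConfigError("n_distractors must be non-negative")

    def duct_rect_px(self) -> tuple[int, int, int, int]:
        """Duct rectangle in pixel coordinates (x0, y0, x1, y1), half-open."""
        x0, y0, x1, y1 = self.duct_region
        return (
            int(round(x0 * self.width)),
            int(round(y0 * self.height)),
            int(round(x1 * self.width)),
            int(round(y1 * self.height)),
        )


@dataclass
class LabeledSlice:
    """One phantom with its image-level label and (for positives) the
    ground-truth stone box used only at evaluation time."""

    image: np.ndarray
    label: int
    image_id: str
    gt_box: BoundingBox | None = None

    def __post_init__(self):
        if self.image.ndim != 2:
            raise ValidationError("image must be 2-D")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValidationError("intensities must lie in [0, 1]")
        if self.label not in (0, 1):
            raise ValidationError(f"label {self.label} not in {{0,1}}")
        if self.label == 0 and self.gt_box is not None:
            raise ValidationError("normal slice must not carry a gt_box")
        if self.label == 1:
            if self.gt_box is None:
                raise ValidationError("stone slice must carry a gt_box")
            h, w = self.image.shape
            if not self.gt_box.inside(h, w):
                raise ValidationError("gt_box outside image bounds")


def _background(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    field_ = gaussian_filter(
        rng.normal(size=(cfg.height, cfg.width)), sigma=min(cfg.height, cfg.width) / 8
    )
    lo, hi = field_.min(), field_.max()
    span = hi - lo if hi > lo else 1.0
    return 0.20 + 0.22 * (field_ - lo) / span


def _add_distractors(img: np.ndarray, cfg: PhantomConfig, rng: np.random.Generator) -> None:
    """Bone-like bright discs/rings, strictly outside the duct rectangle."""
    h, w = img.shape
    dx0, dy0, dx1, dy1 = cfg.duct_rect_px()
    Y, X = np.mgrid[0:h, 0:w]
    for _ in range(cfg.n_distractors):
        for _try in range(200):
            r = rng.uniform(2.5, 6.0)
            cx = rng.uniform(r + 1, w - r - 1)
            cy = rng.uniform(r + 1, h - r - 1)
            # reject if the distractor's bounding square touches the duct
            if not (cx + r < dx0 or cx - r > dx1 or cy + r < dy0 or cy - r > dy1):
                continue
            break
        else:  # pragma: no cover - only for pathological duct regions
            continue
        d2 = (X - cx) ** 2 + (Y - cy) ** 2
        mask = (d2 <= r * r).astype(float)
        if rng.random() < 0.5:  # ring
            mask -= (d2 <= (0.5 * r) ** 2).astype(float)
        mask = gaussian_filter(mask, sigma=0.6)
        level = rng.uniform(0.88, 0.98)
        np.maximum(img, level * mask, out=img)


def _stone_mask(cfg: PhantomConfig, rng: np.random.Generator,
                shape: tuple[int, int]) -> tuple[np.ndarray, BoundingBox]:
    h, w = shape
    rmin, rmax = cfg.stone_radius_range
    a = rng.uniform(rmin, rmax)
    b = rng.uniform(rmin, rmax)
    theta = rng.uniform(0.0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    ex = float(np.hypot(a * ct, b * st))
    ey = float(np.hypot(a * st, b * ct))
    dx0, dy0, dx1, dy1 = cfg.duct_rect_px()
    mx, my = int(np.ceil(ex)) + 1, int(np.ceil(ey)) + 1
    if dx0 + mx >= dx1 - mx or dy0 + my >= dy1 - my:
        raise ConfigError("duct_region too small for the configured stone radii")
    cx = rng.uniform(dx0 + mx, dx1 - mx)
    cy = rng.uniform(dy0 + my, dy1 - my)
    Y, X = np.mgrid[0:h, 0:w]
    u = (X - cx) * ct + (Y - cy) * st
    v = -(X - cx) * st + (Y - cy) * ct
    mask = (u * u) / (a * a) + (v * v) / (b * b) <= 1.0
    rows, cols = np.nonzero(mask)
    box = BoundingBox(int(cols.min()), int(rows.min()),
                      int(cols.max()) + 1, int(rows.max()) + 1)
    return mask.astype(float), box


def generate_phantom(config: PhantomConfig, with_stone: bool,
                     seed: int | None = None, image_id: str | None = None) -> LabeledSlice:
    """Deterministically synthesize one slice (seed defaults to config.seed)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    img = _background(config, rng)
    _add_distractors(img, config, rng)
    gt_box = None
    if with_stone:
        mask, gt_box = _stone_mask(config, rng, img.shape)
        smooth = gaussian_filter(mask, sigma=0.7)
        # scale so the mask interior reaches the full configured contrast
        smooth = smooth / max(smooth.max(), 1e-12)
        img = img + config.stone_contrast * smooth
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    if image_id is None:
        image_id = ("stone" if with_stone else "normal") + f"_{rng.integers(1 << 30):09d}"
    return LabeledSlice(img, int(with_stone), image_id, gt_box)


def generate_dataset(
    n_stone: int,
    n_normal: int | None = None,
    config: PhantomConfig = PhantomConfig(),
    out_dir: str | Path = "phantoms",
) -> DatasetManifest:
    """Write a labelled phantom dataset (PNGs + manifest.csv + boxes.csv).

    The default normal count is twice the stone count, mirroring the curated
    1:2 class ratio of the clinical setting the task emulates.
    """
    if n_stone < 0 or (n_normal is not None and n_normal < 0):
        raise ConfigError("counts must be non-negative")
    if n_normal is None:
        n_normal = 2 * n_stone
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    try:
        img_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ConfigError(f"cannot create output directory {out_dir}: {exc}") from exc

    seeds = np.random.SeedSequence(config.seed).generate_state(n_stone + n_normal)
    records: list[ManifestRecord] = []
    boxes: dict[str, BoundingBox] = {}
    for i in range(n_stone + n_normal):
        with_stone = i < n_stone
        image_id = f"stone_{i:04d}" if with_stone else f"normal_{i - n_stone:04d}"
        sl = generate_phantom(config, with_stone, seed=int(seeds[i]), image_id=image_id)
        path = img_dir / f"{image_id}.png"
        write_image(sl.image, path)
        records.append(ManifestRecord(image_id, str(path), sl.label))
        if sl.gt_box is not None:
            boxes[image_id] = sl.gt_box
    manifest = DatasetManifest(records)
    write_manifest(manifest, out_dir / "manifest.csv")
    write_boxes(boxes, out_dir / "boxes.csv")
    return manifest


def split_dataset(
    manifest: DatasetManifest,
    train_frac: float,
    val_frac: float = 0.0,
    seed: int = 0,
) -> tuple[DatasetManifest, DatasetManifest, DatasetManifest]:
    """Label-stratified (train, val, test) partition; splits are disjoint
    and exhaustive, preserving the manifest's record order within each."""
    if not (0 < train_frac <= 1) or val_frac < 0 or train_frac + val_frac > 1:
        raise ConfigError(f"invalid fractions train={train_frac}, val={val_frac}")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    test_idx: list[int] = []
    for label in (0, 1):
        idx = [i for i, r in enumerate(manifest.records) if r.label == label]
        perm = rng.permutation(len(idx))
        n_train = int(round(train_frac * len(idx)))
        n_val = int(round(val_frac * len(idx)))
        n_val = min(n_val, len(idx) - n_train)
        chosen = [idx[p] for p in perm]
        train_idx += chosen[:n_train]
        val_idx += chosen[n_train : n_train + n_val]
        test_idx += chosen[n_train + n_val :]
    return (
        manifest.subset(sorted(train_idx), "train"),
        manifest.subset(sorted(val_idx), "val"),
        manifest.subset(sorted(test_idx), "test"),
    )
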