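"""Image, manifest, box and detection I/O with a fixed normalization contract.

Coordinate convention (used everywhere in the package): x is the column
index, y the row index, origin at the top-left; boxes are 0-based and
half-open, ``(x_min, y_min, x_max, y_max)``.

Intensities are always rescaled to [0, 1] on read: 8-bit PNG by /255,
16-bit PNG by /65535, DICOM by optional window level/width followed by
min-max rescale.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from PIL import Image

from .errors import ImageIOError, ValidationError

__all__ = [
    "BoundingBox",
    "DetectionRecord",
    "ManifestRecord",
    "DatasetManifest",
    "read_image",
    "write_image",
    "read_manifest",
    "write_manifest",
    "read_boxes",
    "write_boxes",
    "write_detections",
    "read_detections",
]


@dataclass(frozen=True)
class BoundingBox:
    """Half-open pixel box: pixels (y, x) with x_min <= x < x_max etc."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self):
        if self.x_min >= self.x_max or self.y_min >= self.y_max:
            raise ValidationError(f"degenerate box {self!r}")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return self.width * self.height

    def inside(self, height: int, width: int) -> bool:
        return 0 <= self.x_min and 0 <= self.y_min and self.x_max <= width and self.y_max <= height

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


@dataclass(frozen=True)
class DetectionRecord:
    """One image's classification score and (optional) predicted box."""

    image_id: str
    score: float
    box: BoundingBox | None = None

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValidationError(f"score {self.score} outside [0, 1]")


@dataclass(frozen=True)
class ManifestRecord:
    image_id: str
    path: str
    label: int


@dataclass
class DatasetManifest:
    """Ordered image-level label records (the weak annotation set)."""

    records: list[ManifestRecord]
    split: str = "all"

    def __post_init__(self):
        ids = [r.image_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate image_id in manifest")
        for r in self.records:
            if r.label not in (0, 1):
                raise ValidationError(f"label {r.label!r} for {r.image_id} not in {{0,1}}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def subset(self, indices: Sequence[int], split: str) -> "DatasetManifest":
        return DatasetManifest([self.records[i] for i in indices], split=split)


# ---- images ------------------------------------------------------------

def read_image(path, target_size: int | None = None,
               window: tuple[float, float] | None = None) -> np.ndarray:
    """Read a grayscale PNG (8/16-bit) or single-slice DICOM as floats in [0, 1].

    ``window`` is an optional DICOM (level, width) applied before rescaling.
    ``target_size`` bilinearly resizes to a square of that side.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such image: {path}")
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        arr = _read_dicom(path, window)
    else:
        try:
            with Image.open(path) as im:
                if im.mode in ("I", "I;16", "I;16B"):
                    arr = np.asarray(im.convert("I"), dtype=np.float64) / 65535.0
                else:
                    arr = np.asarray(im.convert("L"), dtype=np.float64) / 255.0
        except Exception as exc:  # noqa: BLE001 - rewrap with path context
            raise ImageIOError(f"cannot read image {path}: {exc}") from exc
    if target_size is not None and arr.shape != (target_size, target_size):
        im = Image.fromarray((arr * 65535).astype(np.uint16))
        im = im.resize((target_size, target_size), Image.BILINEAR)
        arr = np.asarray(im, dtype=np.float64) / 65535.0
    return np.clip(arr, 0.0, 1.0)


def _read_dicom(path: Path, window: tuple[float, float] | None) -> np.ndarray:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - soft dependency
        raise ImageIOError("DICOM support requires the optional pydicom dependency") from exc
    try:
        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array.astype(np.float64)
    except Exception as exc:  # noqa: BLE001
        raise ImageIOError(f"cannot read DICOM {path}: {exc}") from exc
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    if window is not None:
        level, width = window
        lo, hi = level - width / 2.0, level + width / 2.0
        arr = np.clip(arr, lo, hi)
    lo, hi = arr.min(), arr.max()
    return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)


def write_image(arr: np.ndarray, path) -> None:
    """Write a [0, 1] intensity array as an 8-bit grayscale PNG."""
    a = np.clip(np.asarray(arr, dtype=float), 0.0, 1.0)
    Image.fromarray(np.round(a * 255).astype(np.uint8), mode="L").save(str(path))


# ---- manifests ---------------------------------------------------------

_MANIFEST_COLS = ["image_id", "path", "label"]


def read_manifest(csv_path, split: str = "all") -> DatasetManifest:
    csv_path = Path(csv_path)
    with open(csv_path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != _MANIFEST_COLS:
            raise ValidationError(
                f"{csv_path}: expected header {','.join(_MANIFEST_COLS)}, got {reader.fieldnames}"
            )
        records = []
        seen: set[str] = set()
        for i, row in enumerate(reader, start=1):
            if row["label"] not in ("0", "1"):
                raise ValidationError(f"{csv_path} row {i}: label {row['label']!r} not in {{0,1}}")
            if row["image_id"] in seen:
                raise ValidationError(f"{csv_path} row {i}: duplicate image_id {row['image_id']!r}")
            seen.add(row["image_id"])
            records.append(ManifestRecord(row["image_id"], row["path"], int(row["label"])))
    return DatasetManifest(records, split=split)


def write_manifest(manifest: DatasetManifest, csv_path) -> None:
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MANIFEST_COLS)
        for r in manifest.records:
            writer.writerow([r.image_id, r.path, r.label])


# ---- ground-truth boxes ------------------------------------------------

_BOX_COLS = ["image_id", "x_min", "y_min", "x_max", "y_max"]


def read_boxes(csv_path) -> dict[str, BoundingBox]:
    csv_path = Path(csv_path)
    with open(csv_path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != _BOX_COLS:
            raise ValidationError(
                f"{csv_path}: expected header {','.join(_BOX_COLS)}, got {reader.fieldnames}"
            )
        boxes: dict[str, BoundingBox] = {}
        for i, row in enumerate(reader, start=1):
            if row["image_id"] in boxes:
                raise ValidationError(f"{csv_path} row {i}: duplicate image_id {row['image_id']!r}")
            try:
                box = BoundingBox(int(row["x_min"]), int(row["y_min"]),
                                  int(row["x_max"]), int(row["y_max"]))
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{csv_path} row {i}: {exc}") from exc
            boxes[row["image_id"]] = box
    return boxes


def write_boxes(boxes: Mapping[str, BoundingBox], csv_path) -> None:
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_BOX_COLS)
        for image_id, b in boxes.items():
            writer.writerow([image_id, b.x_min, b.y_min, b.x_max, b.y_max])


# ---- detections (JSON lines) -------------------------------------------

def write_detections(records: Iterable[DetectionRecord], path) -> None:
    try:
        with open(path, "w") as fh:
            for r in records:
                obj = {
                    "image_id": r.image_id,
                    "score": float(r.score),
                    "box": list(r.box.as_tuple()) if r.box is not None else None,
                }
                fh.write(json.dumps(obj) + "\n")
    except OSError as exc:
        raise ImageIOError(f"cannot write detections to {path}: {exc}") from exc


def read_detections(path) -> list[DetectionRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            box = BoundingBox(*obj["box"]) if obj.get("box") is not None else None
            records.append(DetectionRecord(obj["image_id"], float(obj["score"]), box))
    return records
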