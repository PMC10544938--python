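"""Calibrated scan image and trait-table I/O.

Owns the unit and coordinate conventions used everywhere else:

* pixel coordinates are 0-based, row-major (y down);
* bounding boxes are half-open, ``[x0, x1) x [y0, y1)``, so that
  ``area = (x1 - x0) * (y1 - y0)`` without off-by-one corrections;
* physical calibration is carried per image as dots-per-inch (dpi), from
  which the metric scale follows as ``mm_per_px = 25.4 / dpi`` (25.4 mm to
  the inch).  At a typical flatbed-scanner resolution of 600 dpi one pixel
  spans 0.0423 mm.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

MM_PER_INCH = 25.4


def mm_per_pixel(dpi: float) -> float:
    """Metric size of one pixel, in mm, for a scan at ``dpi`` dots per inch.

    Parameters
    ----------
    dpi : float
        Scanner resolution in dots per inch. Must be positive.

    Returns
    -------
    float
        ``25.4 / dpi`` — e.g. 0.0423 mm at 600 dpi.
    """
    if not np.isfinite(dpi) or dpi <= 0:
        raise ValueError(f"dpi must be a positive finite number, got {dpi!r}")
    return MM_PER_INCH / dpi


@dataclass(frozen=True)
class ScanImage:
    """An 8-bit RGB raster with its physical calibration.

    ``pixels`` is H×W×3 uint8 with channel order (R, G, B) regardless of the
    file dialect it was read from. ``dpi`` is stored per image; batches of
    mixed resolution are legal.
    """

    pixels: np.ndarray
    dpi: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one row and column")
        if px.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {px.dtype}")
        if not np.isfinite(self.dpi) or self.dpi <= 0:
            raise ValueError(f"dpi must be positive, got {self.dpi!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def mm_per_px(self) -> float:
        return mm_per_pixel(self.dpi)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class BoundingBox:
    """Half-open axis-aligned pixel box ``[x0, x1) x [y0, y1)`` with a score."""

    x0: float
    y0: float
    x1: float
    y1: float
    score: float = 1.0

    def __post_init__(self) -> None:
        for name in ("x0", "y0", "x1", "y1", "score"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(
                f"degenerate box: ({self.x0}, {self.y0}, {self.x1}, {self.y1})"
            )
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.width * self.height

    def clip(self, img_w: float, img_h: float) -> "BoundingBox":
        """Clip to image bounds; raises if nothing remains."""
        return BoundingBox(
            max(0.0, self.x0),
            max(0.0, self.y0),
            min(float(img_w), self.x1),
            min(float(img_h), self.y1),
            self.score,
        )

    def iou(self, other: "BoundingBox") -> float:
        ix = max(0.0, min(self.x1, other.x1) - max(self.x0, other.x0))
        iy = max(0.0, min(self.y1, other.y1) - max(self.y0, other.y0))
        inter = ix * iy
        union = self.area + other.area - inter
        return inter / union if union > 0 else 0.0

    def to_xywh(self) -> tuple[float, float, float, float]:
        """COCO-style ``[x, y, w, h]`` corner+size representation."""
        return (self.x0, self.y0, self.width, self.height)

    @classmethod
    def from_xywh(
        cls, x: float, y: float, w: float, h: float, score: float = 1.0
    ) -> "BoundingBox":
        return cls(x, y, x + w, y + h, score)


def crop_center(image: ScanImage, out_w: int, out_h: int) -> ScanImage:
    """Centered crop of ``out_w`` x ``out_h`` pixels; dpi is preserved.

    When the margin is odd the extra pixel goes to the bottom/right side
    (floor-division offsets). Raises ``ValueError`` if the requested crop
    exceeds the image.
    """
    h, w = image.pixels.shape[:2]
    if out_w > w or out_h > h or out_w < 1 or out_h < 1:
        raise ValueError(
            f"crop {out_w}x{out_h} does not fit inside image {w}x{h}"
        )
    y0 = (h - out_h) // 2
    x0 = (w - out_w) // 2
    return ScanImage(image.pixels[y0 : y0 + out_h, x0 : x0 + out_w].copy(), image.dpi)


def split_dataset(
    items: Sequence, ratio: Sequence[int], seed: int
) -> list[list]:
    """Shuffle ``items`` with ``seed`` and partition them proportionally.

    ``ratio`` is a tuple of non-negative integer parts (e.g. ``(2, 1, 1)``
    for train/validation/test). Sizes are proportional to the parts with any
    remainder distributed one item at a time to the earliest parts, so the
    partition sizes are deterministic in the input length. The partitions
    are disjoint and their union is the input.
    """
    items = list(items)
    if not items:
        raise ValueError("cannot split an empty item list")
    parts = [int(r) for r in ratio]
    if any(r < 0 for r in parts) or sum(parts) <= 0:
        raise ValueError(f"ratio parts must be non-negative and sum > 0: {ratio}")
    n = len(items)
    total = sum(parts)
    sizes = [n * r // total for r in parts]
    rem = n - sum(sizes)
    for i in range(len(sizes)):
        if rem == 0:
            break
        if parts[i] > 0:
            sizes[i] += 1
            rem -= 1
    order = np.random.default_rng(seed).permutation(n)
    out: list[list] = []
    start = 0
    for s in sizes:
        out.append([items[order[j]] for j in range(start, start + s)])
        start += s
    return out


def read_scan(path: str | Path, dpi: float | None = None) -> ScanImage:
    """Read a PNG/TIFF/JPEG file as an 8-bit RGB :class:`ScanImage`.

    The dpi is taken from the file metadata when present; pass ``dpi`` to
    override or when the file carries none.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with Image.open(path) as im:
        file_dpi = None
        info_dpi = im.info.get("dpi")
        if info_dpi:
            file_dpi = float(info_dpi[0])
        rgb = np.asarray(im.convert("RGB"), dtype=np.uint8)
    use_dpi = dpi if dpi is not None else file_dpi
    if use_dpi is None or use_dpi <= 0:
        raise ValueError(
            f"{path}: no dpi in file metadata; pass dpi= explicitly"
        )
    return ScanImage(rgb, float(use_dpi))


def write_scan(path: str | Path, image: ScanImage) -> None:
    """Write an RGB image to disk, embedding its dpi in the file metadata."""
    Image.fromarray(image.pixels, mode="RGB").save(
        Path(path), dpi=(image.dpi, image.dpi)
    )


def write_traits(path: str | Path, rows: Iterable[dict]) -> None:
    """Write trait rows to CSV (comma-separated, header, UTF-8, '.' decimal).

    Numeric values survive a round-trip through :func:`read_traits` to at
    least 6 significant digits (they are written with repr precision).
    """
    rows = list(rows)
    if not rows:
        raise ValueError("no trait rows to write")
    df = pd.DataFrame(rows)
    df.to_csv(Path(path), index=False, encoding="utf-8")


def read_traits(path: str | Path) -> pd.DataFrame:
    """Read a trait CSV written by :func:`write_traits`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as e:
        raise ValueError(f"{path}: malformed trait CSV: {e}") from e
    if df.empty:
        raise ValueError(f"{path}: trait CSV holds no rows")
    return df


# ---------------------------------------------------------------------------
# COCO-style annotation JSON
# ---------------------------------------------------------------------------

def boxes_to_coco(
    image_entries: Sequence[dict],
    boxes_per_image: Sequence[Sequence[BoundingBox]],
    category_name: str = "grain",
) -> dict:
    """Assemble a COCO-style annotation dict from per-image box lists.

    ``image_entries`` carry at least ``id``, ``width``, ``height`` (and
    usually ``file_name``). Boxes are stored as COCO ``bbox = [x, y, w, h]``
    with the detection score under ``score``.
    """
    annotations = []
    ann_id = 1
    for entry, boxes in zip(image_entries, boxes_per_image, strict=True):
        for b in boxes:
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": entry["id"],
                    "category_id": 1,
                    "bbox": list(b.to_xywh()),
                    "area": b.area,
                    "iscrowd": 0,
                    "score": b.score,
                }
            )
            ann_id += 1
    return {
        "images": list(image_entries),
        "annotations": annotations,
        "categories": [{"id": 1, "name": category_name}],
    }


def coco_to_boxes(coco: dict) -> dict[int, list[BoundingBox]]:
    """Per-image-id lists of :class:`BoundingBox` from a COCO-style dict."""
    out: dict[int, list[BoundingBox]] = {e["id"]: [] for e in coco.get("images", [])}
    for ann in coco.get("annotations", []):
        x, y, w, h = ann["bbox"]
        box = BoundingBox.from_xywh(x, y, w, h, float(ann.get("score", 1.0)))
        out.setdefault(ann["image_id"], []).append(box)
    return out


def write_coco(path: str | Path, coco: dict) -> None:
    def _np_safe(o):
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(
        json.dumps(coco, indent=1, default=_np_safe), encoding="utf-8"
    )


def read_coco(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return json.loads(path.read_text(encoding="utf-8"))
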