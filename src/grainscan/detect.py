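"""Grain detection on panicle scans.

Two detectors share one output contract (a list of scored
:class:`~grainscan.scan_io.BoundingBox`):

* :func:`detect_baseline` — a deterministic classical detector: red-channel
  Otsu segmentation, connected components, and distance-transform watershed
  to split touching grains.  Fast, training-free, and exact on
  well-separated grains, it carries the desk-scale pipeline.
* :func:`build_model` — a trainable two-stage detector with multi-scale
  feature-pyramid fusion: a region-proposal stage scores objectness on a
  fused image pyramid, and a second stage classifies and refines pooled
  proposals.  Heads are linear over pyramid features and are trained by
  SGD with momentum, exposing the ``train_step(batch) -> loss`` /
  ``predict(image) -> boxes`` contract.  The default hyperparameters
  (input 1425 x 1700, NMS IoU 0.74, 4000 proposals, SGD lr 0.02,
  momentum 0.9, weight decay 1e-4, 100 epochs) are the configuration a
  full-scale run of the cascade would use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from grainscan.scan_io import BoundingBox, ScanImage
from grainscan.traits import otsu_threshold, red_channel, TraitExtractionError


@dataclass
class DetectorConfig:
    """Hyperparameters of the trainable detector."""

    input_size: tuple[int, int] = (1425, 1700)  # (width, height)
    nms_iou: float = 0.74
    rpn_proposals: int = 4000
    backbone_depth: int = 50
    optimizer: str = "SGD"
    lr: float = 0.02
    momentum: float = 0.9
    weight_decay: float = 0.0001
    max_epochs: int = 100
    batch_size: int = 1

    def __post_init__(self) -> None:
        if self.backbone_depth not in (50, 101):
            raise ValueError(f"unsupported backbone depth {self.backbone_depth}")
        if not (0.0 < self.nms_iou < 1.0):
            raise ValueError("nms_iou must lie in (0, 1)")

    def as_dict(self) -> dict:
        return asdict(self)


def nms(boxes: Sequence[BoundingBox], iou_threshold: float) -> list[BoundingBox]:
    """Greedy non-maximum suppression.

    Boxes are visited in descending score order (ties broken by earlier
    input index); a box is kept iff its IoU with every already-kept box is
    <= ``iou_threshold``.  Returns survivors in visit order.
    """
    order = sorted(range(len(boxes)), key=lambda i: (-boxes[i].score, i))
    kept: list[BoundingBox] = []
    for i in order:
        b = boxes[i]
        if all(b.iou(k) <= iou_threshold for k in kept):
            kept.append(b)
    return kept


def count_grains(boxes: Sequence[BoundingBox]) -> int:
    """Grain count = number of detection boxes."""
    return len(boxes)


# ---------------------------------------------------------------------------
# Classical baseline
# ---------------------------------------------------------------------------

def detect_baseline(
    image: ScanImage,
    min_area_px: int = 30,
    seed_fraction: float = 0.5,
    split_factor: float = 1.75,
    return_masks: bool = False,
):
    """Detect grains by Otsu segmentation + watershed splitting.

    Each connected bright blob yields one box; blobs whose interior
    distance transform has several peaks above ``seed_fraction`` x the blob
    maximum are split by marker-controlled watershed (touching grains),
    while isolated convex blobs are never split.  A second pass resolves
    heavily fused grains the watershed cannot separate: any segment larger
    than ``split_factor`` x the scene's median segment area is split into
    ``round(area / median)`` parts by deterministic k-means on its pixel
    coordinates (grain sizes within one panicle vary far less than 1.75x,
    so isolated grains are never touched).  Scores are the segment's
    solidity (area over convex-hull area), a cheap roundness proxy.

    Returns the box list, or ``(boxes, masks)`` with per-box boolean
    full-image masks when ``return_masks`` is set.  A blank image yields an
    empty result, not an error.
    """
    gray = red_channel(image.pixels)
    try:
        thr = otsu_threshold(gray)
    except TraitExtractionError:
        return ([], []) if return_masks else []
    binary = gray > thr
    if not binary.any():
        return ([], []) if return_masks else []
    labels, n_blobs = ndimage.label(binary)
    segments: list[tuple[np.ndarray, np.ndarray]] = []  # (ys, xs) global coords
    slices = ndimage.find_objects(labels)
    for blob_idx, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        window = labels[sl] == blob_idx
        if window.sum() < min_area_px:
            continue
        # pad so the distance transform sees the blob border
        win = np.pad(window, 1)
        dt = ndimage.distance_transform_edt(win)
        markers, n_mark = ndimage.label(dt > seed_fraction * dt.max())
        if n_mark <= 1:
            segs = [win]
        else:
            ws = watershed(-dt, markers, mask=win)
            segs = [ws == k for k in range(1, n_mark + 1)]
        y_off, x_off = sl[0].start - 1, sl[1].start - 1
        for seg in segs:
            if int(seg.sum()) < min_area_px:
                continue
            ys, xs = np.nonzero(seg)
            segments.append((ys + y_off, xs + x_off))

    if not segments:
        return ([], []) if return_masks else []

    # second pass: split area outliers (fused grains) by k-means
    areas = np.array([len(ys) for ys, _ in segments], dtype=float)
    median_area = float(np.median(areas))
    resolved: list[tuple[np.ndarray, np.ndarray]] = []
    for (ys, xs), area in zip(segments, areas):
        k = int(round(area / median_area)) if area > split_factor * median_area else 1
        if k <= 1:
            resolved.append((ys, xs))
        else:
            for part in _kmeans_split(ys, xs, k):
                if len(part[0]) >= min_area_px:
                    resolved.append(part)

    boxes: list[BoundingBox] = []
    masks: list[np.ndarray] = []
    for ys, xs in resolved:
        solidity = _solidity(ys, xs, len(ys))
        boxes.append(
            BoundingBox(
                x0=float(xs.min()),
                y0=float(ys.min()),
                x1=float(xs.max() + 1),
                y1=float(ys.max() + 1),
                score=solidity,
            ).clip(image.width, image.height)
        )
        if return_masks:
            full = np.zeros((image.height, image.width), dtype=bool)
            full[ys, xs] = True
            masks.append(full)
    return (boxes, masks) if return_masks else boxes


def _kmeans_split(
    ys: np.ndarray, xs: np.ndarray, k: int, iters: int = 15
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic Lloyd's k-means on pixel coordinates.

    Centres are initialised at quantiles along the segment's principal
    axis, so the split is reproducible without any randomness.
    """
    pts = np.stack([xs, ys], axis=1).astype(np.float64)
    centred = pts - pts.mean(axis=0)
    u, _, vt = np.linalg.svd(centred, full_matrices=False)
    proj = centred @ vt[0]
    qs = np.quantile(proj, (np.arange(k) + 0.5) / k)
    centres = pts.mean(axis=0) + qs[:, None] * vt[0]
    assign = np.zeros(len(pts), dtype=int)
    for _ in range(iters):
        d = ((pts[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2)
        new_assign = d.argmin(axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            sel = assign == j
            if sel.any():
                centres[j] = pts[sel].mean(axis=0)
    out = []
    for j in range(k):
        sel = assign == j
        if sel.any():
            out.append((ys[sel], xs[sel]))
    return out


def _solidity(ys: np.ndarray, xs: np.ndarray, area: int) -> float:
    """Area over convex-hull area, clipped into [0, 1]."""
    from scipy.spatial import ConvexHull

    pts = np.stack([xs, ys], axis=1).astype(np.float64)
    if len(pts) < 4:
        return 1.0
    try:
        hull_area = ConvexHull(pts).volume + 0.0
    except Exception:
        return 1.0
    # pixel-count area vs continuous hull area; guard the ratio into [0, 1]
    return float(min(1.0, area / hull_area)) if hull_area > 0 else 1.0


# ---------------------------------------------------------------------------
# Trainable two-stage detector with pyramid fusion
# ---------------------------------------------------------------------------

_STRIDES = (4, 8, 16)


def _block_pool(x: np.ndarray, s: int) -> np.ndarray:
    h, w = x.shape
    hs, ws = h // s * s, w // s * s
    return x[:hs, :ws].reshape(hs // s, s, ws // s, s).mean(axis=(1, 3))


def _level_features(gray01: np.ndarray) -> list[np.ndarray]:
    """Per-stride raw feature maps: local mean, local std, gradient magnitude."""
    feats = []
    for s in _STRIDES:
        lvl = _block_pool(gray01, s)
        mean = ndimage.uniform_filter(lvl, 3)
        sq = ndimage.uniform_filter(lvl**2, 3)
        std = np.sqrt(np.maximum(sq - mean**2, 0.0))
        gy, gx = np.gradient(lvl)
        grad = np.hypot(gx, gy)
        feats.append(np.stack([mean, std, grad], axis=0))
    return feats


def _fuse_pyramid(feats: list[np.ndarray]) -> list[np.ndarray]:
    """Top-down fusion: concatenate each level with its upsampled coarser level."""
    fused = []
    for i, f in enumerate(feats):
        if i + 1 < len(feats):
            coarser = feats[i + 1]
            up = coarser.repeat(2, axis=1).repeat(2, axis=2)
            up = up[:, : f.shape[1], : f.shape[2]]
            if up.shape[1] < f.shape[1] or up.shape[2] < f.shape[2]:
                pad = (
                    (0, 0),
                    (0, f.shape[1] - up.shape[1]),
                    (0, f.shape[2] - up.shape[2]),
                )
                up = np.pad(up, pad, mode="edge")
        else:
            up = f
        cat = np.concatenate([f, up], axis=0)
        mu = cat.mean(axis=(1, 2), keepdims=True)
        sd = cat.std(axis=(1, 2), keepdims=True) + 1e-6
        fused.append((cat - mu) / sd)
    return fused


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))


class TwoStageDetector:
    """Two-stage detector over a fused image pyramid, with linear heads.

    Stage 1 (proposal): a shared linear objectness head scores every cell
    of every pyramid level; the top-scoring cells become proposals with
    level-sized anchors.  Stage 2 (refinement): per-proposal pooled
    features feed a linear classifier and a linear box regressor.  Both
    stages train jointly by SGD with momentum on a binary cross-entropy +
    L2-regression objective.
    """

    N_FEAT = 6  # fused channels per level

    def __init__(self, config: DetectorConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        f = self.N_FEAT
        self.w_rpn = rng.normal(0, 0.01, f)
        self.b_rpn = 0.0
        self.w_cls = rng.normal(0, 0.01, f + 2)  # + log w, log h of proposal
        self.b_cls = 0.0
        self.w_reg = np.zeros((4, f + 2))
        self.b_reg = np.zeros(4)
        self._mom = {k: np.zeros_like(v) for k, v in self._params().items()}

    def _params(self) -> dict:
        return {
            "w_rpn": self.w_rpn,
            "w_cls": self.w_cls,
            "w_reg": self.w_reg,
            "b_reg": self.b_reg,
        }

    # -- feature plumbing ---------------------------------------------------

    @staticmethod
    def _prepare(image: ScanImage) -> list[np.ndarray]:
        gray01 = red_channel(image.pixels).astype(np.float64) / 255.0
        return _fuse_pyramid(_level_features(gray01))

    @staticmethod
    def _assign_level(box: BoundingBox) -> int:
        size = np.sqrt(box.area)
        if size < 48:
            return 0
        if size < 96:
            return 1
        return 2

    def _proposal_box(self, level: int, cy: int, cx: int) -> BoundingBox:
        s = _STRIDES[level]
        half = 2.0 * s  # anchor side = 4 x stride
        x = (cx + 0.5) * s
        y = (cy + 0.5) * s
        return BoundingBox(x - half, y - half, x + half, y + half, 1.0)

    # -- training -----------------------------------------------------------

    def train_step(self, batch: Sequence[tuple[ScanImage, Sequence[BoundingBox]]]):
        """One SGD step on a batch of (image, truth boxes); returns the loss."""
        if not batch:
            raise ValueError("empty batch")
        grads = {k: np.zeros_like(v) for k, v in self._params().items()}
        g_b_rpn = 0.0
        g_b_cls = 0.0
        total_loss = 0.0
        for image, truth in batch:
            fused = self._prepare(image)
            loss, g = self._losses_and_grads(fused, list(truth))
            total_loss += loss
            for k in grads:
                grads[k] += g[k]
            g_b_rpn += g["b_rpn"]
            g_b_cls += g["b_cls"]
        n = len(batch)
        total_loss /= n
        cfg = self.config
        params = self._params()
        for k, p in params.items():
            g = grads[k] / n + cfg.weight_decay * p
            self._mom[k] = cfg.momentum * self._mom[k] - cfg.lr * g
            p += self._mom[k]
        self.b_rpn -= cfg.lr * g_b_rpn / n
        self.b_cls -= cfg.lr * g_b_cls / n
        return float(total_loss)

    def _losses_and_grads(self, fused, truth):
        f = self.N_FEAT
        g = {k: np.zeros_like(v) for k, v in self._params().items()}
        g["b_rpn"] = 0.0
        g["b_cls"] = 0.0

        # ---- stage 1: objectness over every pyramid cell
        rpn_loss = 0.0
        n_cells = 0
        truth_by_level = [[] for _ in _STRIDES]
        for t in truth:
            truth_by_level[self._assign_level(t)].append(t)
        for lvl, feat in enumerate(fused):
            _, H, W = feat.shape
            target = np.zeros((H, W))
            s = _STRIDES[lvl]
            for t in truth_by_level[lvl]:
                x0 = int(t.x0 / s)
                x1 = max(x0 + 1, int(np.ceil(t.x1 / s)))
                y0 = int(t.y0 / s)
                y1 = max(y0 + 1, int(np.ceil(t.y1 / s)))
                target[y0:y1, x0:x1] = 1.0
            z = np.tensordot(self.w_rpn, feat, axes=(0, 0)) + self.b_rpn
            p = _sigmoid(z)
            # class-balanced BCE: weight positives and negatives equally
            n_pos = max(target.sum(), 1.0)
            n_neg = max((1 - target).sum(), 1.0)
            w = np.where(target > 0, 0.5 / n_pos, 0.5 / n_neg)
            eps = 1e-12
            rpn_loss += float(
                -(w * (target * np.log(p + eps) + (1 - target) * np.log(1 - p + eps))).sum()
            )
            dz = w * (p - target)
            g["w_rpn"] += np.tensordot(dz, feat, axes=([0, 1], [1, 2]))
            g["b_rpn"] += float(dz.sum())
            n_cells += H * W
        rpn_loss /= len(fused)
        for k in ("w_rpn", "b_rpn"):
            g[k] = g[k] / len(fused)

        # ---- stage 2: classify + regress pooled proposals.
        # During training the proposal set is anchored on the ground truth
        # (one positive anchor per truth box, a fixed grid of negatives), so
        # the stage-2 objective is stationary across steps.
        proposals = self._training_proposals(fused, truth)
        cls_loss = 0.0
        reg_loss = 0.0
        n_pos_prop = 0
        matched = []
        for lvl, cy, cx, box in proposals:
            feats = self._pool(fused[lvl], box, _STRIDES[lvl])
            best_iou, best_t = 0.0, None
            for t in truth:
                iou = box.iou(t)
                if iou > best_iou:
                    best_iou, best_t = iou, t
            label = 1.0 if best_iou >= 0.3 else 0.0
            matched.append((feats, label, best_t, box))
        # class-balanced BCE: positives and negatives carry equal total weight
        n_pos = max(sum(1 for _, lab, _, _ in matched if lab > 0), 1)
        n_neg = max(sum(1 for _, lab, _, _ in matched if lab == 0), 1)
        eps = 1e-12
        for feats, label, best_t, box in matched:
            w = 0.5 / n_pos if label > 0 else 0.5 / n_neg
            z = float(self.w_cls @ feats + self.b_cls)
            p = float(_sigmoid(np.array(z)))
            cls_loss += -w * (
                label * np.log(p + eps) + (1 - label) * np.log(1 - p + eps)
            )
            dz = w * (p - label)
            g["w_cls"] += dz * feats
            g["b_cls"] += dz
            if label > 0 and best_t is not None:
                n_pos_prop += 1
                tgt = self._reg_target(box, best_t)
                pred = self.w_reg @ feats + self.b_reg
                diff = pred - tgt
                reg_loss += 0.5 * float(diff @ diff)
                g["w_reg"] += np.outer(diff, feats)
                g["b_reg"] += diff
        if n_pos_prop:
            reg_loss /= n_pos_prop
            g["w_reg"] /= n_pos_prop
            g["b_reg"] /= n_pos_prop
        loss = rpn_loss + cls_loss + reg_loss
        return loss, g

    def _training_proposals(self, fused, truth):
        """Deterministic proposal set for training: truth-centred positives
        plus a sparse fixed grid of negatives."""
        out = []
        for t in truth:
            lvl = self._assign_level(t)
            s = _STRIDES[lvl]
            _, H, W = fused[lvl].shape
            cx = int(np.clip((t.x0 + t.x1) / 2 / s, 0, W - 1))
            cy = int(np.clip((t.y0 + t.y1) / 2 / s, 0, H - 1))
            out.append((lvl, cy, cx, self._proposal_box(lvl, cy, cx)))
        lvl = 1
        _, H, W = fused[lvl].shape
        for cy in range(2, H - 2, 8):
            for cx in range(2, W - 2, 8):
                out.append((lvl, cy, cx, self._proposal_box(lvl, cy, cx)))
        return out[:512]

    def _make_proposals(self, fused, cap: int | None = None):
        cap = cap or self.config.rpn_proposals
        scored = []
        for lvl, feat in enumerate(fused):
            z = np.tensordot(self.w_rpn, feat, axes=(0, 0)) + self.b_rpn
            p = _sigmoid(z)
            H, W = p.shape
            flat = np.argsort(p.ravel())[::-1][: cap // len(fused) + 1]
            for idx in flat:
                cy, cx = divmod(int(idx), W)
                scored.append((float(p[cy, cx]), lvl, cy, cx))
        scored.sort(key=lambda r: -r[0])
        out = []
        for score, lvl, cy, cx in scored[:cap]:
            out.append((lvl, cy, cx, self._proposal_box(lvl, cy, cx)))
        return out

    def _pool(self, feat: np.ndarray, box: BoundingBox, stride: int) -> np.ndarray:
        _, H, W = feat.shape
        x0 = int(np.clip(box.x0 / stride, 0, W - 1))
        x1 = int(np.clip(np.ceil(box.x1 / stride), x0 + 1, W))
        y0 = int(np.clip(box.y0 / stride, 0, H - 1))
        y1 = int(np.clip(np.ceil(box.y1 / stride), y0 + 1, H))
        pooled = feat[:, y0:y1, x0:x1].mean(axis=(1, 2))
        size = np.array([np.log(box.width), np.log(box.height)]) / 10.0
        return np.concatenate([pooled, size])

    @staticmethod
    def _reg_target(prop: BoundingBox, truth: BoundingBox) -> np.ndarray:
        pw, ph = prop.width, prop.height
        return np.array(
            [
                ((truth.x0 + truth.x1) / 2 - (prop.x0 + prop.x1) / 2) / pw,
                ((truth.y0 + truth.y1) / 2 - (prop.y0 + prop.y1) / 2) / ph,
                np.log(truth.width / pw),
                np.log(truth.height / ph),
            ]
        )

    # -- inference ----------------------------------------------------------

    def predict(
        self, image: ScanImage, score_threshold: float = 0.5
    ) -> list[BoundingBox]:
        """Scored, NMS-filtered boxes for one image."""
        fused = self._prepare(image)
        proposals = self._make_proposals(fused)
        out = []
        for lvl, cy, cx, box in proposals:
            feats = self._pool(fused[lvl], box, _STRIDES[lvl])
            p = float(_sigmoid(np.array(self.w_cls @ feats + self.b_cls)))
            if p < score_threshold:
                continue
            d = self.w_reg @ feats + self.b_reg
            cxn = (box.x0 + box.x1) / 2 + d[0] * box.width
            cyn = (box.y0 + box.y1) / 2 + d[1] * box.height
            wn = box.width * np.exp(np.clip(d[2], -2, 2))
            hn = box.height * np.exp(np.clip(d[3], -2, 2))
            try:
                refined = BoundingBox(
                    cxn - wn / 2, cyn - hn / 2, cxn + wn / 2, cyn + hn / 2, p
                ).clip(image.width, image.height)
            except ValueError:
                continue
            out.append(refined)
        return nms(out, self.config.nms_iou)


def build_model(config: DetectorConfig | None = None, seed: int = 0) -> TwoStageDetector:
    """Build the trainable two-stage pyramid detector."""
    return TwoStageDetector(config or DetectorConfig(), seed=seed)
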