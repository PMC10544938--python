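"""Synthetic scanned-panicle scenes with exact ground truth.

Flatbed scans of rice panicles show bright, elongated grains on a dark
scanner background.  The generator emulates that geometry: each grain is a
rotated superellipse ``|x/a|^n + |y/b|^n = 1`` (n ~ 2.5 gives the rounded
rectangular outline of a rice grain — the circularity of a real grain,
about 0.5 for an 8.6 x 2.8 mm grain, sits between the ellipse and the
rectangle value), filled with a rice-coloured tone whose red channel
dominates, over a dark background.  Grain populations default to the
measured distributions of real panicles: length ~ N(8.607, 0.589) mm
clipped to [5, 11] mm, width ~ N(2.770, 0.248) mm clipped to [2, 4] mm,
and 45-250 grains per panicle.

Because every scene is rendered from known parameters the generator emits
exact annotations: full and visible masks, bounding boxes, per-grain true
traits and occlusion ratios, so detection, restoration and measurement can
all be scored without any real scan.

Geometry is anti-aliased on a subpixel grid; the binary mask is the set of
pixels with >= 50% coverage and pixel colours are assigned from that mask
(two-tone plus optional texture noise), which keeps Otsu segmentation of
the renders exact and makes a zero-noise render exactly two-coloured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from scipy.special import gamma

from grainscan.scan_io import BoundingBox, ScanImage, mm_per_pixel
from grainscan import traits as traits_mod

# Scanner-background and grain tones (R, G, B). The red channel carries the
# strongest grain/background contrast, as on real scans.
BACKGROUND_RGB = (34, 30, 27)
GRAIN_RGB = (206, 178, 136)
BRANCH_RGB = (168, 150, 96)

_SUBPIXEL = 3  # 3x3 coverage samples per pixel


@dataclass(frozen=True)
class GrainModel:
    """Parameters of one rendered grain.

    ``length``/``width`` are the full axes in mm; ``orientation`` is the
    angle of the major axis from the +x direction in radians; ``shape_n``
    is the superellipse exponent (2 = ellipse, larger = boxier);
    ``center`` is the (x, y) pixel position used when the grain is stamped
    into a scene (ignored for standalone crops).
    """

    length: float
    width: float
    orientation: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)
    shape_n: float = 2.5
    color: tuple[int, int, int] = GRAIN_RGB
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if not (self.length >= self.width > 0):
            raise ValueError(
                f"grain axes must satisfy length >= width > 0, "
                f"got {self.length} x {self.width}"
            )
        if self.shape_n < 2:
            raise ValueError(f"shape exponent must be >= 2, got {self.shape_n}")

    def area_mm2(self) -> float:
        """Analytic superellipse area: 4ab * Gamma(1+1/n)^2 / Gamma(1+2/n)."""
        a, b, n = self.length / 2.0, self.width / 2.0, self.shape_n
        return 4.0 * a * b * gamma(1 + 1 / n) ** 2 / gamma(1 + 2 / n)

    def perimeter_mm(self) -> float:
        """Superellipse perimeter by dense quadrature of the arc length."""
        a, b, n = self.length / 2.0, self.width / 2.0, self.shape_n
        t = np.linspace(0.0, np.pi / 2.0, 20001)
        c, s = np.cos(t), np.sin(t)
        x = a * np.abs(c) ** (2.0 / n)
        y = b * np.abs(s) ** (2.0 / n)
        seg = np.hypot(np.diff(x), np.diff(y))
        return 4.0 * float(seg.sum())

    def true_traits(self) -> "traits_mod.GrainTraits":
        """Ground-truth traits implied by the model parameters."""
        area = self.area_mm2()
        perim = self.perimeter_mm()
        d = traits_mod.derived_traits(self.length, self.width, area, perim)
        return traits_mod.GrainTraits(
            length=self.length,
            width=self.width,
            area=area,
            perimeter=perim,
            lw_ratio=d.lw_ratio,
            ap_ratio=d.ap_ratio,
            circularity=d.circularity,
            eq_major=d.eq_major,
            eq_minor=d.eq_minor,
        )


@dataclass(frozen=True)
class GrainDistribution:
    """Sampling config for grain populations.

    Lengths and widths are drawn from normal distributions truncated (by
    re-draw) to the stated ranges; the defaults emulate a real panicle
    population (length 8.607 +/- 0.589 mm within 5-11 mm, width
    2.770 +/- 0.248 mm within 2-4 mm). ``kind='uniform'`` draws uniformly
    over the ranges instead.
    """

    kind: Literal["normal", "uniform"] = "normal"
    length_mean: float = 8.607
    length_sd: float = 0.589
    length_range: tuple[float, float] = (5.0, 11.0)
    width_mean: float = 2.770
    width_sd: float = 0.248
    width_range: tuple[float, float] = (2.0, 4.0)
    shape_n_range: tuple[float, float] = (2.3, 2.7)
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        for lo, hi in (self.length_range, self.width_range, self.shape_n_range):
            if lo > hi:
                raise ValueError(f"infeasible range ({lo}, {hi})")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    if sd == 0:
        if not (lo <= mean <= hi):
            raise ValueError("degenerate distribution outside its range")
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise ValueError("truncated-normal rejection failed; check config")


def sample_grain(params: GrainDistribution, rng: np.random.Generator) -> GrainModel:
    """Draw one grain from the configured population (length >= width)."""
    if params.kind == "uniform":
        length = rng.uniform(*params.length_range)
        width = rng.uniform(*params.width_range)
    else:
        length = _truncated_normal(
            rng, params.length_mean, params.length_sd, *params.length_range
        )
        width = _truncated_normal(
            rng, params.width_mean, params.width_sd, *params.width_range
        )
    if width > length:  # degenerate configs may invert the axes
        length, width = width, length
    return GrainModel(
        length=float(length),
        width=float(width),
        orientation=float(rng.uniform(0.0, np.pi)),
        shape_n=float(rng.uniform(*params.shape_n_range)),
        noise_sd=params.noise_sd,
    )


def _coverage(
    h: int,
    w: int,
    cx: float,
    cy: float,
    a_px: float,
    b_px: float,
    n: float,
    theta: float,
) -> np.ndarray:
    """Subpixel-sampled coverage of a rotated superellipse on an h x w grid."""
    ys = np.arange(h, dtype=np.float64)
    xs = np.arange(w, dtype=np.float64)
    offs = (np.arange(_SUBPIXEL) + 0.5) / _SUBPIXEL - 0.5
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    cover = np.zeros((h, w), dtype=np.float64)
    for oy in offs:
        for ox in offs:
            X, Y = np.meshgrid(xs + ox - cx, ys + oy - cy)
            u = (cos_t * X + sin_t * Y) / a_px
            v = (-sin_t * X + cos_t * Y) / b_px
            cover += (np.abs(u) ** n + np.abs(v) ** n) <= 1.0
    return cover / (_SUBPIXEL * _SUBPIXEL)


def render_grain(
    model: GrainModel,
    mm_per_px: float,
    pad: int = 8,
    rng: np.random.Generator | None = None,
    crop_size: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one grain into a local crop.

    Returns ``(rgb, mask)`` where ``rgb`` is H x W x 3 uint8 and ``mask`` is
    the boolean silhouette (pixels with >= 50% subpixel coverage). The crop
    is sized to the grain's rotated extent plus ``pad``, or to ``crop_size``
    (height, width) when given. Texture noise (``model.noise_sd``) is added
    inside the mask only. Raises if the grain does not fit.
    """
    a = model.length / 2.0 / mm_per_px
    b = model.width / 2.0 / mm_per_px
    cos_t, sin_t = abs(math.cos(model.orientation)), abs(math.sin(model.orientation))
    ext_x = a * cos_t + b * sin_t
    ext_y = a * sin_t + b * cos_t
    if crop_size is None:
        w = int(math.ceil(2 * ext_x)) + 2 * pad
        h = int(math.ceil(2 * ext_y)) + 2 * pad
    else:
        h, w = crop_size
        if 2 * ext_x > w or 2 * ext_y > h:
            raise ValueError(
                f"grain extent {2*ext_x:.0f}x{2*ext_y:.0f} px exceeds crop {w}x{h}"
            )
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    cover = _coverage(h, w, cx, cy, a, b, model.shape_n, model.orientation)
    mask = cover >= 0.5
    rgb = np.empty((h, w, 3), dtype=np.float64)
    rgb[:] = BACKGROUND_RGB
    rgb[mask] = model.color
    if model.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        noise = rng.normal(0.0, model.noise_sd, size=(h, w, 1))
        rgb[mask] += noise[mask]
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8), mask


@dataclass
class MaskPatch:
    """A per-grain binary mask stored locally: canvas offset + raster."""

    y0: int
    x0: int
    mask: np.ndarray  # bool, local window

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def to_full(self, h: int, w: int) -> np.ndarray:
        full = np.zeros((h, w), dtype=bool)
        mh, mw = self.mask.shape
        full[self.y0 : self.y0 + mh, self.x0 : self.x0 + mw] = self.mask
        return full


@dataclass
class SceneAnnotation:
    """Exact ground truth of a synthetic scene."""

    boxes: list[BoundingBox]
    masks: list[MaskPatch]  # full (unoccluded) silhouettes
    visible_masks: list[MaskPatch]  # silhouettes minus later-painted grains
    truths: list["traits_mod.GrainTraits"]
    occlusion_ratios: list[float]
    models: list[GrainModel]

    def __post_init__(self) -> None:
        n = len(self.boxes)
        if not (
            len(self.masks)
            == len(self.visible_masks)
            == len(self.truths)
            == len(self.occlusion_ratios)
            == len(self.models)
            == n
        ):
            raise ValueError("annotation lists must have equal length")


@dataclass(frozen=True)
class OcclusionConfig:
    """Placement policy for scene generation.

    ``max_ratio`` caps every grain's final occlusion ratio (0 disables
    overlap entirely); ``gap_px`` is the extra clearance required around a
    grain when overlap is disabled, so zero-occlusion scenes never produce
    touching blobs.
    """

    max_ratio: float = 0.0
    gap_px: int = 3
    max_tries: int = 200

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_ratio <= 0.9):
            raise ValueError("max_ratio must lie in [0, 0.9]")


def generate_scene(
    n_grains: int,
    occlusion: OcclusionConfig,
    mm_per_px: float,
    rng: np.random.Generator,
    canvas: tuple[int, int] = (1700, 1425),
    distribution: GrainDistribution | None = None,
) -> tuple[ScanImage, SceneAnnotation]:
    """Render a synthetic panicle scan of ``n_grains`` grains.

    Grains are placed by rejection sampling under the occlusion policy and
    painted in placement order (later grains occlude earlier ones).  The
    returned annotation carries, per grain, the full mask, the visible
    mask, the true traits, the bounding box of the full silhouette and the
    realised occlusion ratio.  Raises ``RuntimeError`` when the canvas
    cannot host the requested count under the policy.
    """
    if n_grains < 1:
        raise ValueError("n_grains must be >= 1")
    dist = distribution or GrainDistribution()
    H, W = canvas
    dpi = 25.4 / mm_per_px
    img = np.empty((H, W, 3), dtype=np.uint8)
    img[:] = BACKGROUND_RGB

    placed_models: list[GrainModel] = []
    placed_masks: list[MaskPatch] = []
    occluded_px = []  # per placed grain, pixels covered by later grains
    occupancy = np.zeros((H, W), dtype=bool)

    for _ in range(n_grains):
        ok = False
        for _try in range(occlusion.max_tries):
            model = sample_grain(dist, rng)
            crop, mask = render_grain(model, mm_per_px, pad=2, rng=rng)
            mh, mw = mask.shape
            if mh >= H or mw >= W:
                continue
            y0 = int(rng.integers(0, H - mh))
            x0 = int(rng.integers(0, W - mw))
            win_occ = occupancy[y0 : y0 + mh, x0 : x0 + mw]
            if occlusion.max_ratio == 0.0:
                test_mask = (
                    ndimage.binary_dilation(mask, iterations=occlusion.gap_px)
                    if occlusion.gap_px > 0
                    else mask
                )
                if np.any(win_occ & test_mask):
                    continue
            else:
                # The candidate is painted on top: it occludes earlier
                # grains but is itself unoccluded at placement time.
                feasible = True
                inter_counts = []
                for gi, patch in enumerate(placed_masks):
                    inter = _patch_intersection(patch, y0, x0, mask)
                    inter_counts.append((gi, inter))
                    if inter and (occluded_px[gi] + inter) / placed_masks[
                        gi
                    ].area > occlusion.max_ratio:
                        feasible = False
                        break
                if not feasible:
                    continue
                for gi, inter in inter_counts:
                    occluded_px[gi] += inter
            model = replace(model, center=(x0 + (mw - 1) / 2.0, y0 + (mh - 1) / 2.0))
            placed_models.append(model)
            placed_masks.append(MaskPatch(y0, x0, mask))
            occluded_px.append(0)
            occupancy[y0 : y0 + mh, x0 : x0 + mw] |= mask
            img[y0 : y0 + mh, x0 : x0 + mw][mask] = crop[mask]
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place grain {len(placed_models) + 1}/{n_grains}: "
                "canvas too small for the requested count under this occlusion policy"
            )

    # Visible masks: own mask minus every later-painted silhouette.
    visible: list[MaskPatch] = []
    ratios: list[float] = []
    for i, patch in enumerate(placed_masks):
        vis = patch.mask.copy()
        for later in placed_masks[i + 1 :]:
            _subtract_patch(vis, patch.y0, patch.x0, later)
        visible.append(MaskPatch(patch.y0, patch.x0, vis))
        full_area = patch.area
        ratios.append(1.0 - int(vis.sum()) / full_area)

    boxes = []
    for patch in placed_masks:
        ys, xs = np.nonzero(patch.mask)
        boxes.append(
            BoundingBox(
                patch.x0 + xs.min(),
                patch.y0 + ys.min(),
                patch.x0 + xs.max() + 1,
                patch.y0 + ys.max() + 1,
                1.0,
            )
        )
    ann = SceneAnnotation(
        boxes=boxes,
        masks=placed_masks,
        visible_masks=visible,
        truths=[m.true_traits() for m in placed_models],
        occlusion_ratios=ratios,
        models=placed_models,
    )
    return ScanImage(img, dpi), ann


def _patch_intersection(patch: MaskPatch, y0: int, x0: int, mask: np.ndarray) -> int:
    """Pixel count of the overlap between ``patch`` and a mask at (y0, x0)."""
    ph, pw = patch.mask.shape
    mh, mw = mask.shape
    ty0, ty1 = max(patch.y0, y0), min(patch.y0 + ph, y0 + mh)
    tx0, tx1 = max(patch.x0, x0), min(patch.x0 + pw, x0 + mw)
    if ty0 >= ty1 or tx0 >= tx1:
        return 0
    a = patch.mask[ty0 - patch.y0 : ty1 - patch.y0, tx0 - patch.x0 : tx1 - patch.x0]
    b = mask[ty0 - y0 : ty1 - y0, tx0 - x0 : tx1 - x0]
    return int(np.count_nonzero(a & b))


def _subtract_patch(vis: np.ndarray, y0: int, x0: int, later: MaskPatch) -> None:
    """In place: remove ``later``'s pixels from a visible mask at (y0, x0)."""
    vh, vw = vis.shape
    lh, lw = later.mask.shape
    ty0, ty1 = max(y0, later.y0), min(y0 + vh, later.y0 + lh)
    tx0, tx1 = max(x0, later.x0), min(x0 + vw, later.x0 + lw)
    if ty0 >= ty1 or tx0 >= tx1:
        return
    vis[ty0 - y0 : ty1 - y0, tx0 - x0 : tx1 - x0] &= ~later.mask[
        ty0 - later.y0 : ty1 - later.y0, tx0 - later.x0 : tx1 - later.x0
    ]


# ---------------------------------------------------------------------------
# Paired occluded/clean samples for restoration training and evaluation
# ---------------------------------------------------------------------------

@dataclass
class PairedSample:
    """A 256x256 (by default) occluded/clean image pair of the same grain.

    ``ratio`` is the realised fraction of the grain silhouette covered by
    the occluder; ``occluder_mask`` marks the occluder's pixels and
    ``grain_mask`` the full grain silhouette, so deterministic baselines
    and scoring have exact geometry available.
    """

    occluded: np.ndarray
    clean: np.ndarray
    ratio: float
    occluder_mask: np.ndarray
    grain_mask: np.ndarray
    model: GrainModel

    def __post_init__(self) -> None:
        if self.occluded.shape != self.clean.shape:
            raise ValueError("occluded and clean images must share a shape")
        if self.ratio == 0.0 and not np.array_equal(self.occluded, self.clean):
            raise ValueError("zero-ratio pair must be pixel-identical")


def make_pair(
    model: GrainModel,
    ratio: float,
    rng: np.random.Generator,
    mm_per_px: float = mm_per_pixel(600.0),
    size: int = 256,
    occluder: Literal["grain", "branch", "mixed"] = "mixed",
    tol: float = 0.02,
) -> PairedSample:
    """Build an occluded/clean pair whose realised coverage is ``ratio`` +/- tol.

    The clean image is the grain rendered centred in a ``size`` x ``size``
    crop.  The occluder is either a second grain or a thin branch strip
    (the two occluders seen on real panicles); it is slid along a random
    direction from outside the grain toward its centre, with the offset
    bisected until the covered fraction of the grain mask falls within
    ``tol`` of the request.  Raises ``RuntimeError`` if no placement
    reaches the ratio after bounded retries.
    """
    if not (0.0 <= ratio <= 0.9):
        raise ValueError("ratio must lie in [0, 0.9]")
    clean, grain_mask = render_grain(
        model, mm_per_px, rng=rng, crop_size=(size, size)
    )
    if ratio == 0.0:
        return PairedSample(
            occluded=clean.copy(),
            clean=clean,
            ratio=0.0,
            occluder_mask=np.zeros_like(grain_mask),
            grain_mask=grain_mask,
            model=model,
        )

    grain_area = int(grain_mask.sum())
    cx, cy = (size - 1) / 2.0, (size - 1) / 2.0

    for _attempt in range(40):
        kind = occluder
        if kind == "mixed":
            kind = "grain" if rng.random() < 0.5 else "branch"
        if kind == "grain":
            occ_model = GrainModel(
                length=model.length * float(rng.uniform(0.9, 1.1)),
                width=model.width * float(rng.uniform(0.9, 1.2)),
                orientation=float(rng.uniform(0.0, np.pi)),
                shape_n=model.shape_n,
                color=GRAIN_RGB,
                noise_sd=model.noise_sd,
            )
            occ_rgb, occ_mask_local = render_grain(occ_model, mm_per_px, pad=2, rng=rng)
        else:
            # A rachis-branch strip: long thin rectangle (high exponent).
            occ_model = GrainModel(
                length=model.length * 3.0,
                width=float(rng.uniform(0.8, 1.6)),
                orientation=float(rng.uniform(0.0, np.pi)),
                shape_n=8.0,
                color=BRANCH_RGB,
                noise_sd=model.noise_sd,
            )
            occ_rgb, occ_mask_local = render_grain(occ_model, mm_per_px, pad=2, rng=rng)

        theta = float(rng.uniform(0.0, 2 * np.pi))
        direction = np.array([math.cos(theta), math.sin(theta)])
        far = max(size, max(occ_mask_local.shape)) * 1.5

        def coverage_at(t: float) -> tuple[float, tuple[int, int]]:
            # t=0: occluder centred far away along `direction`; t=1: centred
            # on the grain centre.
            ox = cx + (1.0 - t) * far * direction[0]
            oy = cy + (1.0 - t) * far * direction[1]
            mh, mw = occ_mask_local.shape
            y0 = int(round(oy - (mh - 1) / 2.0))
            x0 = int(round(ox - (mw - 1) / 2.0))
            inter = _window_intersection(grain_mask, occ_mask_local, y0, x0)
            return inter / grain_area, (y0, x0)

        cov_full, _ = coverage_at(1.0)
        if cov_full < ratio:
            continue  # this occluder cannot reach the ratio; redraw
        lo_t, hi_t = 0.0, 1.0
        pos = None
        for _ in range(60):
            mid = 0.5 * (lo_t + hi_t)
            cov, p = coverage_at(mid)
            if abs(cov - ratio) <= tol:
                pos = p
                break
            if cov < ratio:
                lo_t = mid
            else:
                hi_t = mid
        if pos is None:
            continue
        y0, x0 = pos
        occluded = clean.copy()
        occ_mask_canvas = np.zeros_like(grain_mask)
        _stamp(occluded, occ_mask_canvas, occ_rgb, occ_mask_local, y0, x0)
        realised = int((occ_mask_canvas & grain_mask).sum()) / grain_area
        return PairedSample(
            occluded=occluded,
            clean=clean,
            ratio=float(realised),
            occluder_mask=occ_mask_canvas,
            grain_mask=grain_mask,
            model=model,
        )
    raise RuntimeError(f"could not reach occlusion ratio {ratio} after retries")


def _window_intersection(
    canvas_mask: np.ndarray, local_mask: np.ndarray, y0: int, x0: int
) -> int:
    H, W = canvas_mask.shape
    mh, mw = local_mask.shape
    ty0, ty1 = max(0, y0), min(H, y0 + mh)
    tx0, tx1 = max(0, x0), min(W, x0 + mw)
    if ty0 >= ty1 or tx0 >= tx1:
        return 0
    a = canvas_mask[ty0:ty1, tx0:tx1]
    b = local_mask[ty0 - y0 : ty1 - y0, tx0 - x0 : tx1 - x0]
    return int(np.count_nonzero(a & b))


def _stamp(
    img: np.ndarray,
    mask_canvas: np.ndarray,
    rgb_local: np.ndarray,
    mask_local: np.ndarray,
    y0: int,
    x0: int,
) -> None:
    H, W = mask_canvas.shape
    mh, mw = mask_local.shape
    ty0, ty1 = max(0, y0), min(H, y0 + mh)
    tx0, tx1 = max(0, x0), min(W, x0 + mw)
    if ty0 >= ty1 or tx0 >= tx1:
        return
    lm = mask_local[ty0 - y0 : ty1 - y0, tx0 - x0 : tx1 - x0]
    img[ty0:ty1, tx0:tx1][lm] = rgb_local[ty0 - y0 : ty1 - y0, tx0 - x0 : tx1 - x0][lm]
    mask_canvas[ty0:ty1, tx0:tx1] |= lm


def generate_pairs(
    n_pairs: int,
    ratio_range: tuple[float, float],
    seed: int,
    mm_per_px: float = mm_per_pixel(600.0),
    size: int = 256,
    distribution: GrainDistribution | None = None,
) -> list[PairedSample]:
    """A deterministic batch of paired samples, one fresh grain each."""
    dist = distribution or GrainDistribution()
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_pairs):
        ratio = float(rng.uniform(*ratio_range)) if ratio_range[1] > 0 else 0.0
        for _try in range(50):
            model = sample_grain(dist, rng)
            try:
                pairs.append(
                    make_pair(model, ratio, rng, mm_per_px=mm_per_px, size=size)
                )
                break
            except (ValueError, RuntimeError):
                continue  # grain too large for the crop, or unreachable ratio
        else:
            raise RuntimeError("could not build a pair after 50 grain draws")
    return pairs
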