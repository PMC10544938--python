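"""Single-grain trait measurement and panicle-level aggregation.

The measurement pipeline mirrors what works on real panicle scans: the red
channel carries the strongest grain/background contrast, Otsu's criterion
fixes the segmentation threshold, the largest foreground component's outer
contour is traced, and from contour and mask follow the physical traits:

* length — the maximum pairwise distance between contour points (major
  axis), via convex hull + rotating calipers;
* width — the longest chord perpendicular to the major axis, found by
  sweeping perpendicular section lines at 1-px steps;
* projection area — foreground pixel count, scaled to mm^2;
* perimeter — polygonal arc length of the traced outer contour;
* derived — length/width ratio, area/perimeter ratio, circularity
  ``4*pi*A/P^2`` and the equivalent ellipse (major = length, minor =
  ``4A/(pi*L)``, the minor axis of the ellipse with that major and area).

Per-panicle aggregation produces the 15-trait summary (one count, eight
size, six morphology quantities): grain number plus mean/SD of length,
width, projection area, perimeter, area/perimeter ratio, circularity and
length/width ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage import measure


class TraitExtractionError(RuntimeError):
    """A stage of the measurement pipeline failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class Contour:
    """Closed outer boundary polygon, points as (x, y) pixel coordinates."""

    points: np.ndarray  # (N, 2) float, not repeated at closure

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError("contour needs >= 3 (x, y) points")
        object.__setattr__(self, "points", pts)

    def arc_length(self) -> float:
        p = self.points
        d = np.diff(np.vstack([p, p[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


class DerivedTraits(NamedTuple):
    lw_ratio: float
    ap_ratio: float
    circularity: float
    eq_major: float
    eq_minor: float


@dataclass(frozen=True)
class GrainTraits:
    """One grain's measured quantities in physical units (mm, mm^2)."""

    length: float
    width: float
    area: float
    perimeter: float
    lw_ratio: float
    ap_ratio: float
    circularity: float
    eq_major: float
    eq_minor: float

    def __post_init__(self) -> None:
        if not (self.length >= self.width > 0):
            raise ValueError(
                f"length >= width > 0 violated: {self.length} vs {self.width}"
            )
        if not (0.0 < self.circularity <= 1.05):  # discretization slack
            raise ValueError(f"circularity out of (0, 1.05]: {self.circularity}")
        for name, got, want in (
            ("lw_ratio", self.lw_ratio, self.length / self.width),
            ("ap_ratio", self.ap_ratio, self.area / self.perimeter),
            ("circularity", self.circularity,
             4.0 * np.pi * self.area / self.perimeter**2),
        ):
            if abs(got - want) > 1e-9 * max(1.0, abs(want)):
                raise ValueError(f"{name} inconsistent with its inputs")

    def as_row(self) -> dict:
        return {
            "length_mm": self.length,
            "width_mm": self.width,
            "area_mm2": self.area,
            "perimeter_mm": self.perimeter,
            "lw_ratio": self.lw_ratio,
            "ap_ratio": self.ap_ratio,
            "circularity": self.circularity,
            "eq_minor_mm": self.eq_minor,
        }


#: Table order of the 15 panicle-level traits.
PANICLE_TRAIT_ORDER = (
    "GN",
    "MGL", "SGL", "MGW", "SGW", "MGPA", "SGPA", "MGP", "SGP",
    "MGAPR", "SGAPR", "MGC", "SGC", "MGLWR", "SGLWR",
)


@dataclass(frozen=True)
class PanicleTraits:
    """The 15 panicle traits: grain number + mean/SD of 7 grain quantities."""

    GN: int
    MGL: float
    SGL: float
    MGW: float
    SGW: float
    MGPA: float
    SGPA: float
    MGP: float
    SGP: float
    MGAPR: float
    SGAPR: float
    MGC: float
    SGC: float
    MGLWR: float
    SGLWR: float

    def __post_init__(self) -> None:
        if self.GN < 1:
            raise ValueError("GN must be >= 1")
        for name in ("SGL", "SGW", "SGPA", "SGP", "SGAPR", "SGC", "SGLWR"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def as_row(self) -> dict:
        return {k: getattr(self, k) for k in PANICLE_TRAIT_ORDER}


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def red_channel(rgb: np.ndarray) -> np.ndarray:
    """The R channel, unchanged (no luminance mixing)."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB, got shape {rgb.shape}")
    return rgb[:, :, 0]


def otsu_threshold(gray: np.ndarray) -> int:
    """Otsu's threshold over all 256 candidate levels.

    Returns the smallest level t maximizing the between-class variance of
    the split {<= t} / {> t}; foreground is ``gray > t``.  Raises on a
    constant image, for which no split exists.
    """
    gray = np.asarray(gray)
    if gray.dtype != np.uint8:
        raise ValueError("otsu_threshold expects an 8-bit grayscale image")
    hist = np.bincount(gray.ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise TraitExtractionError("otsu", "constant image: no threshold exists")
    w0 = np.cumsum(hist)  # pixels <= t, for t = 0..255
    sum0 = np.cumsum(hist * np.arange(256))
    w1 = total - w0
    mu0 = np.divide(sum0, w0, out=np.zeros(256), where=w0 > 0)
    mu1 = np.divide(sum0[-1] - sum0, w1, out=np.zeros(256), where=w1 > 0)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[w1 == 0] = -1.0  # no valid split beyond the last occupied level
    return int(np.argmax(sigma_b))


def binarize(gray: np.ndarray, threshold: int) -> np.ndarray:
    return np.asarray(gray) > threshold


def _largest_component(binary: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(binary)
    if n == 0:
        raise TraitExtractionError("contour", "empty foreground")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def largest_outer_contour(binary: np.ndarray) -> Contour:
    """Outer boundary polygon of the largest foreground component.

    Interior holes are filled before tracing, so only the outer boundary is
    returned.  The polygon is the 0.5-level marching-squares isoline of the
    (zero-padded) mask: a closed, simple, subpixel-positioned curve.
    """
    binary = np.asarray(binary, dtype=bool)
    comp = _largest_component(binary)
    comp = ndimage.binary_fill_holes(comp)
    padded = np.pad(comp.astype(np.float64), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise TraitExtractionError("contour", "no contour found")
    rc = max(contours, key=len)
    if np.allclose(rc[0], rc[-1]):
        rc = rc[:-1]
    # (row, col) -> (x, y); undo the 1-px pad.
    pts = np.stack([rc[:, 1] - 1.0, rc[:, 0] - 1.0], axis=1)
    return Contour(pts)


def _hull_points(contour: Contour) -> np.ndarray:
    pts = contour.points
    try:
        hull = ConvexHull(pts)
        return pts[hull.vertices]
    except Exception:  # degenerate (collinear) input
        return pts


def _rotating_calipers_diameter(hull: np.ndarray) -> tuple[float, int, int]:
    """Max pairwise distance over convex-hull vertices (antipodal pairs).

    ``hull`` must be in counter-clockwise order (ConvexHull guarantees it).
    Returns (distance, index_a, index_b).
    """
    m = len(hull)
    if m == 1:
        return 0.0, 0, 0
    if m == 2:
        return float(np.linalg.norm(hull[1] - hull[0])), 0, 1

    def area2(p, q, r):
        return abs(
            (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])
        )

    best = (0.0, 0, 0)
    k = 1
    for i in range(m):
        j = (i + 1) % m
        # advance the antipodal point while the supported triangle grows
        while area2(hull[i], hull[j], hull[(k + 1) % m]) > area2(
            hull[i], hull[j], hull[k]
        ):
            k = (k + 1) % m
        for p in (i, j):
            d = float(np.linalg.norm(hull[k] - hull[p]))
            if d > best[0]:
                best = (d, p, k)
    return best


def grain_length(
    contour: Contour, mm_per_px: float
) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Grain length: the farthest pair of contour points, in mm.

    Also returns the achieving point pair — the grain's major axis — which
    the width measurement needs.
    """
    hull = _hull_points(contour)
    d, i, j = _rotating_calipers_diameter(hull)
    if d == 0.0:
        raise TraitExtractionError("length", "degenerate contour")
    return d * mm_per_px, (hull[i].copy(), hull[j].copy())


def grain_width(
    contour: Contour,
    major_axis: tuple[np.ndarray, np.ndarray],
    mm_per_px: float,
) -> float:
    """Grain width: the longest chord perpendicular to the major axis.

    Section lines perpendicular to the axis are swept at 1-px steps; at
    each, the chord is the span between the extreme intersections of the
    line with the contour polygon; the maximum chord is the width.
    """
    p0, p1 = np.asarray(major_axis[0]), np.asarray(major_axis[1])
    axis = p1 - p0
    axis_len = np.linalg.norm(axis)
    if axis_len == 0:
        raise TraitExtractionError("width", "zero-length major axis")
    u = axis / axis_len  # along the axis
    pts = contour.points
    # rotate into the axis frame: s = along-axis coordinate, t = perpendicular
    rel = pts - p0
    s = rel @ u
    t = rel @ np.array([-u[1], u[0]])
    # polygon edges in the rotated frame
    s2 = np.roll(s, -1)
    t2 = np.roll(t, -1)
    best = 0.0
    for si in np.arange(np.ceil(s.min()), np.floor(s.max()) + 1.0, 1.0):
        lo = np.minimum(s, s2)
        hi = np.maximum(s, s2)
        cross = (lo <= si) & (hi >= si) & (hi > lo)
        if not np.any(cross):
            continue
        frac = (si - s[cross]) / (s2[cross] - s[cross])
        ts = t[cross] + frac * (t2[cross] - t[cross])
        chord = float(ts.max() - ts.min())
        if chord > best:
            best = chord
    if best == 0.0:
        raise TraitExtractionError("width", "no perpendicular chord found")
    return best * mm_per_px


def grain_area(binary: np.ndarray, mm_per_px: float) -> float:
    """Projection area: pixel count of the largest component, in mm^2."""
    comp = _largest_component(np.asarray(binary, dtype=bool))
    comp = ndimage.binary_fill_holes(comp)
    return float(comp.sum()) * mm_per_px**2


def _smooth_closed(points: np.ndarray, window: int = 5) -> np.ndarray:
    """Circular moving average over a closed polygon's vertices.

    The raw 0.5-level boundary polygon staircases along diagonal edges,
    overestimating a smooth shape's perimeter by ~6%; a short circular
    moving average removes the staircase (disk perimeters converge to
    2*pi*r within ~0.5%) while barely rounding true corners.
    """
    n = len(points)
    if n <= window:
        return points
    k = np.ones(window) / window
    half = window // 2
    out = np.empty_like(points)
    for d in range(2):
        ext = np.concatenate([points[-half:, d], points[:, d], points[:half, d]])
        out[:, d] = np.convolve(ext, k, mode="valid")[:n]
    return out


def grain_perimeter(contour: Contour, mm_per_px: float, smooth_window: int = 5) -> float:
    """Perimeter: arc length of the smoothed closed outer contour, in mm.

    The boundary polygon is regularised with a ``smooth_window``-point
    circular moving average before the arc length is taken (see
    :func:`_smooth_closed`); the frozen reference value for a filled
    10 x 10 px square at 1 mm/px is 36.17 mm.
    """
    return Contour(_smooth_closed(contour.points, smooth_window)).arc_length() * mm_per_px


def derived_traits(
    length: float, width: float, area: float, perimeter: float
) -> DerivedTraits:
    """Shape descriptors derived from the four primary measurements."""
    if min(length, width, area, perimeter) <= 0:
        raise ValueError("all primary traits must be positive")
    return DerivedTraits(
        lw_ratio=length / width,
        ap_ratio=area / perimeter,
        circularity=4.0 * np.pi * area / perimeter**2,
        eq_major=length,
        eq_minor=4.0 * area / (np.pi * length),
    )


def extract_grain_traits(crop: np.ndarray, mm_per_px: float) -> GrainTraits:
    """Full measurement pipeline for a single-grain RGB crop.

    red channel -> Otsu -> largest component -> outer contour -> length,
    width, area, perimeter -> derived traits.  Stage failures propagate as
    :class:`TraitExtractionError` carrying the stage name.
    """
    gray = red_channel(crop)
    t = otsu_threshold(gray)
    binary = binarize(gray, t)
    if not binary.any():
        raise TraitExtractionError("segmentation", "empty foreground after Otsu")
    contour = largest_outer_contour(binary)
    length, axis = grain_length(contour, mm_per_px)
    width = grain_width(contour, axis, mm_per_px)
    if width > length:  # numerically possible on near-isotropic shapes
        length, width = width, length
    area = grain_area(binary, mm_per_px)
    perimeter = grain_perimeter(contour, mm_per_px)
    d = derived_traits(length, width, area, perimeter)
    return GrainTraits(
        length=length,
        width=width,
        area=area,
        perimeter=perimeter,
        lw_ratio=d.lw_ratio,
        ap_ratio=d.ap_ratio,
        circularity=d.circularity,
        eq_major=d.eq_major,
        eq_minor=d.eq_minor,
    )


def aggregate_panicle(
    grains: Sequence[GrainTraits], sd: str = "sample"
) -> PanicleTraits:
    """Aggregate per-grain traits into the 15-trait panicle summary.

    ``sd`` selects the SD convention: ``"sample"`` (n-1, default) or
    ``"population"`` (n). A single grain yields all SDs equal to 0.
    """
    if not grains:
        raise ValueError("cannot aggregate an empty grain list")
    if sd not in ("sample", "population"):
        raise ValueError(f"unknown sd convention {sd!r}")
    ddof = 1 if sd == "sample" else 0

    def stats(vals: np.ndarray) -> tuple[float, float]:
        if len(vals) == 1:
            return float(vals[0]), 0.0
        return float(vals.mean()), float(vals.std(ddof=ddof))

    L = np.array([g.length for g in grains])
    W = np.array([g.width for g in grains])
    A = np.array([g.area for g in grains])
    P = np.array([g.perimeter for g in grains])
    APR = np.array([g.ap_ratio for g in grains])
    C = np.array([g.circularity for g in grains])
    LWR = np.array([g.lw_ratio for g in grains])
    mgl, sgl = stats(L)
    mgw, sgw = stats(W)
    mgpa, sgpa = stats(A)
    mgp, sgp = stats(P)
    mgapr, sgapr = stats(APR)
    mgc, sgc = stats(C)
    mglwr, sglwr = stats(LWR)
    return PanicleTraits(
        GN=len(grains),
        MGL=mgl, SGL=sgl, MGW=mgw, SGW=sgw,
        MGPA=mgpa, SGPA=sgpa, MGP=mgp, SGP=sgp,
        MGAPR=mgapr, SGAPR=sgapr, MGC=mgc, SGC=sgc,
        MGLWR=mglwr, SGLWR=sglwr,
    )


DEFAULT_BINS = {
    "length_mm": np.arange(4.0, 12.5, 0.5),
    "width_mm": np.arange(1.5, 4.6, 0.25),
    "lw_ratio": np.arange(1.0, 6.25, 0.25),
}


def thousand_grain_stats(
    grains: Sequence[GrainTraits],
    n: int = 1000,
    bins: dict[str, np.ndarray] | None = None,
    seed: int = 0,
) -> dict:
    """Thousand-grain trait distributions.

    Draws ``n`` grains from the pool (without replacement when the pool is
    large enough, else with replacement and a warning) and histograms
    length, width and length/width ratio over fixed bin edges.  Returns
    ``{"sample_size": n, "histograms": {trait: (counts, edges)},
    "summary": {trait: {mean, sd}}}``; deterministic per seed.
    """
    if not grains:
        raise ValueError("empty grain pool")
    bins = bins or DEFAULT_BINS
    rng = np.random.default_rng(seed)
    pool = np.arange(len(grains))
    if len(grains) >= n:
        idx = rng.choice(pool, size=n, replace=False)
    else:
        warnings.warn(
            f"pool of {len(grains)} grains < requested {n}; sampling with replacement",
            stacklevel=2,
        )
        idx = rng.choice(pool, size=n, replace=True)
    chosen = [grains[i] for i in idx]
    values = {
        "length_mm": np.array([g.length for g in chosen]),
        "width_mm": np.array([g.width for g in chosen]),
        "lw_ratio": np.array([g.lw_ratio for g in chosen]),
    }
    out_hist = {}
    out_summary = {}
    for trait, vals in values.items():
        edges = np.asarray(bins[trait], dtype=float)
        counts, edges = np.histogram(np.clip(vals, edges[0], edges[-1]), bins=edges)
        out_hist[trait] = (counts, edges)
        out_summary[trait] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))}
    return {"sample_size": int(n), "histograms": out_hist, "summary": out_summary}
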