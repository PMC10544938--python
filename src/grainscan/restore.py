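"""Occluded-grain silhouette completion.

Two restorers share one contract (``restore(occluded) -> restored`` on
8-bit RGB crops):

* a trainable conditional-GAN image-to-image model: a U-Net generator
  whose skip connections concatenate each encoder feature map into the
  matching decoder layer, adversarially trained against a *fused*
  discriminator with two heads on a shared trunk — a global head scoring
  the whole (condition, candidate) pair and a patch head scoring an N x N
  grid of local patches (70-px receptive field for the default layer
  schedule, giving a 30 x 30 map at 256 x 256).  The generator objective
  is the fused adversarial loss plus an L1 reconstruction term
  (weight 100, following the image-to-image translation formulation this
  architecture builds on);
* a deterministic geometric baseline: the visible silhouette's boundary
  (away from the occluder) is fitted with an ellipse by least squares and
  the occluded region is repainted as grain where the fitted ellipse
  predicts grain, as background elsewhere.

Restoration never discards observed evidence: when the visible-region mask
is supplied, observed pixels are copied through unchanged, so the restored
silhouette is a superset of the visible one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import EllipseModel

from grainscan import _nn
from grainscan.synth import PairedSample, BACKGROUND_RGB
from grainscan.traits import (
    TraitExtractionError,
    binarize,
    largest_outer_contour,
    otsu_threshold,
    red_channel,
)


@dataclass
class RestorerConfig:
    """Hyperparameters of the learned restorer.

    ``patch_grid`` pools the patch head's score map to N x N when set
    (N = 1 degenerates the patch head into a second global head); ``None``
    keeps the native map size.  ``global_weight``/``patch_weight`` fuse the
    two adversarial heads (1:1 by default); ``l1_weight`` scales the
    reconstruction term.
    """

    image_size: int = 256
    batch_size: int = 64
    optimizer: str = "Adam"
    lr: float = 0.0002
    max_epochs: int = 500
    patch_grid: int | None = None
    base_channels: int = 8
    adv_weight: float = 1.0
    l1_weight: float = 100.0
    global_weight: float = 0.5
    patch_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.image_size % 8 != 0:
            raise ValueError("image_size must be a multiple of 8 (3 pooling stages)")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path) -> "RestorerConfig":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass
class FusedDiscriminatorOutput:
    """Both discriminator heads' scores for one (condition, candidate) pair."""

    global_score: float
    patch_scores: np.ndarray  # N x N in (0, 1)


# ---------------------------------------------------------------------------
# Generator: U-Net with skip connections
# ---------------------------------------------------------------------------

class UNetGenerator:
    """3-stage encoder-decoder with concatenating skip connections.

    Channel schedule with base c: encoder 3 -> c -> 2c -> 4c (halving
    resolution each stage), bottleneck 4c, decoder mirrors it doubling the
    resolution, each decoder stage consuming [upsampled, skip] concatenated
    features; a final linear conv maps back to 3 channels.  Fully
    convolutional: accepts any input size divisible by 8.
    """

    def __init__(self, config: RestorerConfig | None = None, seed: int = 0):
        self.config = config or RestorerConfig()
        c = self.config.base_channels
        rng = np.random.default_rng(seed)
        L = lambda *a: _nn.Conv2d(*a, rng=rng)  # noqa: E731
        self.enc1 = L(3, c)
        self.enc2 = L(c, 2 * c)
        self.enc3 = L(2 * c, 4 * c)
        self.bott = L(4 * c, 4 * c)
        self.dec3 = L(8 * c, 2 * c)
        self.dec2 = L(4 * c, c)
        self.dec1 = L(2 * c, c)
        self.out = L(c, 3)
        self.pool = _nn.AvgPool2()
        self.up = _nn.UpsampleNearest2()
        self._convs = [
            self.enc1, self.enc2, self.enc3, self.bott,
            self.dec3, self.dec2, self.dec1, self.out,
        ]
        self._relus = {name: _nn.ReLU() for name in
                       ("e1", "e2", "e3", "b", "d3", "d2", "d1")}
        self._pools = [_nn.AvgPool2() for _ in range(3)]
        self._ups = [_nn.UpsampleNearest2() for _ in range(3)]

    @property
    def layers(self) -> list[_nn.Layer]:
        return list(self._convs)

    def feature_schedule(self, size: int | None = None) -> list[tuple[str, int, int]]:
        """(name, channels, spatial size) ledger of the forward pass."""
        s = size or self.config.image_size
        c = self.config.base_channels
        return [
            ("input", 3, s),
            ("enc1", c, s),
            ("enc2", 2 * c, s // 2),
            ("enc3", 4 * c, s // 4),
            ("bottleneck", 4 * c, s // 8),
            ("dec3", 2 * c, s // 4),
            ("dec2", c, s // 2),
            ("dec1", c, s),
            ("output", 3, s),
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] % 8 or x.shape[3] % 8:
            raise ValueError("input size must be a multiple of 8")
        r = self._relus
        e1 = r["e1"].forward(self.enc1.forward(x))
        e2 = r["e2"].forward(self.enc2.forward(self._pools[0].forward(e1)))
        e3 = r["e3"].forward(self.enc3.forward(self._pools[1].forward(e2)))
        b = r["b"].forward(self.bott.forward(self._pools[2].forward(e3)))
        u3 = np.concatenate([self._ups[0].forward(b), e3], axis=1)
        d3 = r["d3"].forward(self.dec3.forward(u3))
        u2 = np.concatenate([self._ups[1].forward(d3), e2], axis=1)
        d2 = r["d2"].forward(self.dec2.forward(u2))
        u1 = np.concatenate([self._ups[2].forward(d2), e1], axis=1)
        d1 = r["d1"].forward(self.dec1.forward(u1))
        self._split = (b.shape[1], d3.shape[1], d2.shape[1])
        return self.out.forward(d1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        r = self._relus
        cb, c3, c2 = self._split
        dd1 = self.dec1.backward(r["d1"].backward(self.out.backward(dout)))
        dup2, de1_skip = dd1[:, : dd1.shape[1] // 2], dd1[:, dd1.shape[1] // 2 :]
        dd2 = self.dec2.backward(r["d2"].backward(self._ups[2].backward(dup2)))
        dup3, de2_skip = dd2[:, : dd2.shape[1] // 2], dd2[:, dd2.shape[1] // 2 :]
        dd3 = self.dec3.backward(r["d3"].backward(self._ups[1].backward(dup3)))
        dub, de3_skip = dd3[:, : dd3.shape[1] // 2], dd3[:, dd3.shape[1] // 2 :]
        db = self.bott.backward(r["b"].backward(self._ups[0].backward(dub)))
        de3 = self.enc3.backward(r["e3"].backward(de3_skip + self._pools[2].backward(db)))
        de2 = self.enc2.backward(r["e2"].backward(de2_skip + self._pools[1].backward(de3)))
        de1 = self.enc1.backward(r["e1"].backward(de1_skip + self._pools[0].backward(de2)))
        return de1

    def zero_grad(self) -> None:
        for layer in self._convs:
            layer.zero_grad()

    # -- convenience --------------------------------------------------------

    def fit_l1(
        self,
        x: np.ndarray,
        y: np.ndarray,
        steps: int = 200,
        lr: float = 1e-3,
        checkpoint_every: int = 25,
    ) -> list[float]:
        """Train with an L1 objective on a fixed batch; return checkpointed errors.

        The returned list holds the mean absolute reconstruction error
        evaluated at step 0 (untrained) and after every
        ``checkpoint_every`` steps.
        """
        opt = _nn.Adam(self.layers, lr=lr)
        errors = [float(np.abs(self.forward(x) - y).mean())]
        for step in range(1, steps + 1):
            opt.zero_grad()
            out = self.forward(x)
            diff = out - y
            dout = np.sign(diff) / diff.size
            self.backward(dout)
            opt.step()
            if step % checkpoint_every == 0:
                errors.append(float(np.abs(self.forward(x) - y).mean()))
        return errors


def build_generator(config: RestorerConfig | None = None, seed: int = 0) -> UNetGenerator:
    return UNetGenerator(config, seed=seed)


# ---------------------------------------------------------------------------
# Fused Global + Patch discriminator
# ---------------------------------------------------------------------------

class FusedDiscriminator:
    """Shared conv trunk with a patch-score head and a global-score head.

    The trunk is three stride-2 4x4 convolutions followed by two stride-1
    4x4 convolutions producing the patch logit map (receptive field 70 px;
    30 x 30 for a 256 input).  The global head average-pools the trunk's
    third feature map and maps it to a single logit.  Both heads consume
    the same concatenated (condition, candidate) pair.
    """

    def __init__(self, config: RestorerConfig | None = None, seed: int = 0):
        self.config = config or RestorerConfig()
        c = self.config.base_channels
        rng = np.random.default_rng(seed)
        self.c1 = _nn.Conv2d(6, c, 4, 2, 1, rng=rng)
        self.c2 = _nn.Conv2d(c, 2 * c, 4, 2, 1, rng=rng)
        self.c3 = _nn.Conv2d(2 * c, 4 * c, 4, 2, 1, rng=rng)
        self.c4 = _nn.Conv2d(4 * c, 4 * c, 4, 1, 1, rng=rng)
        self.c5 = _nn.Conv2d(4 * c, 1, 4, 1, 1, rng=rng)
        self.glob = _nn.Linear(4 * c, 1, rng=rng)
        self._lrelus = [_nn.LeakyReLU() for _ in range(4)]

    @property
    def layers(self) -> list[_nn.Layer]:
        return [self.c1, self.c2, self.c3, self.c4, self.c5, self.glob]

    def forward_logits(
        self, cond: np.ndarray, cand: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """(patch logit map, global logit) for a batch of pairs."""
        x = np.concatenate([cond, cand], axis=1)
        h1 = self._lrelus[0].forward(self.c1.forward(x))
        h2 = self._lrelus[1].forward(self.c2.forward(h1))
        h3 = self._lrelus[2].forward(self.c3.forward(h2))
        h4 = self._lrelus[3].forward(self.c4.forward(h3))
        patch = self.c5.forward(h4)  # (N, 1, hp, wp)
        self._h3_shape = h3.shape
        pooled = h3.mean(axis=(2, 3))
        glob = self.glob.forward(pooled)  # (N, 1)
        if self.config.patch_grid is not None:
            patch = _adaptive_avg(patch, self.config.patch_grid)
            self._native_patch = None
        return patch, glob

    def backward_logits(self, dpatch: np.ndarray, dglob: np.ndarray) -> np.ndarray:
        if self.config.patch_grid is not None:
            dpatch = _adaptive_avg_backward(dpatch)
        dpool = self.glob.backward(dglob)  # (N, 4c)
        n, c, h, w = self._h3_shape
        dh3_global = (dpool / (h * w))[:, :, None, None] * np.ones((n, c, h, w))
        dh4 = self._lrelus[3].backward(self.c5.backward(dpatch))
        dh3 = self._lrelus[2].backward(self.c4.backward(dh4)) + dh3_global
        dh2 = self._lrelus[1].backward(self.c3.backward(dh3))
        dh1 = self._lrelus[0].backward(self.c2.backward(dh2))
        dx = self.c1.backward(dh1)
        return dx[:, 3:]  # gradient w.r.t. the candidate half only

    def forward(self, cond: np.ndarray, cand: np.ndarray) -> FusedDiscriminatorOutput:
        """Scores (not logits) for a single (condition, candidate) pair."""
        c = _to_nchw(cond)
        a = _to_nchw(cand)
        patch, glob = self.forward_logits(c, a)
        return FusedDiscriminatorOutput(
            global_score=float(_nn.sigmoid(glob)[0, 0]),
            patch_scores=_nn.sigmoid(patch)[0, 0],
        )

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()


def _adaptive_avg(patch: np.ndarray, n: int) -> np.ndarray:
    """Average-pool an (N, 1, H, W) logit map to (N, 1, n, n)."""
    N, _, H, W = patch.shape
    ys = np.linspace(0, H, n + 1).astype(int)
    xs = np.linspace(0, W, n + 1).astype(int)
    out = np.empty((N, 1, n, n))
    cache = np.empty((n, n, 4), dtype=int)
    for i in range(n):
        for j in range(n):
            y0, y1, x0, x1 = ys[i], ys[i + 1], xs[j], xs[j + 1]
            cache[i, j] = (y0, y1, x0, x1)
            out[:, :, i, j] = patch[:, :, y0:y1, x0:x1].mean(axis=(2, 3))
    _adaptive_avg.last_cache = (cache, (N, 1, H, W))
    return out


def _adaptive_avg_backward(dout: np.ndarray, _cache_unused=None) -> np.ndarray:
    cache, shape = _adaptive_avg.last_cache
    dpatch = np.zeros(shape)
    n = dout.shape[2]
    for i in range(n):
        for j in range(n):
            y0, y1, x0, x1 = cache[i, j]
            dpatch[:, :, y0:y1, x0:x1] += dout[:, :, i : i + 1, j : j + 1] / (
                (y1 - y0) * (x1 - x0)
            )
    return dpatch


def build_discriminator(
    config: RestorerConfig | None = None, seed: int = 0
) -> FusedDiscriminator:
    return FusedDiscriminator(config, seed=seed)


# ---------------------------------------------------------------------------
# Training loop (conditional GAN)
# ---------------------------------------------------------------------------

def _to_nchw(img: np.ndarray) -> np.ndarray:
    """uint8 HWC or float NCHW -> float64 NCHW in [0, 1]."""
    a = np.asarray(img)
    if a.ndim == 3:
        a = a[None]
    if a.shape[-1] == 3 and a.shape[1] != 3:
        a = a.transpose(0, 3, 1, 2)
    a = a.astype(np.float64)
    if a.max() > 1.5:
        a = a / 255.0
    return a


class Restorer:
    """A trained restorer closure around the U-Net generator."""

    def __init__(self, generator: UNetGenerator, config: RestorerConfig,
                 history: list[dict] | None = None):
        self.generator = generator
        self.config = config
        self.history = history or []

    def restore(
        self, occluded: np.ndarray, visible_mask: np.ndarray | None = None
    ) -> np.ndarray:
        """Restore one 8-bit RGB crop.

        When ``visible_mask`` is given, observed pixels are copied through
        unchanged, so the restored silhouette contains the visible one.
        """
        x = _to_nchw(occluded)
        out = self.generator.forward(x)
        img = np.clip(out[0].transpose(1, 2, 0) * 255.0, 0, 255).astype(np.uint8)
        if visible_mask is not None:
            img = img.copy()
            img[visible_mask] = np.asarray(occluded)[visible_mask]
        return img

    def save(self, path) -> None:
        state = _nn.collect_state(self.generator.layers)
        np.savez(Path(path), **state)

    @classmethod
    def load(cls, path, config: RestorerConfig | None = None) -> "Restorer":
        config = config or RestorerConfig()
        gen = UNetGenerator(config)
        with np.load(Path(path)) as data:
            _nn.load_state(gen.layers, dict(data))
        return cls(gen, config)


def train(
    pairs: Sequence[PairedSample],
    config: RestorerConfig | None = None,
    seed: int = 0,
    steps: int | None = None,
    checkpoint_every: int = 25,
    val_pairs: Sequence[PairedSample] | None = None,
    checkpoint_dir=None,
) -> Restorer:
    """Train the conditional-GAN restorer on paired occluded/clean samples.

    Alternates one discriminator step (real pair -> 1, generated pair -> 0,
    fused global+patch BCE) and one generator step (fused adversarial loss
    toward 1 plus ``l1_weight`` x L1 reconstruction).  ``steps`` caps the
    number of optimisation steps (otherwise ``max_epochs`` passes over the
    data); fully deterministic for a fixed seed.  Non-finite losses raise
    ``RuntimeError``.
    """
    if not pairs:
        raise ValueError("empty training set")
    config = config or RestorerConfig()
    rng = np.random.default_rng(seed)
    gen = UNetGenerator(config, seed=seed)
    disc = FusedDiscriminator(config, seed=seed + 1)
    g_opt = _nn.Adam(gen.layers, lr=config.lr)
    d_opt = _nn.Adam(disc.layers, lr=config.lr)

    X = np.stack([_to_nchw(p.occluded)[0] for p in pairs])
    Y = np.stack([_to_nchw(p.clean)[0] for p in pairs])
    vals = val_pairs if val_pairs is not None else pairs
    VX = np.stack([_to_nchw(p.occluded)[0] for p in vals])
    VY = np.stack([_to_nchw(p.clean)[0] for p in vals])

    n = len(pairs)
    bs = min(config.batch_size, n)
    total_steps = steps if steps is not None else config.max_epochs * max(1, n // bs)
    history: list[dict] = []

    def val_l1() -> float:
        return float(np.abs(gen.forward(VX) - VY).mean())

    history.append({"step": 0, "g_loss": math.nan, "d_loss": math.nan,
                    "val_l1": val_l1()})
    gw, pw = config.global_weight, config.patch_weight
    for step in range(1, total_steps + 1):
        idx = rng.choice(n, size=bs, replace=False)
        xb, yb = X[idx], Y[idx]

        # --- discriminator step
        d_opt.zero_grad()
        fake = gen.forward(xb)
        p_real, g_real = disc.forward_logits(xb, yb)
        lp, dlp = _nn.bce_with_logits(p_real, 1.0)
        lg, dlg = _nn.bce_with_logits(g_real, 1.0)
        d_loss = pw * lp + gw * lg
        disc.backward_logits(pw * dlp, gw * dlg)
        p_fake, g_fake = disc.forward_logits(xb, fake)
        lp, dlp = _nn.bce_with_logits(p_fake, 0.0)
        lg, dlg = _nn.bce_with_logits(g_fake, 0.0)
        d_loss += pw * lp + gw * lg
        disc.backward_logits(pw * dlp, gw * dlg)
        d_opt.step()

        # --- generator step
        g_opt.zero_grad()
        fake = gen.forward(xb)
        p_fake, g_fake = disc.forward_logits(xb, fake)
        lp, dlp = _nn.bce_with_logits(p_fake, 1.0)
        lg, dlg = _nn.bce_with_logits(g_fake, 1.0)
        adv = pw * lp + gw * lg
        disc.zero_grad()  # discriminator params are frozen in this step
        dfake_adv = disc.backward_logits(pw * dlp, gw * dlg)
        diff = fake - yb
        l1 = float(np.abs(diff).mean())
        dfake = config.adv_weight * dfake_adv + config.l1_weight * np.sign(diff) / diff.size
        gen.backward(dfake)
        g_opt.step()

        g_loss = config.adv_weight * adv + config.l1_weight * l1
        if not (np.isfinite(g_loss) and np.isfinite(d_loss)):
            raise RuntimeError(f"training diverged at step {step}: "
                               f"g_loss={g_loss}, d_loss={d_loss}")
        if step % checkpoint_every == 0 or step == total_steps:
            entry = {"step": step, "g_loss": g_loss, "d_loss": d_loss,
                     "val_l1": val_l1()}
            history.append(entry)
            if checkpoint_dir is not None:
                path = Path(checkpoint_dir) / f"restorer_step{step:06d}.npz"
                np.savez(path, **_nn.collect_state(gen.layers))
    return Restorer(gen, config, history)


# ---------------------------------------------------------------------------
# Deterministic geometric baseline
# ---------------------------------------------------------------------------

def restore_baseline(
    occluded: np.ndarray,
    occluder_mask: np.ndarray,
    min_visible_fraction: float = 0.3,
) -> np.ndarray:
    """Complete an occluded grain by least-squares ellipse extrapolation.

    The visible silhouette (Otsu foreground minus the occluder) must make
    up at least ``min_visible_fraction`` of the crop's foreground.  Its
    boundary points away from the occluder are fitted with an ellipse; the
    occluder's pixels are then repainted as grain (median visible grain
    colour) inside the fitted ellipse and as background outside it.
    Deterministic; the visible silhouette is always preserved.
    """
    occluded = np.asarray(occluded)
    occluder_mask = np.asarray(occluder_mask, dtype=bool)
    if occluded.shape[:2] != occluder_mask.shape:
        raise ValueError("occluder mask shape must match the crop")
    if not occluder_mask.any():
        return occluded.copy()
    gray = red_channel(occluded)
    thr = otsu_threshold(gray)
    fg = binarize(gray, thr)
    visible = fg & ~occluder_mask
    fg_area = int(fg.sum())
    if fg_area == 0 or int(visible.sum()) / fg_area < min_visible_fraction:
        raise ValueError(
            "too little visible silhouette to extrapolate "
            f"({int(visible.sum())}/{fg_area} foreground pixels)"
        )
    contour = largest_outer_contour(visible)
    # keep only boundary points that are true grain boundary, not the cut
    # introduced by the occluder
    near_occ = ndimage.binary_dilation(occluder_mask, iterations=3)
    pts = contour.points
    xi = np.clip(np.round(pts[:, 0]).astype(int), 0, occluder_mask.shape[1] - 1)
    yi = np.clip(np.round(pts[:, 1]).astype(int), 0, occluder_mask.shape[0] - 1)
    keep = ~near_occ[yi, xi]
    pts = pts[keep]
    if len(pts) < 10:
        raise ValueError("too few unoccluded boundary points for the ellipse fit")
    model = EllipseModel.from_estimate(pts)
    if not model:
        raise ValueError("ellipse fit failed on the visible boundary")
    xc, yc = model.center
    a, b = model.axis_lengths
    theta = model.theta

    H, W = occluder_mask.shape
    ys, xs = np.nonzero(occluder_mask)
    dx = xs - xc
    dy = ys - yc
    ct, st = math.cos(theta), math.sin(theta)
    u = (ct * dx + st * dy) / a
    v = (-st * dx + ct * dy) / b
    inside = (u * u + v * v) <= 1.0

    grain_color = np.median(occluded[visible].reshape(-1, 3), axis=0)
    bg_mask = ~fg & ~occluder_mask
    if bg_mask.any():
        bg_color = np.median(occluded[bg_mask].reshape(-1, 3), axis=0)
    else:
        bg_color = np.array(BACKGROUND_RGB, dtype=float)

    restored = occluded.copy()
    restored[ys[inside], xs[inside]] = np.round(grain_color).astype(np.uint8)
    restored[ys[~inside], xs[~inside]] = np.round(bg_color).astype(np.uint8)
    return restored
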