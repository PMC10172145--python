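"""Virtual-scanning view super-resolution network.

Maps scale-1 spatial-angular views to scale-3 views, emulating the 3x3
hardware scan of a scanning light-field microscope.  The architecture
follows the three-feature design for phase-correlated angular views:

* a feature extractor built from linear operations only (reshaping /
  decoupling convolutions, biases allowed, no nonlinearity) producing
  - spatial-angular features, one C-channel map per angular view,
  - light-field features on the macro-pixel interleaved (h*a, w*a) grid,
    extracted with an angular-stride dilated convolution (dilation = a),
  - angular-mixed features, a learned 1x1 weighted mix over all angles;
* K cascaded interaction blocks in the light-field domain, each fusing the
  light-field feature with the (realigned) spatial-angular and
  angular-mixed features through a dilated convolution with a local
  residual connection;
* concatenation of the K block outputs with the two realigned companion
  features -> (K+2)*C channels, squeezed to C by a 1x1 convolution and
  leaky-rectified activation;
* an upsampling head (per-angle convolution to scale^2 channels + pixel
  shuffle x3) added to the bicubically upsampled input (global residual),
  so zeroing the learned head reduces the network to exact bicubic
  upsampling.

Training uses the L1 loss with Adam (beta1 = 0.9, beta2 = 0.999), learning
rate 2e-4 halved every 10 epochs, on 25 -> 75 pixel patch pairs.

This is a self-contained CPU implementation: convolutions, the pixel
shuffle and Adam are written on numpy arrays with explicit backward passes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from .realign import SpatialAngularViews

__all__ = [
    "VsNetConfig",
    "TrainConfig",
    "VsNet",
    "bicubic_upsample_views",
    "extract_features",
    "interact_fuse",
    "predict_patch",
    "enhance_fov",
    "train",
    "normalize_dataset",
    "denormalize",
    "adapt_angle_count",
    "sample_patch_pairs",
    "save_checkpoint",
    "load_checkpoint",
]

DTYPE = np.float32


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class VsNetConfig:
    """Architecture hyperparameters.

    ``channels`` (C) is the 2D-convolution feature width, default 64;
    ``cascades`` (K) the number of interaction blocks, default 4; the
    upsampling ``scale`` is fixed at 3 (one virtual 3x3 scan).
    """

    n_angles_side: int = 13
    channels: int = 64
    cascades: int = 4
    scale: int = 3
    leaky_slope: float = 0.1

    def __post_init__(self) -> None:
        if self.scale != 3:
            raise ValueError("the virtual scan factor is fixed at 3")
        if self.channels < 1 or self.cascades < 1:
            raise ValueError("channels and cascades must be >= 1")
        if self.n_angles_side % 2 == 0:
            raise ValueError("angular side must be odd")


@dataclass
class TrainConfig:
    """Optimisation settings (defaults follow the published schedule)."""

    lr0: float = 2e-4
    lr_halve_every: int = 10
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    epochs: int = 40
    batch_size: int = 4
    patch_in: int = 25
    seed: int = 0

    @property
    def patch_out(self) -> int:
        return 3 * self.patch_in

    def lr_at(self, epoch: int) -> float:
        """Learning rate for a 0-based epoch (halved every 10 by default)."""
        return self.lr0 * 0.5 ** (epoch // self.lr_halve_every)


# ---------------------------------------------------------------------------
# primitive layers (numpy, explicit backward)
# ---------------------------------------------------------------------------

class _Conv2d:
    """Same-padded 2D convolution with optional dilation, im2col based."""

    def __init__(self, cin: int, cout: int, ksize: int, dilation: int,
                 rng: np.random.Generator, zero_init: bool = False):
        self.ksize, self.dilation = ksize, dilation
        fan_in = cin * ksize * ksize
        scale = 0.0 if zero_init else math.sqrt(2.0 / fan_in)
        self.w = (rng.standard_normal((cout, cin, ksize, ksize))
                  * scale).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cols = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, d = self.ksize, self.dilation
        pad = d * (k // 2)
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        B, C, H, W = x.shape
        s = xp.strides
        return np.lib.stride_tricks.as_strided(
            xp, (B, C, k, k, H, W),
            (s[0], s[1], s[2] * d, s[3] * d, s[2], s[3]))

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols = self._im2col(np.ascontiguousarray(x, dtype=DTYPE))
        self._cols = cols
        y = np.einsum("ockl,bcklhw->bohw", self.w, cols, optimize=True)
        return y + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = np.ascontiguousarray(dy, dtype=DTYPE)
        cols = self._cols
        self.gw += np.einsum("bohw,bcklhw->ockl", dy, cols, optimize=True)
        self.gb += dy.sum(axis=(0, 2, 3))
        k, d = self.ksize, self.dilation
        pad = d * (k // 2)
        B, _, H, W = dy.shape
        cin = self.w.shape[1]
        dxp = np.zeros((B, cin, H + 2 * pad, W + 2 * pad), dtype=DTYPE)
        dcols = np.einsum("ockl,bohw->bcklhw", self.w, dy, optimize=True)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i * d:i * d + H, j * d:j * d + W] += dcols[:, :, i, j]
        self._cols = None
        return dxp[:, :, pad:pad + H, pad:pad + W] if pad else dxp

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class _LeakyReLU:
    def __init__(self, slope: float):
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)


def _pixel_shuffle(x: np.ndarray, r: int) -> np.ndarray:
    B, C, H, W = x.shape
    c = C // (r * r)
    return (x.reshape(B, c, r, r, H, W)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(B, c, H * r, W * r))


def _pixel_shuffle_back(dy: np.ndarray, r: int) -> np.ndarray:
    B, c, Hr, Wr = dy.shape
    H, W = Hr // r, Wr // r
    return (dy.reshape(B, c, H, r, W, r)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(B, c * r * r, H, W))


def _interleave(views: np.ndarray, a: int) -> np.ndarray:
    """(a*a, C, h, w) angle-major -> (1, C, h*a, w*a) macro-pixel layout."""
    A, C, h, w = views.shape
    return (views.reshape(a, a, C, h, w)
            .transpose(2, 3, 0, 4, 1)          # C, h, u, w, v
            .reshape(1, C, h * a, w * a))


def _deinterleave(lf: np.ndarray, a: int) -> np.ndarray:
    """Inverse of :func:`_interleave`."""
    _, C, Ha, Wa = lf.shape
    h, w = Ha // a, Wa // a
    return (lf.reshape(C, h, a, w, a)
            .transpose(2, 4, 0, 1, 3)          # u, v, C, h, w
            .reshape(a * a, C, h, w))


def _upsample_nearest(x: np.ndarray, a: int) -> np.ndarray:
    return np.repeat(np.repeat(x, a, axis=2), a, axis=3)


def _upsample_nearest_back(dy: np.ndarray, a: int) -> np.ndarray:
    B, C, Ha, Wa = dy.shape
    h, w = Ha // a, Wa // a
    return dy.reshape(B, C, h, a, w, a).sum(axis=(3, 5))


def bicubic_upsample_views(views: np.ndarray, scale: int = 3) -> np.ndarray:
    """Bicubic x``scale`` upsampling of each angular view (A, h, w).

    Pixel-center aligned, so low-resolution samples coincide with the
    central sub-phase of the fine grid — the same convention the scan
    realignment uses.
    """
    A, h, w = views.shape
    out = np.empty((A, h * scale, w * scale), dtype=np.float64)
    for i in range(A):
        out[i] = _sk_resize(views[i].astype(np.float64),
                            (h * scale, w * scale), order=3, mode="edge",
                            anti_aliasing=False, preserve_range=True)
    return out


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class VsNet:
    """Three-branch virtual-scanning super-resolution network (see module
    docstring for the architecture)."""

    def __init__(self, cfg: VsNetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        a, C, K = cfg.n_angles_side, cfg.channels, cfg.cascades
        A = a * a
        # linear feature extractor
        self.conv_sa = _Conv2d(1, C, 3, 1, rng)          # per-angle, shared
        self.conv_lf = _Conv2d(1, C, 3, a, rng)          # dilated, LF domain
        self.conv_am = _Conv2d(A, C, 1, 1, rng)          # angular mix
        # interaction blocks
        self.blocks = [_Conv2d(3 * C, C, 3, a, rng) for _ in range(K)]
        self.block_acts = [_LeakyReLU(cfg.leaky_slope) for _ in range(K)]
        # fusion and upsampling head; the head starts at zero so an
        # untrained network is exactly the bicubic baseline and training
        # only ever adds detail on top of the global residual
        self.conv_fuse = _Conv2d((K + 2) * C, C, 1, 1, rng)
        self.act_fuse = _LeakyReLU(cfg.leaky_slope)
        self.conv_up = _Conv2d(C, cfg.scale**2, 3, 1, rng, zero_init=True)
        self.norm_divisor: float = 1.0

    # -- parameter plumbing -------------------------------------------------
    def layers(self):
        return ([self.conv_sa, self.conv_lf, self.conv_am]
                + self.blocks + [self.conv_fuse, self.conv_up])

    def params(self):
        out = []
        for layer in self.layers():
            out.extend(layer.params())
        return out

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0

    def zero_head(self) -> None:
        """Zero the upsampling head: the network becomes exact bicubic."""
        self.conv_up.w[...] = 0.0
        self.conv_up.b[...] = 0.0

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray,
                base: np.ndarray | None = None) -> np.ndarray:
        """x: (A, h, w) scale-1 views -> (A, 3h, 3w) scale-3 views.

        ``base`` may carry a precomputed bicubic upsample of ``x`` (the
        global residual), which the training loop caches per patch.
        """
        cfg = self.cfg
        a, A = cfg.n_angles_side, cfg.n_angles_side**2
        if x.shape[0] != A:
            raise ValueError("angle count mismatch with the configuration")
        x32 = np.ascontiguousarray(x, dtype=DTYPE)

        f_sa = self.conv_sa.forward(x32[:, None])            # (A, C, h, w)
        lf_in = _interleave(x32[:, None], a)                 # (1, 1, ah, aw)
        f_lf = self.conv_lf.forward(lf_in)                   # (1, C, ah, aw)
        f_am = self.conv_am.forward(x32[None])               # (1, C, h, w)

        g_sa = _interleave(f_sa, a)                          # (1, C, ah, aw)
        g_am = _upsample_nearest(f_am, a)                    # (1, C, ah, aw)

        feats = [f_lf]
        for blk, act in zip(self.blocks, self.block_acts):
            inp = np.concatenate([feats[-1], g_sa, g_am], axis=1)
            out = act.forward(blk.forward(inp)) + feats[-1]  # local residual
            feats.append(out)
        cat = np.concatenate(feats[1:] + [g_sa, g_am], axis=1)  # (K+2)C
        fused = self.act_fuse.forward(self.conv_fuse.forward(cat))

        per_angle = _deinterleave(fused, a)                  # (A, C, h, w)
        up = self.conv_up.forward(per_angle)                 # (A, 9, h, w)
        hi = _pixel_shuffle(up, cfg.scale)[:, 0]             # (A, 3h, 3w)
        if base is None:
            base = bicubic_upsample_views(np.asarray(x, dtype=np.float64),
                                          cfg.scale)
        return hi.astype(np.float64) + base

    def backward(self, dout: np.ndarray) -> None:
        """Accumulate parameter gradients for d(loss)/d(output)."""
        cfg = self.cfg
        a, K, C = cfg.n_angles_side, cfg.cascades, cfg.channels
        dup = _pixel_shuffle_back(dout.astype(DTYPE)[:, None], cfg.scale)
        d_pa = self.conv_up.backward(dup)
        d_fused = _interleave(d_pa, a)
        d_cat = self.conv_fuse.backward(self.act_fuse.backward(d_fused))
        d_feats = list(np.split(d_cat, K + 2, axis=1))
        d_gsa = d_feats[K]
        d_gam = d_feats[K + 1]
        grad = np.zeros_like(d_feats[0])
        for k in range(K - 1, -1, -1):
            grad = grad + d_feats[k]
            d_inp = self.blocks[k].backward(
                self.block_acts[k].backward(grad))
            d_prev, d_s, d_m = (d_inp[:, :C], d_inp[:, C:2 * C],
                                d_inp[:, 2 * C:])
            d_gsa = d_gsa + d_s
            d_gam = d_gam + d_m
            grad = grad + d_prev  # residual path
            if k == 0:
                d_flf = grad
        d_fam = _upsample_nearest_back(d_gam, a)
        d_fsa = _deinterleave(d_gsa, a)
        self.conv_am.backward(d_fam)
        self.conv_lf.backward(d_flf)
        self.conv_sa.backward(d_fsa)


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def _views_array(views) -> np.ndarray:
    if isinstance(views, SpatialAngularViews):
        a = views.n_angles_side
        return views.data.reshape(a * a, *views.data.shape[2:])
    return np.asarray(views)


def extract_features(patch, cfg: VsNetConfig, seed: int = 0) -> dict:
    """Run the (randomly initialised) linear feature extractor on a patch.

    Exposes the three feature domains and their shape contract: for an
    h x h x a^2 input the spatial-angular branch is (a^2, h, h, C), the
    light-field branch (h*a, h*a, C) and the angular-mixed branch (h, h, C).
    """
    x = _views_array(patch)
    a = cfg.n_angles_side
    if x.shape[0] != a * a:
        raise ValueError("angle count mismatch with the configuration")
    net = VsNet(cfg, seed=seed)
    x32 = np.ascontiguousarray(x, dtype=DTYPE)
    f_sa = net.conv_sa.forward(x32[:, None])
    f_lf = net.conv_lf.forward(_interleave(x32[:, None], a))
    f_am = net.conv_am.forward(x32[None])
    return {
        "spatial_angular": f_sa.transpose(0, 2, 3, 1),
        "light_field": f_lf[0].transpose(1, 2, 0),
        "angular_mixed": f_am[0].transpose(1, 2, 0),
    }


def interact_fuse(patch, cfg: VsNetConfig, seed: int = 0) -> dict:
    """Run extractor + K interaction blocks + fusion; report the channel
    bookkeeping ((K+2)*C concatenated -> C fused) and the fused feature."""
    x = _views_array(patch)
    net = VsNet(cfg, seed=seed)
    a, C, K = cfg.n_angles_side, cfg.channels, cfg.cascades
    x32 = np.ascontiguousarray(x, dtype=DTYPE)
    f_lf = net.conv_lf.forward(_interleave(x32[:, None], a))
    g_sa = _interleave(net.conv_sa.forward(x32[:, None]), a)
    g_am = _upsample_nearest(net.conv_am.forward(x32[None]), a)
    feats = [f_lf]
    for blk, act in zip(net.blocks, net.block_acts):
        inp = np.concatenate([feats[-1], g_sa, g_am], axis=1)
        feats.append(act.forward(blk.forward(inp)) + feats[-1])
    cat = np.concatenate(feats[1:] + [g_sa, g_am], axis=1)
    fused = net.act_fuse.forward(net.conv_fuse.forward(cat))
    return {"concat_channels": cat.shape[1],
            "expected_concat_channels": (K + 2) * C,
            "fused": fused[0].transpose(1, 2, 0)}


def predict_patch(patch, model: VsNet) -> np.ndarray:
    """Enhance one scale-1 patch to scale 3: (A, h, w) -> (A, 3h, 3w)."""
    x = _views_array(patch)
    return model.forward(x)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _tile_weight(length: int, overlap: int, has_prev: bool,
                 has_next: bool) -> np.ndarray:
    """Per-axis sigmoid fusion ramp; flat where no neighbour overlaps."""
    w = np.ones(length)
    if overlap <= 0:
        return w
    d = np.arange(length, dtype=np.float64)
    tau = max(overlap / 8.0, 1e-6)
    if has_prev:
        w *= _sigmoid((d - overlap / 2.0) / tau)
    if has_next:
        w *= _sigmoid(((length - 1 - d) - overlap / 2.0) / tau)
    return w


def enhance_fov(views, model: VsNet, patch_side: int | None = None
                ) -> SpatialAngularViews:
    """Tiled full-field inference with sigmoid-weighted fusion.

    The field is partitioned into a 3x3 grid of partially overlapping
    patches (69-pixel patches with stride 42 for the standard 153-pixel
    field, giving nine 207-pixel outputs fused into 459); fusion weights
    are renormalised so they sum to 1 at every output pixel.
    """
    x = _views_array(views)
    A, S, S2 = x.shape
    if S != S2:
        raise ValueError("field must be square")
    if patch_side is None:
        patch_side = round(S * 69 / 153)
        if (S - patch_side) % 2:
            patch_side += 1
    if patch_side > S or (S - patch_side) % 2:
        raise ValueError("field side is not tileable: need (side - patch) "
                         "divisible by 2")
    stride = (S - patch_side) // 2
    scale = model.cfg.scale
    out_side = S * scale
    p_out = patch_side * scale
    overlap_out = (patch_side - stride) * scale
    num = np.zeros((A, out_side, out_side))
    den = np.zeros((out_side, out_side))
    starts = [0, stride, 2 * stride] if stride > 0 else [0]
    for gi, sy in enumerate(starts):
        wy = _tile_weight(p_out, overlap_out, gi > 0, gi < len(starts) - 1)
        for gj, sx in enumerate(starts):
            wx = _tile_weight(p_out, overlap_out, gj > 0,
                              gj < len(starts) - 1)
            w2 = np.outer(wy, wx)
            pred = model.forward(x[:, sy:sy + patch_side,
                                   sx:sx + patch_side])
            oy, ox = sy * scale, sx * scale
            num[:, oy:oy + p_out, ox:ox + p_out] += pred * w2[None]
            den[oy:oy + p_out, ox:ox + p_out] += w2
    out = num / den[None]
    a = model.cfg.n_angles_side
    return SpatialAngularViews(out.reshape(a, a, out_side, out_side),
                               n_angles_side=a, scale=3)


# ---------------------------------------------------------------------------
# dataset utilities and training
# ---------------------------------------------------------------------------

def normalize_dataset(stacks: list) -> tuple[list, float]:
    """Divide every stack by the mean of the per-stack maxima.

    This is the intensity convention for time-lapse training data: one
    shared divisor keeps relative brightness between stacks, and the
    divisor is returned for inversion with :func:`denormalize`.
    """
    arrays = [np.asarray(s, dtype=np.float64) for s in stacks]
    if not arrays:
        raise ValueError("empty dataset")
    maxima = [float(a.max()) for a in arrays]
    divisor = float(np.mean(maxima))
    if divisor <= 0:
        raise ValueError("all-zero dataset cannot be normalized")
    return [a / divisor for a in arrays], divisor


def denormalize(stack: np.ndarray, divisor: float) -> np.ndarray:
    return np.asarray(stack) * divisor


def sample_patch_pairs(lr_views: np.ndarray, hr_views: np.ndarray,
                       n_patches: int, patch_in: int,
                       rng: np.random.Generator,
                       content_bias: float = 0.5) -> list:
    """Random co-located (scale-1, scale-3) patch crops from a view pair.

    ``content_bias`` rejects (with retries) crops whose summed intensity
    falls below that fraction of the mean candidate mass, so sparse scenes
    still contribute informative patches; 0 disables the bias.
    """
    lr = _views_array(lr_views)
    hr = _views_array(hr_views)
    if hr.shape[1] != 3 * lr.shape[1]:
        raise ValueError("pair is not a x3 scale pair")
    side = lr.shape[1]
    if patch_in > side:
        raise ValueError("patch larger than the field")
    mean_mass = float(lr.sum()) * (patch_in / side) ** 2
    pairs = []
    for _ in range(n_patches):
        for _attempt in range(20):
            y = int(rng.integers(0, side - patch_in + 1))
            x = int(rng.integers(0, side - patch_in + 1))
            crop = lr[:, y:y + patch_in, x:x + patch_in]
            if content_bias <= 0 or crop.sum() >= content_bias * mean_mass:
                break
        pairs.append((crop.copy(),
                      hr[:, 3 * y:3 * (y + patch_in),
                         3 * x:3 * (x + patch_in)].copy()))
    return pairs


def l1_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size


class _Adam:
    def __init__(self, params, beta1: float, beta2: float, eps: float = 1e-8):
        self.params = params
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def train(pairs: list, cfg: VsNetConfig, tcfg: TrainConfig | None = None,
          model: VsNet | None = None, norm_divisor: float = 1.0,
          log_every: int = 0) -> tuple[VsNet, dict]:
    """Train a network on (scale-1 patch, scale-3 patch) pairs.

    Adam with the configured betas; learning rate 2e-4 halved every 10
    epochs; L1 loss.  One global seed drives weight initialisation and
    shuffling.  Returns the model and a history dict with the per-epoch
    mean training loss and learning rates.  Raises on an empty dataset or
    if the loss turns non-finite.
    """
    if not pairs:
        raise ValueError("empty training dataset")
    tcfg = tcfg or TrainConfig()
    rng = np.random.default_rng(tcfg.seed)
    if model is None:
        model = VsNet(cfg, seed=tcfg.seed)
    model.norm_divisor = norm_divisor
    opt = _Adam(model.params(), tcfg.adam_beta1, tcfg.adam_beta2)
    history = {"loss": [], "lr": []}
    n = len(pairs)
    bases = [bicubic_upsample_views(np.asarray(p[0], dtype=np.float64), 3)
             for p in pairs]
    for epoch in range(tcfg.epochs):
        lr = tcfg.lr_at(epoch)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tcfg.batch_size):
            model.zero_grad()
            batch = order[start:start + tcfg.batch_size]
            bl = 0.0
            for idx in batch:
                xin, target = pairs[idx]
                pred = model.forward(xin, base=bases[idx])
                loss, dpred = l1_loss(pred, np.asarray(target,
                                                       dtype=np.float64))
                model.backward(dpred / len(batch))
                bl += loss / len(batch)
            if not math.isfinite(bl):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {bl}")
            opt.step(lr)
            losses.append(bl)
        history["loss"].append(float(np.mean(losses)))
        history["lr"].append(lr)
        if log_every and (epoch + 1) % log_every == 0:
            print(f"epoch {epoch + 1}/{tcfg.epochs}  "
                  f"loss {history['loss'][-1]:.5f}  lr {lr:.2e}")
    return model, history


def adapt_angle_count(views: SpatialAngularViews,
                      target_side: int) -> SpatialAngularViews:
    """Bilinear interpolation over the angular (u, v) grid.

    Lets a model trained on one microlens geometry consume data from
    another (e.g. 13x13 -> 21x21).  Grid endpoints coincide, so the
    central (chief-ray) view is preserved bit-exactly when both sides are
    odd.
    """
    if target_side < 3 or target_side % 2 == 0:
        raise ValueError("target angular side must be odd and >= 3")
    a_src = views.n_angles_side
    if a_src == target_side:
        return views
    pos = np.arange(target_side) * (a_src - 1) / (target_side - 1)
    i0 = np.minimum(pos.astype(int), a_src - 2)
    frac = pos - i0
    data = views.data.astype(np.float64)
    # interpolate along u then v
    du = (data[i0] * (1 - frac)[:, None, None, None]
          + data[i0 + 1] * frac[:, None, None, None])
    dv = (du[:, i0] * (1 - frac)[None, :, None, None]
          + du[:, i0 + 1] * frac[None, :, None, None])
    exact = np.isclose(frac, 0.0)
    dv[np.ix_(exact, exact)] = data[np.ix_(i0[exact], i0[exact])]
    return SpatialAngularViews(dv, n_angles_side=target_side,
                               scale=views.scale)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: VsNet, path, seed: int | None = None,
                    extra: dict | None = None) -> None:
    """Single-file archive: config, weights, normalisation divisor, seed."""
    cfg = model.cfg
    payload = {
        "cfg_n_angles_side": cfg.n_angles_side,
        "cfg_channels": cfg.channels,
        "cfg_cascades": cfg.cascades,
        "cfg_leaky_slope": cfg.leaky_slope,
        "norm_divisor": model.norm_divisor,
        "seed": -1 if seed is None else seed,
    }
    for i, (p, _) in enumerate(model.params()):
        payload[f"param_{i}"] = p
    if extra:
        payload.update(extra)
    np.savez_compressed(str(path), **payload)


def load_checkpoint(path) -> VsNet:
    arch = np.load(str(path) if str(path).endswith(".npz")
                   else str(path) + ".npz")
    cfg = VsNetConfig(n_angles_side=int(arch["cfg_n_angles_side"]),
                      channels=int(arch["cfg_channels"]),
                      cascades=int(arch["cfg_cascades"]),
                      leaky_slope=float(arch["cfg_leaky_slope"]))
    model = VsNet(cfg, seed=0)
    for i, (p, _) in enumerate(model.params()):
        p[...] = arch[f"param_{i}"]
    model.norm_divisor = float(arch["norm_divisor"])
    return model
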