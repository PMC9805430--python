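"""Modified U-Net that segments future geographic atrophy from baseline
OCT B-scans.

The network is the classic encoder/decoder with skip connections, with
square kernels throughout, two convolutions + ReLU per block, 2x2 max
pooling, learned 2x2 upsampling, and a final 1x1 convolution to a
two-channel (positive, negative) softmax. It is trained per B-scan with a
compound loss: a smoothed soft-Dice term plus the mean binary cross
entropy of the positive-class probability,

    L = (1 - (2|y ∩ ŷ| + 1) / (|y| + |ŷ| + 1)) + H(y, ŷ)

with set cardinalities read as sums of probabilities, so the loss is
differentiable. Optimization is Adam at learning rate 1e-4.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from ._nn import Conv2d, UpConv2x2, maxpool2x2, unpool2x2, Adam

_CLAMP = 1e-7  # BCE probability clamp


@dataclass
class UNetConfig:
    """Architecture and training hyperparameters.

    ``in_shape`` is (height, width) of one B-scan and must be divisible by
    ``2**depth`` so that every pooling halves cleanly.
    """

    depth: int = 4
    base_channels: int = 16
    kernel_size: int = 3
    in_shape: tuple = (256, 128)
    learning_rate: float = 1e-4
    epochs: int = 50
    batch_size: int = 8
    prior_bias_init: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.kernel_size % 2 != 1 or self.kernel_size < 1:
            raise ValueError("kernel must be square with odd extent")
        h, w = self.in_shape
        f = 2 ** self.depth
        if h % f or w % f:
            raise ValueError(
                f"in_shape {self.in_shape} not divisible by 2^depth = {f}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class LossValue:
    total: float
    dice_term: float
    bce_term: float


class _ConvBlock:
    """Two same-padded convolutions, each followed by ReLU."""

    def __init__(self, in_ch, out_ch, k, rng, dtype):
        self.conv1 = Conv2d(in_ch, out_ch, k, rng, dtype)
        self.conv2 = Conv2d(out_ch, out_ch, k, rng, dtype)
        self._m1 = self._m2 = None

    def forward(self, x, keep=True):
        a = self.conv1.forward(x, keep=keep)
        np.maximum(a, 0, out=a)
        if keep:
            self._m1 = a > 0
        b = self.conv2.forward(a, keep=keep)
        np.maximum(b, 0, out=b)
        if keep:
            self._m2 = b > 0
        return b

    def backward(self, dy, need_input_grad=True):
        dy = dy * self._m2
        dy = self.conv2.backward(dy)
        np.multiply(dy, self._m1, out=dy)
        return self.conv1.backward(dy, need_input_grad=need_input_grad)

    @property
    def convs(self):
        return [self.conv1, self.conv2]

    @property
    def params(self):
        return self.conv1.params + self.conv2.params


class UNetModel:
    """Forward network plus everything the inversion pass needs.

    Blocks, in forward order: ``enc[0] .. enc[depth-1]``, ``bottleneck``,
    ``dec[depth-1] .. dec[0]`` (each decoder block is preceded by its
    learned upsampling ``up[i]`` and a skip concatenation), then a 1x1
    convolution to two channels and a softmax over channels.
    """

    def __init__(self, cfg: UNetConfig, dtype=np.float32):
        self.cfg = cfg
        self.dtype = dtype
        rng = np.random.default_rng(cfg.seed)
        d, b, k = cfg.depth, cfg.base_channels, cfg.kernel_size
        chans = [b * 2 ** i for i in range(d + 1)]
        self.enc = []
        in_ch = 1
        for i in range(d):
            self.enc.append(_ConvBlock(in_ch, chans[i], k, rng, dtype))
            in_ch = chans[i]
        self.bottleneck = _ConvBlock(chans[d - 1], chans[d], k, rng, dtype)
        self.up = [None] * d
        self.dec = [None] * d
        for i in reversed(range(d)):
            self.up[i] = UpConv2x2(chans[i + 1], chans[i], rng, dtype)
            self.dec[i] = _ConvBlock(2 * chans[i], chans[i], k, rng, dtype)
        self.out_conv = Conv2d(chans[0], 2, 1, rng, dtype)
        self._skip_shapes = None

    # ------------------------------------------------------------------
    @property
    def params(self):
        p = []
        for blk in self.enc:
            p += blk.params
        p += self.bottleneck.params
        for i in range(self.cfg.depth):
            p += self.up[i].params + self.dec[i].params
        p += self.out_conv.params
        return p

    def parameter_checksum(self) -> float:
        return float(sum(np.abs(v).sum() for v, _ in self.params))

    def state_dict(self) -> dict:
        out = {}
        for i, blk in enumerate(self.enc):
            out[f"enc{i}.w1"], out[f"enc{i}.b1"] = blk.conv1.weight, blk.conv1.bias
            out[f"enc{i}.w2"], out[f"enc{i}.b2"] = blk.conv2.weight, blk.conv2.bias
        out["bott.w1"], out["bott.b1"] = self.bottleneck.conv1.weight, self.bottleneck.conv1.bias
        out["bott.w2"], out["bott.b2"] = self.bottleneck.conv2.weight, self.bottleneck.conv2.bias
        for i in range(self.cfg.depth):
            out[f"up{i}.w"], out[f"up{i}.b"] = self.up[i].weight, self.up[i].bias
            out[f"dec{i}.w1"], out[f"dec{i}.b1"] = self.dec[i].conv1.weight, self.dec[i].conv1.bias
            out[f"dec{i}.w2"], out[f"dec{i}.b2"] = self.dec[i].conv2.weight, self.dec[i].conv2.bias
        out["out.w"], out["out.b"] = self.out_conv.weight, self.out_conv.bias
        return out

    def load_state_dict(self, state: dict):
        for key, arr in self.state_dict().items():
            arr[...] = state[key]

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray, keep: bool = False, capture: bool = False):
        """Forward pass on an (N, 1, H, W) batch.

        With ``capture=True`` also returns per-block output activations and
        the max-pool switches, in forward order — the bookkeeping the
        deconvnet inversion consumes.
        """
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("expected (N, 1, H, W) input")
        if tuple(x.shape[2:]) != tuple(self.cfg.in_shape):
            raise ValueError(
                f"input spatial shape {x.shape[2:]} != configured "
                f"{tuple(self.cfg.in_shape)}")
        acts, switches = [], []
        skips = []
        h = x.astype(self.dtype, copy=False)
        for blk in self.enc:
            h = blk.forward(h, keep=keep)
            skips.append(h)
            h, sw = maxpool2x2(h)
            switches.append(sw)
        if capture:
            acts = [("enc", i, s) for i, s in enumerate(skips)]
        if keep:
            self._switch_cache = switches
        h = self.bottleneck.forward(h, keep=keep)
        if capture:
            acts.append(("bottleneck", None, h))
        self._skips = skips if keep else None
        for i in reversed(range(self.cfg.depth)):
            u = self.up[i].forward(h, keep=keep)
            h = np.concatenate([u, skips[i]], axis=1)
            h = self.dec[i].forward(h, keep=keep)
            if capture:
                acts.append(("dec", i, h))
        logits = self.out_conv.forward(h, keep=keep)
        if capture:
            return logits, acts, switches
        return logits

    def backward(self, dlogits: np.ndarray):
        d = self.cfg.depth
        dh = self.out_conv.backward(dlogits)
        dskip = [None] * d
        for i in range(d):
            dh = self.dec[i].backward(dh)
            c = dh.shape[1] // 2
            du, dskip[i] = dh[:, :c], dh[:, c:]
            dh = self.up[i].backward(du)
        dh = self.bottleneck.backward(dh)
        for i in reversed(range(d)):
            # route the pooling gradient back to the argmax positions
            dpre = unpool2x2(dh, self._switch_cache[i]) + dskip[i]
            # the raw input needs no gradient, so the first block skips it
            dh = self.enc[i].backward(dpre, need_input_grad=(i > 0))
        return dh

    def forward_backward(self, x, dlogits_fn):
        """One training step helper: forward with caches, compute the
        logits-gradient via ``dlogits_fn(logits)``, backprop."""
        logits = self.forward(x, keep=True)
        loss, dlogits = dlogits_fn(logits)
        self.backward(dlogits)
        return loss


def build_unet(cfg: UNetConfig, dtype=np.float32) -> UNetModel:
    """Construct the network with weights deterministically seeded from
    ``cfg.seed``."""
    return UNetModel(cfg, dtype=dtype)


# ----------------------------------------------------------------------
# probabilities and loss
# ----------------------------------------------------------------------

def softmax2(logits: np.ndarray) -> np.ndarray:
    """Two-channel softmax along axis 1, numerically stabilized."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def positive_probability(logits: np.ndarray) -> np.ndarray:
    """Positive-class probability map(s) from the (N, 2, H, W) logits.
    Channel 0 is the positive class."""
    return softmax2(logits)[:, 0]


def _loss_terms(p: np.ndarray, t: np.ndarray):
    """Per-sample soft Dice and BCE terms for batched (N, H, W) inputs."""
    n = p.shape[0]
    pf = p.reshape(n, -1)
    tf = t.reshape(n, -1)
    inter = (pf * tf).sum(axis=1)
    sizes = pf.sum(axis=1) + tf.sum(axis=1)
    dice = 1.0 - (2.0 * inter + 1.0) / (sizes + 1.0)
    pc = np.clip(pf, _CLAMP, 1.0 - _CLAMP)
    bce = -(tf * np.log(pc) + (1.0 - tf) * np.log(1.0 - pc)).mean(axis=1)
    return dice, bce


def dice_bce_loss(pred: np.ndarray, truth: np.ndarray) -> LossValue:
    """Compound loss of a probability map against a binary mask.

    The Dice term uses soft cardinalities (sums of probabilities) and a +1
    smoothing constant in numerator and denominator; the BCE term is the
    mean binary cross entropy of the positive-class probability, with
    probabilities clamped to [1e-7, 1 - 1e-7].
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    dice, bce = _loss_terms(pred[None], truth[None])
    return LossValue(total=float(dice[0] + bce[0]),
                     dice_term=float(dice[0]), bce_term=float(bce[0]))


def _loss_and_logit_grad(logits: np.ndarray, truth: np.ndarray):
    """Training loss of one mini-batch and its exact logits gradient.

    The Dice term is computed over the batch as one set (soft intersection
    and cardinalities summed across the batch). On sparse ground truth this
    is essential: per-image smoothed Dice scores an all-background
    prediction as perfect on every empty mask, which makes the empty
    (collapsed) network a strong attractor; pooling the batch removes that
    degenerate optimum while leaving the per-pair loss definition (and its
    value on a single image) unchanged.
    """
    p = positive_probability(logits)           # (N, H, W)
    t = truth.astype(p.dtype, copy=False)
    pf = p.reshape(-1)
    tf = t.reshape(-1)
    inter = (pf * tf).sum()
    sizes = pf.sum() + tf.sum()
    dice = 1.0 - (2.0 * inter + 1.0) / (sizes + 1.0)
    pc = np.clip(pf, _CLAMP, 1.0 - _CLAMP)
    bce = -(tf * np.log(pc) + (1.0 - tf) * np.log(1.0 - pc)).mean()

    ddice = -(2.0 * tf * (sizes + 1.0) - (2.0 * inter + 1.0)) / (sizes + 1.0) ** 2
    # Dice chains through the 2-class softmax (dp/dz_pos = p(1-p)); for the
    # cross entropy the analytic softmax form (p - t)/N is used: in the
    # unclamped region it equals the chained expression exactly, and unlike
    # it the gradient does not vanish when the softmax saturates, so pixels
    # mis-classified with (float32) certainty still receive a restoring
    # force instead of dying
    dz_pos = (ddice * pf * (1.0 - pf) + (pf - tf) / pf.size).reshape(p.shape)
    dlogits = np.stack([dz_pos, -dz_pos], axis=1).astype(logits.dtype)
    return float(dice + bce), dlogits, float(dice), float(bce)


# ----------------------------------------------------------------------
# training / inference
# ----------------------------------------------------------------------

def normalize_bscan(bscan: np.ndarray) -> np.ndarray:
    """Min-max normalize one B-scan to [0, 1] (constant scans map to 0)."""
    b = np.asarray(bscan, dtype=np.float32)
    lo, hi = float(b.min()), float(b.max())
    if hi - lo <= 0:
        return np.zeros_like(b)
    return (b - lo) / (hi - lo)


def train(model: UNetModel, samples, cfg: UNetConfig, progress: bool = False):
    """Train on a list of ``(bscan, truth_mask)`` pairs.

    Mini-batch Adam at ``cfg.learning_rate`` for ``cfg.epochs`` full passes;
    shuffling and weight init both derive from ``cfg.seed``. Returns the
    per-epoch history as a list of dicts with keys
    ``epoch, mean_loss, dice_term, bce_term``.
    """
    if len(samples) == 0:
        raise ValueError("empty training set")
    x = np.stack([normalize_bscan(b) for b, _ in samples])[:, None]
    y = np.stack([np.asarray(t, dtype=np.float32) for _, t in samples])
    if x.shape[2:] != y.shape[1:]:
        raise ValueError("B-scan and mask shapes differ")
    x = x.astype(model.dtype)
    y = y.astype(model.dtype)
    if cfg.prior_bias_init:
        # start the final softmax at the empirical positive-class prior:
        # with ~1-2% positive pixels, a symmetric start (p = 0.5) gives the
        # background BCE a violent first pull that can drive the network
        # into the saturated all-background optimum before features form
        q = float(np.clip(y.mean(), 1e-4, 0.5))
        model.out_conv.bias[:] = np.array([np.log(q), np.log1p(-q)],
                                          dtype=model.out_conv.bias.dtype)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xD1CE]))
    opt = Adam(model.params, lr=cfg.learning_rate)
    history = []
    n = len(samples)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        tot = dic = bce = 0.0
        nb = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            opt.zero_grad()
            stats = {}

            def fn(logits):
                loss, dlog, d, h = _loss_and_logit_grad(logits, yb)
                stats["d"], stats["h"], stats["l"] = d, h, loss
                return loss, dlog

            model.forward_backward(xb, fn)
            opt.step()
            tot += stats["l"]
            dic += stats["d"]
            bce += stats["h"]
            nb += 1
        history.append({"epoch": epoch, "mean_loss": tot / nb,
                        "dice_term": dic / nb, "bce_term": bce / nb})
        if progress:
            print(f"epoch {epoch}: loss {tot / nb:.4f}")
    return history


def predict(model: UNetModel, bscan: np.ndarray) -> np.ndarray:
    """Positive-class probability map for one B-scan (deterministic)."""
    b = normalize_bscan(bscan)
    if b.shape != tuple(model.cfg.in_shape):
        raise ValueError(
            f"B-scan shape {b.shape} != configured {tuple(model.cfg.in_shape)}")
    logits = model.forward(b[None, None].astype(model.dtype))
    return positive_probability(logits)[0].astype(np.float64)


def predict_batch(model: UNetModel, bscans) -> list:
    """Probability maps for a sequence of B-scans, batched for speed."""
    x = np.stack([normalize_bscan(b) for b in bscans])[:, None].astype(model.dtype)
    out = []
    for start in range(0, len(x), 16):
        logits = model.forward(x[start:start + 16])
        out.extend(positive_probability(logits).astype(np.float64))
    return out


def binarize(p: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Positive classification for probabilities strictly above the
    threshold; a pixel exactly at the threshold is negative."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return np.asarray(p) > threshold


# ----------------------------------------------------------------------
# checkpoints: npz weights + JSON config sidecar
# ----------------------------------------------------------------------

def save_model(model: UNetModel, path):
    path = Path(path)
    np.savez(path, **model.state_dict())
    side = path.with_suffix(".json")
    side.write_text(json.dumps(asdict(model.cfg), indent=2))


def load_model(path) -> UNetModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing checkpoint: {path}")
    side = path.with_suffix(".json")
    if not side.exists():
        raise FileNotFoundError(f"missing checkpoint config sidecar: {side}")
    cfg_d = json.loads(side.read_text())
    cfg_d["in_shape"] = tuple(cfg_d["in_shape"])
    cfg = UNetConfig(**cfg_d)
    model = build_unet(cfg)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
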