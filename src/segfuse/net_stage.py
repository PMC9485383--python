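"""Compact encoder-decoder segmentation network (numpy, manual backprop).

The architecture keeps the mechanism that matters for this pipeline: a
symmetric encoder/decoder where each 2x2 max-pool records its argmax
indices and the mirrored decoder stage upsamples by placing values back
at exactly those indices (no learned upsampling, no skip concatenation).
The head is a 1x1 convolution followed by per-pixel softmax, so the
per-class score maps lie on the probability simplex.

Everything is plain numpy so training is deterministic for a fixed seed
and runs at desk scale (depth 2, base width 8, 192x192 inputs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ConfigError, InferenceError, TrainingError


@dataclass
class NetConfig:
    in_channels: int
    n_classes: int
    depth: int = 2
    base_width: int = 8
    epochs: int = 40
    batch_size: int = 8
    learning_rate: float = 1e-2
    seed: int = 0
    class_weights: str = "none"  # "none" | "inverse"

    def __post_init__(self):
        if self.n_classes not in (2, 4):
            raise ConfigError("n_classes must be 2 or 4")
        if self.depth < 2:
            raise ConfigError("depth must be >= 2")
        if self.class_weights not in ("none", "inverse"):
            raise ConfigError("class_weights must be 'none' or 'inverse'")


def max_pool_with_indices(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2 max pool of (B, C, H, W); returns pooled values and argmax indices.

    Indices are 0..3 into each 2x2 block in row-major order
    (top-left, top-right, bottom-left, bottom-right).
    """
    b, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ConfigError(f"spatial size {h}x{w} not divisible by 2")
    blocks = (
        x.reshape(b, c, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(b, c, h // 2, w // 2, 4)
    )
    idx = blocks.argmax(axis=-1)
    pooled = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
    return pooled, idx


def max_unpool(y: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Inverse of :func:`max_pool_with_indices`: values back at recorded
    argmax positions, zeros elsewhere."""
    b, c, hh, ww = y.shape
    blocks = np.zeros((b, c, hh, ww, 4), dtype=y.dtype)
    np.put_along_axis(blocks, idx[..., None], y[..., None], axis=-1)
    return (
        blocks.reshape(b, c, hh, ww, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(b, c, hh * 2, ww * 2)
    )


class _Conv3x3:
    """Same-padded 3x3 convolution, computed as 9 shifted 1x1 GEMMs."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * 9))
        self.weight = rng.normal(0.0, scale, (cout, cin, 3, 3)).astype(np.float32)
        self.bias = np.zeros(cout, dtype=np.float32)
        self._cols = None
        self._shape = None

    def forward(self, x: np.ndarray, keep: bool) -> np.ndarray:
        b, c, h, w = x.shape
        cout = self.weight.shape[0]
        xp = np.zeros((b, c, h + 2, w + 2), dtype=self.weight.dtype)
        xp[:, :, 1:-1, 1:-1] = x
        # channel-major im2col: (B, C*9, H*W) built from 9 contiguous copies
        cols6 = np.empty((b, c, 3, 3, h, w), dtype=self.weight.dtype)
        for i in range(3):
            for j in range(3):
                cols6[:, :, i, j] = xp[:, :, i : i + h, j : j + w]
        cols = cols6.reshape(b, c * 9, h * w)
        w2 = self.weight.reshape(cout, c * 9)
        out = np.matmul(w2, cols).reshape(b, cout, h, w)
        out += self.bias[None, :, None, None]
        if keep:
            self._cols, self._shape = cols, (b, c, h, w)
        return out

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        b, c, h, w = self._shape
        cout = self.weight.shape[0]
        gf = np.ascontiguousarray(grad).reshape(b, cout, h * w)
        # batched GEMM with a transposed view: no transpose copy
        d_weight = (
            np.matmul(gf, self._cols.swapaxes(1, 2)).sum(axis=0).reshape(self.weight.shape)
        )
        d_bias = gf.sum(axis=(0, 2))
        w2 = self.weight.reshape(cout, c * 9)
        dcols = np.matmul(w2.T, gf).reshape(b, c, 3, 3, h, w)
        dxp = np.zeros((b, c, h + 2, w + 2), dtype=self.weight.dtype)
        for i in range(3):
            for j in range(3):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, i, j]
        self._cols = None
        return dxp[:, :, 1:-1, 1:-1], d_weight, d_bias

    @property
    def params(self):
        return [self.weight, self.bias]


class _Conv1x1:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.weight = rng.normal(0.0, np.sqrt(2.0 / cin), (cout, cin)).astype(np.float32)
        self.bias = np.zeros(cout, dtype=np.float32)
        self._x = None

    def forward(self, x: np.ndarray, keep: bool) -> np.ndarray:
        if keep:
            self._x = x
        return np.einsum("oc,bchw->bohw", self.weight, x) + self.bias[None, :, None, None]

    def backward(self, grad: np.ndarray):
        d_weight = np.einsum("bohw,bchw->oc", grad, self._x)
        d_bias = grad.sum(axis=(0, 2, 3))
        dx = np.einsum("oc,bohw->bchw", self.weight, grad)
        self._x = None
        return dx, d_weight, d_bias

    @property
    def params(self):
        return [self.weight, self.bias]


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SegmentationNet:
    """Encoder-decoder with pooling-index unpooling. See module docstring."""

    def __init__(self, config: NetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        widths = [config.base_width * (2**s) for s in range(config.depth)]
        self.enc = []
        cin = config.in_channels
        for w_ in widths:
            self.enc.append(_Conv3x3(cin, w_, rng))
            cin = w_
        self.dec = []
        for s in reversed(range(config.depth)):
            cout = widths[s - 1] if s > 0 else config.base_width
            self.dec.append(_Conv3x3(widths[s], cout, rng))
            widths[s] = cout  # decoder stage s outputs cout channels
        self.head = _Conv1x1(config.base_width, config.n_classes, rng)
        self._relu_masks = []
        self._pool_idx = []

    # -- forward / backward -------------------------------------------------

    def _layers(self):
        return [*self.enc, *self.dec, self.head]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for layer in self._layers() for p in layer.params)

    def forward(self, x: np.ndarray, keep: bool = False) -> np.ndarray:
        """Logits of shape (B, n_classes, H, W)."""
        if x.shape[1] != self.config.in_channels:
            raise InferenceError(
                f"expected {self.config.in_channels} input channels, got {x.shape[1]}"
            )
        h, w = x.shape[2:]
        if h % (2**self.config.depth) or w % (2**self.config.depth):
            raise ConfigError(
                f"input size {h}x{w} not divisible by 2^{self.config.depth}"
            )
        self._relu_masks = []
        self._pool_idx = []
        out = x
        for conv in self.enc:
            out = conv.forward(out, keep)
            mask = out > 0
            out = out * mask
            if keep:
                self._relu_masks.append(mask)
            out, idx = max_pool_with_indices(out)
            self._pool_idx.append(idx)
        for i, conv in enumerate(self.dec):
            out = max_unpool(out, self._pool_idx[-(i + 1)])
            out = conv.forward(out, keep)
            mask = out > 0
            out = out * mask
            if keep:
                self._relu_masks.append(mask)
        return self.head.forward(out, keep)

    def backward(self, d_logits: np.ndarray) -> list[np.ndarray]:
        """Gradients for all parameters, in :meth:`_layers` order."""
        grads = {}
        g, dw, db = self.head.backward(d_logits)
        grads[id(self.head)] = (dw, db)
        n_dec = len(self.dec)
        masks = self._relu_masks
        for i, conv in enumerate(reversed(self.dec)):
            g = g * masks[len(self.enc) + n_dec - 1 - i]
            g, dw, db = conv.backward(g)
            grads[id(conv)] = (dw, db)
            # gradient of unpool = pooled gather at the recorded indices
            g, _ = _gather_at_indices(g, self._pool_idx[i])
        for i, conv in enumerate(reversed(self.enc)):
            g = max_unpool(g, self._pool_idx[len(self.enc) - 1 - i])
            g = g * masks[len(self.enc) - 1 - i]
            g, dw, db = conv.backward(g)
            grads[id(conv)] = (dw, db)
        flat = []
        for layer in self._layers():
            flat.extend(grads[id(layer)])
        return flat

    # -- inference ----------------------------------------------------------

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _softmax(self.forward(x, keep=False))

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {
            "config_json": np.frombuffer(
                json.dumps(self.config.__dict__).encode(), dtype=np.uint8
            )
        }
        for li, layer in enumerate(self._layers()):
            arrays[f"w{li}"] = layer.weight
            arrays[f"b{li}"] = layer.bias
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "SegmentationNet":
        with np.load(Path(path)) as data:
            cfg = NetConfig(**json.loads(bytes(data["config_json"]).decode()))
            model = cls(cfg)
            for li, layer in enumerate(model._layers()):
                layer.weight = data[f"w{li}"]
                layer.bias = data[f"b{li}"]
        return model


def _gather_at_indices(g: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Backward of unpool: pick gradient at the recorded argmax positions."""
    b, c, h, w = g.shape
    blocks = (
        g.reshape(b, c, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(b, c, h // 2, w // 2, 4)
    )
    out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
    return out, idx


def build_network(config: NetConfig) -> SegmentationNet:
    """Construct a seeded network; two builds with one seed are identical."""
    return SegmentationNet(config)


def _loss_and_grad(model, x, y, weights):
    logits = model.forward(x, keep=True)
    probs = _softmax(logits)
    b, c, h, w = probs.shape
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, y[:, None], 1.0, axis=1)
    pix_w = weights[y] if weights is not None else np.ones(y.shape)
    wsum = pix_w.sum()
    logp = np.log(np.clip(np.take_along_axis(probs, y[:, None], axis=1)[:, 0], 1e-12, None))
    loss = float(-(pix_w * logp).sum() / wsum)
    d_logits = (probs - onehot) * pix_w[:, None] / wsum
    grads = model.backward(d_logits)
    return loss, grads


def train_segmentation(
    model: SegmentationNet,
    images: np.ndarray,
    labels: np.ndarray,
    epochs: int | None = None,
    batch_size: int | None = None,
    learning_rate: float | None = None,
    seed: int | None = None,
) -> list[float]:
    """Train with per-pixel cross-entropy and Adam; returns the loss trace.

    ``images`` is (N, C, H, W), ``labels`` is (N, H, W) with values in
    ``0..n_classes-1``. Deterministic for fixed seed and thread count.
    """
    cfg = model.config
    epochs = cfg.epochs if epochs is None else epochs
    batch_size = cfg.batch_size if batch_size is None else batch_size
    lr = cfg.learning_rate if learning_rate is None else learning_rate
    seed = cfg.seed if seed is None else seed

    images = np.asarray(images, dtype=model.enc[0].weight.dtype)
    labels = np.asarray(labels)
    if images.ndim != 4 or labels.shape != (images.shape[0], *images.shape[2:]):
        raise TrainingError("images must be (N,C,H,W) with labels (N,H,W)")
    if labels.size == 0:
        raise TrainingError("empty training set")
    if labels.min() < 0 or labels.max() >= cfg.n_classes:
        raise TrainingError(
            f"labels outside 0..{cfg.n_classes - 1}: model/label space mismatch"
        )

    weights = None
    if cfg.class_weights == "inverse":
        freq = np.bincount(labels.ravel(), minlength=cfg.n_classes).astype(np.float64)
        freq = np.maximum(freq, 1.0)
        weights = freq.sum() / (cfg.n_classes * freq)

    params = [p for layer in model._layers() for p in layer.params]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    rng = np.random.default_rng(seed)
    n = images.shape[0]
    trace = []
    for _epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            sel = order[start : start + batch_size]
            loss, grads = _loss_and_grad(model, images[sel], labels[sel], weights)
            epoch_loss += loss * len(sel)
            step += 1
            for k, (p, g) in enumerate(zip(params, grads)):
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1**step)
                vhat = v[k] / (1 - beta2**step)
                p -= lr * mhat / (np.sqrt(vhat) + eps)
        trace.append(epoch_loss / n)
    return trace


def extract_score_maps(model: SegmentationNet, image: np.ndarray) -> np.ndarray:
    """Per-class probability maps (C, H, W) for a single (C_in, H, W) image.

    Values lie in [0, 1] and sum to 1 per pixel; no thresholding.
    """
    image = np.asarray(image, dtype=model.enc[0].weight.dtype)
    if image.ndim != 3:
        raise InferenceError("expected a single (C, H, W) image")
    return model.predict_proba(image[None])[0]


def predict_argmax(score_maps: np.ndarray) -> np.ndarray:
    """Per-pixel class of maximal score; ties go to the lowest class index."""
    return np.asarray(score_maps).argmax(axis=0)
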