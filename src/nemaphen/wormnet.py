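"""WormNet: a small convolutional classifier separating valid worm masks
from noise (loops, merged worms, debris, fragments).

The network is implemented directly in NumPy: stacked
convolution-batchnorm-ReLU-maxpool blocks followed by a fully connected
two-way softmax head, trained with stochastic gradient descent with
momentum.  Default training recipe: momentum 0.9, L2 regularization 1e-4,
mini-batch 256, learning rate 0.005, data reshuffled every epoch, and an
85/15 stratified train/test split.  All hyperparameters are overridable.

Masks of arbitrary size are first centred on a zero canvas sized at the
65th percentile of the batch's mask sizes (per axis), then rescaled to the
fixed 64 x 128 network input and re-binarized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
from skimage.transform import resize

INPUT_SHAPE = (64, 128)
PAD_PERCENTILE = 65

_SERIAL_VERSION = 1


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def batch_pad_size(masks: list[np.ndarray], percentile: float = PAD_PERCENTILE) -> tuple[int, int]:
    """Per-axis percentile of mask canvas sizes; a singleton batch keeps its own size."""
    if not masks:
        raise ValueError("empty mask batch")
    if len(masks) == 1:
        return masks[0].shape
    heights = [m.shape[0] for m in masks]
    widths = [m.shape[1] for m in masks]
    return (
        int(round(np.percentile(heights, percentile))),
        int(round(np.percentile(widths, percentile))),
    )


def preprocess_mask_for_net(
    mask: np.ndarray, pad_size: tuple[int, int], input_shape: tuple[int, int] = INPUT_SHAPE
) -> np.ndarray:
    """Centre a binary mask on the batch pad canvas and rescale to the net input.

    Masks larger than the canvas are cropped centrally; the rescaled image
    is re-binarized at 0.5 so the input stays strictly {0, 1}.
    """
    mask = np.asarray(mask).astype(np.float32)
    ph, pw = pad_size
    h, w = mask.shape
    # central crop of anything exceeding the canvas
    if h > ph:
        off = (h - ph) // 2
        mask = mask[off : off + ph]
        h = ph
    if w > pw:
        off = (w - pw) // 2
        mask = mask[:, off : off + pw]
        w = pw
    canvas = np.zeros((ph, pw), dtype=np.float32)
    r0, c0 = (ph - h) // 2, (pw - w) // 2
    canvas[r0 : r0 + h, c0 : c0 + w] = mask
    out = resize(canvas, input_shape, order=1, anti_aliasing=True, preserve_range=True)
    return (out >= 0.5).astype(np.float32)


# ---------------------------------------------------------------------------
# Layers (NumPy forward/backward)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patch matrix for a same-padded 3x3 conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # (N, C, H, W, 3, 3) -> (N, H, W, C, 3, 3)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * 9), (n, c, h, w)


class _Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.w = (rng.standard_normal((c_in * 9, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.vw = np.zeros_like(self.w)
        self.vb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.col, (n, c, h, w) = _im2col(x)
        self.in_shape = (n, c, h, w)
        out = self.col @ self.w + self.b
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self.in_shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, -1)
        self.dw = self.col.T @ dflat
        self.db = dflat.sum(axis=0)
        dcol = (dflat @ self.w.T).reshape(n, h, w, c, 3, 3)
        dxp = np.zeros((n, c, h + 2, w + 2), dtype=np.float32)
        for i in range(3):
            for j in range(3):
                dxp[:, :, i : i + h, j : j + w] += dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, 1:-1, 1:-1]

    def params(self):
        return [("w", True), ("b", False)]


class _BatchNorm:
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.w = np.ones(channels, dtype=np.float32)  # gamma
        self.b = np.zeros(channels, dtype=np.float32)  # beta
        self.vw = np.zeros_like(self.w)
        self.vb = np.zeros_like(self.b)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self.inv_std = 1.0 / np.sqrt(var + self.eps)
        self.xhat = (x - mean[None, :, None, None]) * self.inv_std[None, :, None, None]
        return self.w[None, :, None, None] * self.xhat + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n_eff = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dw = (dout * self.xhat).sum(axis=(0, 2, 3))
        self.db = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.w[None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3))[None, :, None, None]
            - self.xhat * (dxhat * self.xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        ) * self.inv_std[None, :, None, None]
        return dx

    def params(self):
        return [("w", False), ("b", False)]


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self.mask = x > 0
        return x * self.mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self.mask


class _MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self.x_shape = x.shape
        self.argmask = xr == out[:, :, :, None, :, None]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self.x_shape
        d = self.argmask * dout[:, :, :, None, :, None]
        return d.reshape(n, c, h, w)


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.w = (rng.standard_normal((d_in, d_out)) * scale).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.vw = np.zeros_like(self.w)
        self.vb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw = self.x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.w.T


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class NetSpec:
    """Architecture plus training recipe (all overridable by the user)."""

    input_shape: tuple[int, int] = INPUT_SHAPE
    conv_channels: tuple[int, ...] = (16, 32, 64)
    global_pool: bool = False    # average-pool features before the binary head
    augment_flips: bool = True   # add flipped copies of the training masks
    momentum: float = 0.9
    l2: float = 1e-4
    batch_size: int = 256
    learning_rate: float = 0.005
    epochs: int = 50
    test_fraction: float = 0.15


class WormNet:
    """Binary mask classifier: class 0 = valid worm, class 1 = noise/faulty."""

    def __init__(self, spec: NetSpec, seed: int = 0):
        self.spec = spec
        self.pad_size: tuple[int, int] | None = None
        rng = np.random.default_rng(seed)
        self.convs: list[_Conv3x3] = []
        self.bns: list[_BatchNorm] = []
        c_in = 1
        for c_out in spec.conv_channels:
            self.convs.append(_Conv3x3(c_in, c_out, rng))
            self.bns.append(_BatchNorm(c_out))
            c_in = c_out
        h, w = spec.input_shape
        reduce = 2 ** len(spec.conv_channels)
        if spec.global_pool:
            self.head = _Dense(c_in, 2, rng)
        else:
            self.head = _Dense((h // reduce) * (w // reduce) * c_in, 2, rng)
        self.relus = [_ReLU() for _ in spec.conv_channels]
        self.pools = [_MaxPool2() for _ in spec.conv_channels]

    # -- forward/backward ---------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = x[:, None, :, :].astype(np.float32)
        for conv, bn, relu, pool in zip(self.convs, self.bns, self.relus, self.pools):
            out = pool.forward(relu.forward(bn.forward(conv.forward(out), train)))
        n = out.shape[0]
        self._feat_shape = out.shape
        if self.spec.global_pool:
            return self.head.forward(out.mean(axis=(2, 3)))
        return self.head.forward(out.reshape(n, -1))

    def _backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        n, c, h, w = self._feat_shape
        if self.spec.global_pool:
            d = np.broadcast_to(d[:, :, None, None] / (h * w), self._feat_shape).astype(np.float32)
        else:
            d = d.reshape(self._feat_shape)
        for conv, bn, relu, pool in zip(
            reversed(self.convs), reversed(self.bns), reversed(self.relus), reversed(self.pools)
        ):
            d = conv.backward(bn.backward(relu.backward(pool.backward(d))))

    def _layers_with_params(self):
        return [*self.convs, *self.bns, self.head]

    def _sgd_step(self, lr: float, momentum: float, l2: float) -> None:
        for layer in self._layers_with_params():
            decay = l2 if isinstance(layer, (_Conv3x3, _Dense)) else 0.0
            layer.vw = momentum * layer.vw - lr * (layer.dw + decay * layer.w)
            layer.w = layer.w + layer.vw
            layer.vb = momentum * layer.vb - lr * layer.db
            layer.b = layer.b + layer.vb

    # -- public API ---------------------------------------------------------

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Per-sample softmax probabilities, column 1 = noise probability."""
        probs = []
        for i in range(0, len(x), batch_size):
            logits = self._forward(x[i : i + batch_size], train=False)
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            probs.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(probs) if probs else np.empty((0, 2))

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        *,
        seed: int = 0,
        epochs: int | None = None,
        verbose: bool = False,
    ) -> None:
        """SGD-with-momentum training; data reshuffled every epoch."""
        spec = self.spec
        epochs = spec.epochs if epochs is None else epochs
        rng = np.random.default_rng(seed)
        n = len(x)
        for _epoch in range(epochs):
            order = rng.permutation(n)
            for i in range(0, n, spec.batch_size):
                idx = order[i : i + spec.batch_size]
                logits = self._forward(x[idx], train=True)
                logits = logits - logits.max(axis=1, keepdims=True)
                e = np.exp(logits)
                p = e / e.sum(axis=1, keepdims=True)
                dlogits = p.copy()
                dlogits[np.arange(len(idx)), y[idx]] -= 1.0
                dlogits /= len(idx)
                self._backward(dlogits.astype(np.float32))
                self._sgd_step(spec.learning_rate, spec.momentum, spec.l2)

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        arrays = {}
        for k, layer in enumerate(self._layers_with_params()):
            arrays[f"w{k}"] = layer.w
            arrays[f"b{k}"] = layer.b
            if isinstance(layer, _BatchNorm):
                arrays[f"rm{k}"] = layer.running_mean
                arrays[f"rv{k}"] = layer.running_var
        meta = dict(asdict(self.spec))
        meta["pad_size"] = list(self.pad_size) if self.pad_size else None
        meta["version"] = _SERIAL_VERSION
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "WormNet":
        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode())
        if meta.pop("version") != _SERIAL_VERSION:
            raise ValueError("model file version mismatch")
        pad_size = meta.pop("pad_size")
        meta["input_shape"] = tuple(meta["input_shape"])
        meta["conv_channels"] = tuple(meta["conv_channels"])
        model = cls(NetSpec(**meta))
        model.pad_size = tuple(pad_size) if pad_size else None
        for k, layer in enumerate(model._layers_with_params()):
            layer.w = data[f"w{k}"]
            layer.b = data[f"b{k}"]
            if isinstance(layer, _BatchNorm):
                layer.running_mean = data[f"rm{k}"]
                layer.running_var = data[f"rv{k}"]
        return model


# ---------------------------------------------------------------------------
# Training entry points
# ---------------------------------------------------------------------------

def train_wormnet(
    masks: list[np.ndarray],
    labels: np.ndarray,
    spec: NetSpec | None = None,
    *,
    seed: int = 0,
    epochs: int | None = None,
) -> tuple[WormNet, float, float]:
    """Train the mask classifier on a labelled corpus.

    Labels: 0 = valid worm, 1 = noise/faulty.  The corpus is split
    85/15 (stratified, seeded); the pad canvas is the 65th percentile of
    the *training* masks' sizes and is stored with the model so later
    classification preprocesses identically.

    Returns ``(model, train_accuracy, test_accuracy)``.

    Raises
    ------
    ValueError
        On single-class input or class imbalance beyond 70/30.
    """
    spec = spec or NetSpec()
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training requires both valid and faulty examples")
    if counts.min() / counts.sum() < 0.30:
        raise ValueError(
            f"class balance {counts.tolist()} exceeds 70/30; rebalance the corpus"
        )

    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for cls_label in classes:
        idx = np.flatnonzero(labels == cls_label)
        n_test = max(1, int(round(spec.test_fraction * len(idx))))
        test_idx.extend(rng.choice(idx, size=n_test, replace=False))
    test_mask = np.zeros(len(labels), dtype=bool)
    test_mask[test_idx] = True

    train_masks = [m for m, t in zip(masks, test_mask) if not t]
    pad = batch_pad_size(train_masks)
    x = np.stack([preprocess_mask_for_net(m, pad, spec.input_shape) for m in masks])
    y = labels

    model = WormNet(spec, seed=seed)
    model.pad_size = pad
    x_train, y_train = x[~test_mask], y[~test_mask]
    if spec.augment_flips:
        # Mirrored masks are equally valid/faulty; augmentation only ever
        # touches the training split.
        x_train = np.concatenate([x_train, x_train[:, :, ::-1], x_train[:, ::-1, :]])
        y_train = np.concatenate([y_train, y_train, y_train])
    model.fit(x_train, y_train, seed=seed, epochs=epochs)

    train_acc = float(
        (model.predict_proba(x[~test_mask]).argmax(axis=1) == y[~test_mask]).mean()
    )
    test_acc = float((model.predict_proba(x[test_mask]).argmax(axis=1) == y[test_mask]).mean())
    return model, train_acc, test_acc


def classify_masks(
    model: WormNet, masks: list[np.ndarray], *, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Noise probability and ``net_noise`` flag for each mask.

    Flagged masks stay in the feature table, marked for review; exclusion
    happens only at export time.
    """
    if not masks:
        return np.empty(0), np.empty(0, dtype=bool)
    if model.pad_size is None:
        raise ValueError("model has no stored preprocessing parameters")
    x = np.stack(
        [preprocess_mask_for_net(m, model.pad_size, model.spec.input_shape) for m in masks]
    )
    scores = model.predict_proba(x)[:, 1]
    return scores, scores > threshold
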