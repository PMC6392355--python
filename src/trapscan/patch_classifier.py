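"""Three-class patch classifier (human / animal / background).

A compact five-conv-layer CNN in the AlexNet-96 mold: 96 x 96 x 3 input,
per-layer filter counts reduced to [16, 32, 64, 64, 32] to keep CPU
inference fast, three softmax scores out.  The network, its im2col
convolution kernels and the Adam trainer are implemented here directly in
NumPy so that training a desk-scale model takes minutes on one CPU and is
bit-reproducible given a seed.

Patches of arbitrary aspect ratio are padded to a square with edge
replication (no anisotropic stretch) before resizing to the 96-px input.
Class imbalance is handled by oversampling with color-content
modification: new samples are never raw duplicates but grayscale, gain- or
channel-shuffled variants, which pushes the network toward shape and
texture cues rather than color.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

CLASSES = ("human", "animal", "background")
INPUT_SIZE = 96

# the unreduced AlexNet per-layer filter counts, for parameter-count comparison
ALEXNET_FILTERS = (96, 256, 384, 384, 256)

CHECKPOINT_MAGIC = "trapscan-cnn"
CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture knobs: five conv stages then two hidden FC layers."""

    filters: tuple[int, ...] = (16, 32, 64, 64, 32)
    input_size: int = INPUT_SIZE
    n_classes: int = len(CLASSES)
    fc_sizes: tuple[int, ...] = (256, 128)

    def __post_init__(self):
        if len(self.filters) != 5 or any(f < 1 for f in self.filters):
            raise ValueError("filters must be 5 positive counts")


@dataclass
class ClassScores:
    """Normalized scores for the three classes; argmax is the prediction."""

    s_human: float
    s_animal: float
    s_background: float

    def as_array(self) -> np.ndarray:
        return np.array([self.s_human, self.s_animal, self.s_background])

    @property
    def predicted_class(self) -> str:
        return CLASSES[int(np.argmax(self.as_array()))]

    @property
    def score(self) -> float:
        return float(self.as_array().max())


# ---------------------------------------------------------------------------
# patch geometry


def rescale_patch(patch: np.ndarray) -> np.ndarray:
    """Pad to square with edge replication, resize to 96 x 96 x 3 uint8."""
    arr = np.asarray(patch)
    if arr.size == 0:
        raise ValueError("empty patch")
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    arr = arr.astype(np.uint8)
    h, w = arr.shape[:2]
    if h != w:
        side = max(h, w)
        ph, pw = side - h, side - w
        arr = np.pad(
            arr,
            ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2), (0, 0)),
            mode="edge",
        )
    if arr.shape[0] != INPUT_SIZE:
        img = Image.fromarray(arr).resize((INPUT_SIZE, INPUT_SIZE), Image.BILINEAR)
        arr = np.asarray(img)
    return arr


# ---------------------------------------------------------------------------
# conv/pool primitives (im2col)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (x.shape[2] - k) // stride + 1
    wo = (x.shape[3] - k) // stride + 1
    col = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            col[:, :, i, j] = x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return col.reshape(n, c * k * k, ho * wo), ho, wo


def _col2im(dcol: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    dxp = np.zeros((n, c, hp, wp), dtype=dcol.dtype)
    dcol = dcol.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dcol[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp


class _Conv:
    def __init__(self, c_in, c_out, k, stride, pad, rng):
        scale = np.sqrt(2.0 / (c_in * k * k))  # He init for ReLU stacks
        self.w = (rng.standard_normal((c_out, c_in * k * k)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x):
        self.x_shape = x.shape
        col, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        self.col = col
        out = np.matmul(self.w[None], col) + self.b[None, :, None]
        return out.reshape(x.shape[0], self.c_out, ho, wo)

    def backward(self, dout):
        n, _, ho, wo = dout.shape
        dflat = dout.reshape(n, self.c_out, ho * wo)
        self.dw = np.einsum("nfp,ncp->fc", dflat, self.col).astype(np.float32)
        self.db = dflat.sum(axis=(0, 2)).astype(np.float32)
        dcol = np.matmul(self.w.T[None], dflat)
        del self.col
        return _col2im(dcol, self.x_shape, self.k, self.stride, self.pad)

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def n_params(self):
        return self.w.size + self.b.size


class _ReLU:
    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, dout):
        return dout * self.mask

    def params(self):
        return []

    def n_params(self):
        return 0


class _MaxPool2:
    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        mask = xr == out[:, :, :, None, :, None]
        # ties split the gradient evenly
        self.mask = mask / mask.sum(axis=(3, 5), keepdims=True)
        self.x_shape = x.shape
        return out

    def backward(self, dout):
        n, c, h, w = self.x_shape
        d = dout[:, :, :, None, :, None] * self.mask
        return d.reshape(n, c, h, w).astype(np.float32)

    def params(self):
        return []

    def n_params(self):
        return 0


class _Flatten:
    def forward(self, x):
        self.x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self.x_shape)

    def params(self):
        return []

    def n_params(self):
        return 0


class _Dense:
    def __init__(self, d_in, d_out, rng):
        scale = np.sqrt(2.0 / d_in)
        self.w = (rng.standard_normal((d_in, d_out)) * scale).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)

    def forward(self, x):
        self.x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw = (self.x.T @ dout).astype(np.float32)
        self.db = dout.sum(axis=0).astype(np.float32)
        dx = dout @ self.w.T
        del self.x
        return dx

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def n_params(self):
        return self.w.size + self.b.size


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SmallCNN:
    """Five conv+ReLU stages (maxpool after 1, 2 and 5), two hidden FC
    layers, softmax over the three classes."""

    def __init__(self, config: ClassifierConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        f1, f2, f3, f4, f5 = config.filters
        s = config.input_size
        self.layers = [
            _Conv(3, f1, k=7, stride=2, pad=3, rng=rng), _ReLU(), _MaxPool2(),   # s/4
            _Conv(f1, f2, k=5, stride=1, pad=2, rng=rng), _ReLU(), _MaxPool2(),  # s/8
            _Conv(f2, f3, k=3, stride=1, pad=1, rng=rng), _ReLU(),
            _Conv(f3, f4, k=3, stride=1, pad=1, rng=rng), _ReLU(),
            _Conv(f4, f5, k=3, stride=1, pad=1, rng=rng), _ReLU(), _MaxPool2(),  # s/16
            _Flatten(),
        ]
        feat = (s // 16) * (s // 16) * f5
        dims = (feat, *config.fc_sizes)
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            self.layers += [_Dense(d_in, d_out, rng), _ReLU()]
        self.layers.append(_Dense(dims[-1], config.n_classes, rng))

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits for a (N, 3, S, S) float32 batch (inputs in [-0.5, 0.5])."""
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _softmax(self.forward(x))

    def backward(self, dlogits: np.ndarray):
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params():
                out[f"layer{i}_{name}"] = arr
        return out

    def load_state(self, arrays: dict[str, np.ndarray]):
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params():
                arr[...] = arrays[f"layer{i}_{name}"]


def build_model(config: ClassifierConfig | None = None, seed: int = 0) -> SmallCNN:
    """Construct the CNN; logs the parameter count."""
    config = config or ClassifierConfig()
    model = SmallCNN(config, seed=seed)
    logger.info("built CNN filters=%s params=%d", config.filters, model.n_params())
    return model


# ---------------------------------------------------------------------------
# data handling


def _to_batch(patches: np.ndarray) -> np.ndarray:
    """uint8 (N, S, S, 3) -> float32 (N, 3, S, S) centered on zero."""
    x = np.asarray(patches, dtype=np.float32) / 255.0 - 0.5
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def _color_modify(patch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One random color-content modification; never an identity copy."""
    mode = rng.integers(3)
    x = patch.astype(np.float32)
    if mode == 0:  # grayscale conversion
        gray = x[..., 0] * 0.299 + x[..., 1] * 0.587 + x[..., 2] * 0.114
        out = np.repeat(gray[:, :, None], 3, axis=2)
    elif mode == 1:  # per-channel gain
        gains = rng.uniform(0.6, 1.4, size=3)
        out = x * gains[None, None, :]
    else:  # channel shuffle (always a non-identity permutation)
        perms = [(1, 2, 0), (2, 0, 1), (0, 2, 1), (2, 1, 0), (1, 0, 2)]
        out = x[:, :, perms[rng.integers(len(perms))]]
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def oversample_balance(
    patches: np.ndarray, labels: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Bring every class up to the majority count with color-modified copies.

    Returns (patches, labels) with equal class counts; appended samples are
    color-content modifications of randomly drawn class members, never raw
    duplicates.  Deterministic given ``seed``.
    """
    patches = np.asarray(patches)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) == 0:
        raise ValueError("no samples")
    target = counts.max()
    rng = np.random.default_rng(seed)
    add_p, add_l = [], []
    for cls, cnt in zip(classes, counts):
        if cnt == 0:
            raise ValueError(f"class {cls} has no samples")
        deficit = target - cnt
        if deficit == 0:
            continue
        idx = np.nonzero(labels == cls)[0]
        src = rng.choice(idx, size=deficit, replace=True)
        for s in src:
            add_p.append(_color_modify(patches[s], rng))
            add_l.append(cls)
    if not add_p:
        return patches, labels
    return (
        np.concatenate([patches, np.stack(add_p)]),
        np.concatenate([labels, np.array(add_l, dtype=labels.dtype)]),
    )


def load_patch_dataset(root: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a class-per-subfolder image tree into (patches, labels)."""
    root = Path(root)
    patches, labels = [], []
    for ci, cls in enumerate(CLASSES):
        cdir = root / cls
        if not cdir.is_dir():
            raise FileNotFoundError(f"missing class folder: {cdir}")
        for p in sorted(cdir.iterdir()):
            if p.suffix.lower() not in {".jpg", ".jpeg", ".png"}:
                continue
            patches.append(rescale_patch(np.asarray(Image.open(p).convert("RGB"))))
            labels.append(ci)
    if not patches:
        raise ValueError(f"no patches under {root}")
    return np.stack(patches), np.array(labels)


# ---------------------------------------------------------------------------
# training


def train(
    patches: np.ndarray,
    labels: np.ndarray,
    config: ClassifierConfig | None = None,
    seed: int = 0,
    epochs: int = 6,
    batch_size: int = 32,
    lr: float = 1e-3,
    val_patches: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
    balance: bool = True,
) -> tuple[SmallCNN, float]:
    """Train the CNN with Adam on softmax cross-entropy.

    ``patches`` are uint8 (N, 96, 96, 3), ``labels`` integer class indices.
    If no validation split is supplied, 15% of the training data is held
    out (stratified by shuffling).  Returns (model, held-out accuracy).
    Deterministic given ``seed``.
    """
    config = config or ClassifierConfig()
    patches = np.asarray(patches)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < config.n_classes:
        raise ValueError("every class must be present in the training set")
    rng = np.random.default_rng(seed)
    if val_patches is None:
        order = rng.permutation(len(labels))
        n_val = max(1, int(0.15 * len(labels)))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        val_patches, val_labels = patches[val_idx], labels[val_idx]
        patches, labels = patches[tr_idx], labels[tr_idx]
    if balance:
        patches, labels = oversample_balance(patches, labels, seed=seed + 1)

    model = SmallCNN(config, seed=seed)
    params = [(layer, name, arr) for layer in model.layers for name, arr in layer.params()]
    m = [np.zeros_like(arr) for _, _, arr in params]
    v = [np.zeros_like(arr) for _, _, arr in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    n = len(labels)
    for epoch in range(epochs):
        order = rng.permutation(n)
        total_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            x = _to_batch(patches[idx])
            y = labels[idx]
            logits = model.forward(x)
            p = _softmax(logits)
            total_loss += -np.log(np.maximum(p[np.arange(len(y)), y], 1e-12)).sum()
            d = (p - np.eye(config.n_classes, dtype=np.float32)[y]) / len(y)
            model.backward(d.astype(np.float32))
            t += 1
            for k, (layer, name, arr) in enumerate(params):
                g = getattr(layer, "d" + name)
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mh = m[k] / (1 - beta1**t)
                vh = v[k] / (1 - beta2**t)
                arr -= lr * mh / (np.sqrt(vh) + eps)
        logger.info("epoch %d/%d mean loss %.4f", epoch + 1, epochs, total_loss / n)
    acc = evaluate_accuracy(model, val_patches, val_labels)
    logger.info("held-out accuracy %.4f (n=%d)", acc, len(val_labels))
    return model, acc


def evaluate_accuracy(
    model: SmallCNN, patches: np.ndarray, labels: np.ndarray, batch_size: int = 64
) -> float:
    correct = 0
    for start in range(0, len(labels), batch_size):
        x = _to_batch(patches[start : start + batch_size])
        pred = model.predict_proba(x).argmax(axis=1)
        correct += int((pred == labels[start : start + batch_size]).sum())
    return correct / len(labels)


def classify_patch(model: SmallCNN, patch: np.ndarray) -> ClassScores:
    """Normalized three-class scores for one patch (any size; rescaled)."""
    p = rescale_patch(patch)
    probs = model.predict_proba(_to_batch(p[None]))[0]
    return ClassScores(
        s_human=float(probs[0]), s_animal=float(probs[1]), s_background=float(probs[2])
    )


# ---------------------------------------------------------------------------
# checkpoints


def save_model(model: SmallCNN, path: str | Path):
    """Single-file checkpoint: versioned JSON header + weight arrays."""
    meta = {
        "magic": CHECKPOINT_MAGIC,
        "version": CHECKPOINT_VERSION,
        "filters": list(model.config.filters),
        "input_size": model.config.input_size,
        "n_classes": model.config.n_classes,
        "fc_sizes": list(model.config.fc_sizes),
        "classes": list(CLASSES),
    }
    arrays = model.state_arrays()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> SmallCNN:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"no classifier checkpoint at {path}; train one with "
            f"`trapscan train --data <patch dir> --out {path}`"
        )
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("magic") != CHECKPOINT_MAGIC:
            raise ValueError(f"{path} is not a trapscan checkpoint")
        config = ClassifierConfig(
            filters=tuple(meta["filters"]),
            input_size=meta["input_size"],
            n_classes=meta["n_classes"],
            fc_sizes=tuple(meta["fc_sizes"]),
        )
        model = SmallCNN(config, seed=0)
        model.load_state({k: data[k] for k in data.files if k != "__meta__"})
    return model


def alexnet_comparison_params(config: ClassifierConfig | None = None) -> tuple[int, int]:
    """(reduced, unreduced) parameter counts for the same topology."""
    config = config or ClassifierConfig()
    reduced = SmallCNN(config, seed=0).n_params()
    full = SmallCNN(
        ClassifierConfig(
            filters=ALEXNET_FILTERS,
            input_size=config.input_size,
            n_classes=config.n_classes,
            fc_sizes=config.fc_sizes,
        ),
        seed=0,
    ).n_params()
    return reduced, full
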