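"""Fixed convolutional feature extractor for image-driven runs.

The default pipeline uses synthetic embeddings; this module recreates the
image-computable alternative: a small CNN trained on grayscale CIFAR-10
whose last fully-connected hidden layer (64 rectified units) embeds task
images.  Architecture (valid padding): conv 5x5x8 - maxpool 2x2 -
conv 5x5x16 - maxpool 2x2 - FC-128 - FC-64, plus an FC-10 classifier used
only during training; 63,658 parameters up to the embedding layer.  Inputs
are 32x32 grayscale in [0, 1], normalized with mean 0.479 and sd 0.239.
Training uses SGD (lr 0.01, momentum 0.9) for ten epochs.

The CIFAR-10 archive is external and never bundled; callers must supply the
extracted ``cifar-10-batches-py`` directory.  Everything is plain NumPy
(im2col convolutions), adequate for a network this small.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .synthetic_data import EmbeddingMatrix

__all__ = ["EncoderSpec", "ExternalDataError", "init_encoder", "train_encoder",
           "embed_images", "load_cifar10", "gray_response"]

NORM_MEAN = 0.479
NORM_SD = 0.239


class ExternalDataError(FileNotFoundError):
    """Raised when the external CIFAR-10 dataset is required but absent."""


# ---------------------------------------------------------------------------
# minimal conv-net plumbing (im2col)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, out_h*out_w, C*k*k) patch matrix, valid padding."""
    n, c, h, w = x.shape
    oh, ow = h - k + 1, w - k + 1
    s0, s1, s2, s3 = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x, shape=(n, c, oh, ow, k, k), strides=(s0, s1, s2, s3, s2, s3)
    )
    return patches.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * k * k), oh, ow


def _conv_forward(x, Wf, b):
    cols, oh, ow = _im2col(x, Wf.shape[-1])
    out = cols @ Wf.reshape(Wf.shape[0], -1).T + b  # (N, oh*ow, F)
    return out.transpose(0, 2, 1).reshape(x.shape[0], Wf.shape[0], oh, ow), cols


def _conv_backward(dout, cols, x_shape, Wf):
    n, f, oh, ow = dout.shape
    d2 = dout.reshape(n, f, oh * ow).transpose(0, 2, 1)  # (N, L, F)
    gW = np.einsum("nlf,nlp->fp", d2, cols).reshape(Wf.shape)
    gb = d2.sum(axis=(0, 1))
    dcols = d2 @ Wf.reshape(f, -1)  # (N, L, C*k*k)
    # scatter patches back
    _, c, h, w = x_shape
    k = Wf.shape[-1]
    dx = np.zeros(x_shape)
    dcols = dcols.reshape(n, oh, ow, c, k, k)
    for i in range(k):
        for j in range(k):
            dx[:, :, i:i + oh, j:j + ow] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dx, gW, gb


def _pool_forward(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5))
    mask = xr == out[:, :, :, None, :, None]
    return out, mask


def _pool_backward(dout, mask):
    return (mask * dout[:, :, :, None, :, None]).reshape(
        mask.shape[0], mask.shape[1], mask.shape[2] * 2, mask.shape[4] * 2
    )


@dataclass
class EncoderSpec:
    """Weights and metadata of the feature extractor."""

    params: dict[str, np.ndarray]
    trained: bool = False
    test_accuracy: float | None = None
    norm_mean: float = NORM_MEAN
    norm_sd: float = NORM_SD


def init_encoder(seed: int = 0) -> EncoderSpec:
    rng = np.random.default_rng(seed)

    def u(shape, fan_in):
        b = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-b, b, size=shape)

    params = {
        "c1": u((8, 1, 5, 5), 25), "c1b": u((8,), 25),
        "c2": u((16, 8, 5, 5), 200), "c2b": u((16,), 200),
        "f1": u((128, 400), 400), "f1b": u((128,), 400),
        "f2": u((64, 128), 128), "f2b": u((64,), 128),
        "f3": u((10, 64), 64), "f3b": u((10,), 64),
    }
    return EncoderSpec(params=params)


def _forward(params, x, need_cache=False):
    h1, cols1 = _conv_forward(x, params["c1"], params["c1b"])
    r1 = np.maximum(h1, 0)
    p1, m1 = _pool_forward(r1)
    h2, cols2 = _conv_forward(p1, params["c2"], params["c2b"])
    r2 = np.maximum(h2, 0)
    p2, m2 = _pool_forward(r2)
    flat = p2.reshape(x.shape[0], -1)
    z1 = flat @ params["f1"].T + params["f1b"]
    a1 = np.maximum(z1, 0)
    z2 = a1 @ params["f2"].T + params["f2b"]
    emb = np.maximum(z2, 0)  # the 64-unit embedding layer
    logits = emb @ params["f3"].T + params["f3b"]
    if not need_cache:
        return logits, emb
    cache = (x, cols1, h1, m1, p1, cols2, h2, m2, p2, flat, z1, a1, z2, emb)
    return logits, emb, cache


def _backward(params, cache, dlogits):
    x, cols1, h1, m1, p1, cols2, h2, m2, p2, flat, z1, a1, z2, emb = cache
    g = {}
    g["f3"] = dlogits.T @ emb
    g["f3b"] = dlogits.sum(0)
    demb = (dlogits @ params["f3"]) * (z2 > 0)
    g["f2"] = demb.T @ a1
    g["f2b"] = demb.sum(0)
    da1 = (demb @ params["f2"]) * (z1 > 0)
    g["f1"] = da1.T @ flat
    g["f1b"] = da1.sum(0)
    dflat = da1 @ params["f1"]
    dp2 = dflat.reshape(p2.shape)
    dr2 = _pool_backward(dp2, m2) * (h2 > 0)
    dp1, g["c2"], g["c2b"] = _conv_backward(dr2, cols2, p1.shape, params["c2"])
    dr1 = _pool_backward(dp1, m1) * (h1 > 0)
    _, g["c1"], g["c1b"] = _conv_backward(dr1, cols1, x.shape, params["c1"])
    return g


# ---------------------------------------------------------------------------
# data and training
# ---------------------------------------------------------------------------

def load_cifar10(dataset_path: str | Path):
    """Load the standard pickled CIFAR-10 batches as grayscale [0, 1] arrays."""
    root = Path(dataset_path)
    if (root / "cifar-10-batches-py").exists():
        root = root / "cifar-10-batches-py"
    train_files = [root / f"data_batch_{i}" for i in range(1, 6)]
    test_file = root / "test_batch"
    if not all(f.exists() for f in train_files) or not test_file.exists():
        raise ExternalDataError(
            f"external data required: CIFAR-10 batches not found under {dataset_path}"
        )

    def _read(path):
        with open(path, "rb") as fh:
            d = pickle.load(fh, encoding="bytes")
        imgs = d[b"data"].reshape(-1, 3, 32, 32).astype(float) / 255.0
        gray = imgs.mean(axis=1, keepdims=True)  # luminance as channel mean
        return gray, np.array(d[b"labels"])

    xs, ys = zip(*[_read(f) for f in train_files])
    x_test, y_test = _read(test_file)
    return np.concatenate(xs), np.concatenate(ys), x_test, y_test


def _normalize(images: np.ndarray, spec: EncoderSpec) -> np.ndarray:
    return (images - spec.norm_mean) / spec.norm_sd


def train_encoder(
    dataset_path: str | Path | None = None,
    epochs: int = 10,
    lr: float = 0.01,
    momentum: float = 0.9,
    batch_size: int = 64,
    seed: int = 0,
    data: tuple | None = None,
) -> EncoderSpec:
    """Train the classifier with SGD and return the frozen feature extractor.

    ``data`` may supply ``(x_train, y_train, x_test, y_test)`` directly
    (grayscale, (N, 1, 32, 32), labels int); otherwise the CIFAR-10 archive
    is read from ``dataset_path``.
    """
    if data is None:
        x_train, y_train, x_test, y_test = load_cifar10(dataset_path)
    else:
        x_train, y_train, x_test, y_test = data
    spec = init_encoder(seed)
    params = spec.params
    x_train = _normalize(x_train, spec)
    x_test = _normalize(x_test, spec)
    vel = {k: np.zeros_like(v) for k, v in params.items()}
    rng = np.random.default_rng(seed)
    n = len(x_train)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits, _, cache = _forward(params, xb, need_cache=True)
            z = logits - logits.max(axis=1, keepdims=True)
            p = np.exp(z)
            p /= p.sum(axis=1, keepdims=True)
            dlogits = p
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            grads = _backward(params, cache, dlogits)
            for k in params:
                vel[k] = momentum * vel[k] - lr * grads[k]
                params[k] = params[k] + vel[k]
    # evaluate in chunks to bound memory
    correct = 0
    for start in range(0, len(x_test), 512):
        logits, _ = _forward(params, x_test[start:start + 512])
        correct += int((logits.argmax(1) == y_test[start:start + 512]).sum())
    spec.trained = True
    spec.test_accuracy = correct / len(x_test)
    return spec


def embed_images(encoder: EncoderSpec, images: np.ndarray) -> EmbeddingMatrix:
    """Embed a batch of grayscale 32x32 images (values in [0, 1])."""
    images = np.asarray(images, dtype=float)
    if images.ndim == 3:
        images = images[:, None, :, :]
    if images.shape[1:] != (1, 32, 32):
        raise ValueError(f"expected (n, 1, 32, 32) grayscale images, got {images.shape}")
    _, emb = _forward(encoder.params, _normalize(images, encoder))
    return EmbeddingMatrix(values=np.maximum(emb, 0.0), require_coverage=False)


def gray_response(encoder: EncoderSpec, level: float = 0.5) -> np.ndarray:
    """Embedding of a uniform gray screen, for checking the zero-input convention."""
    img = np.full((1, 1, 32, 32), level)
    _, emb = _forward(encoder.params, _normalize(img, encoder))
    return emb[0]
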