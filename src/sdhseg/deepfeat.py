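"""Data-driven deep features from a compact U-net, with strict fold
isolation.

A small encoder-decoder segmentation network (3 resolution levels, base 16
channels) is trained per cross-validation fold on slices from that fold's
training scans only; the activations of the second layer before the output
layer — the last decoder convolution, widened to 64 channels — are pooled
(mean) over each superpixel to give 64 deep features. A scan's features
always come from the model whose training set excluded it, so the deep
block can never leak test information into the classifier.

The network is implemented directly in NumPy (im2col convolutions, manual
backpropagation, Adam) and trained with a combined cross-entropy + soft
Dice loss. Deep features are optional and off by default: the pipeline is
fully functional in hand-crafted-only mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ct_io import CTVolume
from .preprocess import HeadMasks
from .superpixel import SuperpixelMap, rescale_brain_window

__all__ = [
    "UnetSpec",
    "UnetArtifact",
    "train_unet",
    "extract_deep_features",
    "DEEP_COLUMNS",
    "unet_forward",
]

N_DEEP_FEATURES = 64
DEEP_COLUMNS = [f"deep_{i:02d}" for i in range(N_DEEP_FEATURES)]


@dataclass(frozen=True)
class UnetSpec:
    """Reduced U-net: 3 encoder levels, base 16 channels, 64-channel tap.

    ``feature_tap`` names the layer whose activations become deep features:
    the second layer before the per-pixel output, with exactly 64 channels.
    Input and output spatial dimensions are equal (same-padded 3x3 convs).
    """

    depth: int = 3
    base_channels: int = 16
    tap_channels: int = N_DEEP_FEATURES
    feature_tap: str = "dec1_conv2"
    patch_size: int = 32
    epochs: int = 4
    lr: float = 2e-3
    seed: int = 0

    def __post_init__(self):
        if self.tap_channels != N_DEEP_FEATURES:
            raise ValueError("feature tap layer must have exactly 64 channels")
        if self.patch_size % 2 ** (self.depth - 1) != 0:
            raise ValueError("patch size must be divisible by the pooling factor")


@dataclass
class UnetArtifact:
    params: dict
    spec: UnetSpec
    fold_id: int
    loss_history: list[float] = field(default_factory=list)


# ------------------------------------------------------------ primitives


def _conv2d(x, W, b):
    """Same-padded 3x3 (or 1x1) convolution. x: (N,C,H,W); W: (O,C,kh,kw)."""
    kh, kw = W.shape[2], W.shape[3]
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    y = np.einsum("nchwij,ocij->nohw", cols, W, optimize=True)
    return y + b[None, :, None, None], cols


def _conv2d_backward(dy, cols, W, x_shape):
    dW = np.einsum("nohw,nchwij->ocij", dy, cols, optimize=True)
    db = dy.sum(axis=(0, 2, 3))
    kh, kw = W.shape[2], W.shape[3]
    ph, pw = kh // 2, kw // 2
    dyp = np.pad(dy, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    dcols = np.lib.stride_tricks.sliding_window_view(dyp, (kh, kw), axis=(2, 3))
    Wf = W[:, :, ::-1, ::-1]
    dx = np.einsum("nohwij,ocij->nchw", dcols, Wf, optimize=True)
    return dx[:, :, : x_shape[2], : x_shape[3]], dW, db


def _pool2(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    y = xr.max(axis=(3, 5))
    mask = xr == y[:, :, :, None, :, None]
    return y, mask


def _pool2_backward(dy, mask):
    dxr = mask * dy[:, :, :, None, :, None]
    n, c, h2, _, w2, _ = dxr.shape
    return dxr.reshape(n, c, h2 * 2, w2 * 2)


def _up2(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _up2_backward(dy):
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def _init_params(spec: UnetSpec, rng: np.random.Generator) -> dict:
    b0 = spec.base_channels

    def he(o, c, k):
        return rng.standard_normal((o, c, k, k)) * math.sqrt(2.0 / (c * k * k))

    layers = {
        "enc1_conv1": he(b0, 1, 3),
        "enc1_conv2": he(b0, b0, 3),
        "enc2_conv1": he(2 * b0, b0, 3),
        "enc2_conv2": he(2 * b0, 2 * b0, 3),
        "bott_conv1": he(4 * b0, 2 * b0, 3),
        "bott_conv2": he(4 * b0, 4 * b0, 3),
        "dec2_conv1": he(2 * b0, 6 * b0, 3),
        "dec2_conv2": he(2 * b0, 2 * b0, 3),
        "dec1_conv1": he(b0, 3 * b0, 3),
        "dec1_conv2": he(spec.tap_channels, b0, 3),
        "out_conv": he(1, spec.tap_channels, 1),
    }
    params = {}
    for name, W in layers.items():
        params[f"{name}.W"] = W
        params[f"{name}.b"] = np.zeros(W.shape[0])
    return params


def unet_forward(params: dict, x: np.ndarray, want_cache: bool = False):
    """Forward pass. Returns (probability, tap_activations[, cache])."""
    cache: dict = {}

    def conv_relu(name, inp):
        y, cols = _conv2d(inp, params[f"{name}.W"], params[f"{name}.b"])
        a = np.maximum(y, 0.0)
        if want_cache:
            cache[name] = (cols, y, inp.shape)
        return a

    e1 = conv_relu("enc1_conv2", conv_relu("enc1_conv1", x))
    p1, m1 = _pool2(e1)
    e2 = conv_relu("enc2_conv2", conv_relu("enc2_conv1", p1))
    p2, m2 = _pool2(e2)
    b = conv_relu("bott_conv2", conv_relu("bott_conv1", p2))
    u2 = np.concatenate([_up2(b), e2], axis=1)
    d2 = conv_relu("dec2_conv2", conv_relu("dec2_conv1", u2))
    u1 = np.concatenate([_up2(d2), e1], axis=1)
    tap = conv_relu("dec1_conv2", conv_relu("dec1_conv1", u1))
    z, cols_out = _conv2d(tap, params["out_conv.W"], params["out_conv.b"])
    prob = 1.0 / (1.0 + np.exp(-z))
    if want_cache:
        cache["out_conv"] = (cols_out, z, tap.shape)
        cache["pool"] = (m1, m2)
        cache["splits"] = {"e1": e1.shape[1], "e2": e2.shape[1], "b": b.shape[1], "d2": d2.shape[1]}
        return prob, tap, cache
    return prob, tap


def _loss_and_grad(params: dict, x: np.ndarray, t: np.ndarray):
    """Cross-entropy + soft-Dice loss and dLoss/dparams."""
    prob, _, cache = unet_forward(params, x, want_cache=True)
    eps = 1e-7
    p = np.clip(prob, eps, 1 - eps)
    npix = p.size
    bce = float(-(t * np.log(p) + (1 - t) * np.log(1 - p)).mean())
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum()) + 1.0
    dice = 2.0 * inter / denom
    loss = bce + (1.0 - dice)

    # gradient wrt pre-sigmoid logits
    dprob_bce = (p - t) / npix  # already includes sigmoid'
    ddice_dp = (2.0 * t * denom - 2.0 * inter) / denom**2
    dprob_dice = -ddice_dp * p * (1 - p)
    dz = dprob_bce + dprob_dice

    grads: dict[str, np.ndarray] = {}

    def conv_back(name, dy):
        cols, y_pre, in_shape = cache[name]
        dx, dW, db = _conv2d_backward(dy, cols, params[f"{name}.W"], in_shape)
        grads[f"{name}.W"] = dW
        grads[f"{name}.b"] = db
        return dx

    def conv_relu_back(name, da):
        _, y_pre, _ = cache[name]
        return conv_back(name, da * (y_pre > 0))

    dtap = conv_back("out_conv", dz)
    du1 = conv_relu_back("dec1_conv1", conv_relu_back("dec1_conv2", dtap))
    c_d2 = cache["splits"]["d2"]
    dd2_up, de1 = du1[:, :c_d2], du1[:, c_d2:]
    du2 = conv_relu_back("dec2_conv1", conv_relu_back("dec2_conv2", _up2_backward(dd2_up)))
    c_b = cache["splits"]["b"]
    db_up, de2 = du2[:, :c_b], du2[:, c_b:]
    dp2 = conv_relu_back("bott_conv1", conv_relu_back("bott_conv2", _up2_backward(db_up)))
    m1, m2 = cache["pool"]
    de2 = de2 + _pool2_backward(dp2, m2)
    dp1 = conv_relu_back("enc2_conv1", conv_relu_back("enc2_conv2", de2))
    de1 = de1 + _pool2_backward(dp1, m1)
    conv_relu_back("enc1_conv1", conv_relu_back("enc1_conv2", de1))
    return loss, grads


# ------------------------------------------------------------ training


def _sample_patches(slices, masks, patch, n_per_slice, rng):
    xs, ts = [], []
    for img, msk in zip(slices, masks):
        h, w = img.shape
        if h < patch or w < patch:
            continue
        pos = np.argwhere(msk)
        for j in range(n_per_slice):
            if len(pos) and j % 2 == 0:  # half the patches centered on lesion
                r, c = pos[rng.integers(len(pos))]
                r0 = int(np.clip(r - patch // 2, 0, h - patch))
                c0 = int(np.clip(c - patch // 2, 0, w - patch))
            else:
                r0 = int(rng.integers(0, h - patch + 1))
                c0 = int(rng.integers(0, w - patch + 1))
            xs.append(img[r0 : r0 + patch, c0 : c0 + patch])
            ts.append(msk[r0 : r0 + patch, c0 : c0 + patch])
    return np.array(xs)[:, None], np.array(ts, dtype=float)[:, None]


def train_unet(
    training_slices: list[tuple[str, np.ndarray, np.ndarray]],
    fold_id: int,
    spec: UnetSpec = UnetSpec(),
    held_out_scan_ids: set[str] | None = None,
    batch_size: int = 8,
    patches_per_slice: int = 2,
) -> UnetArtifact:
    """Train one fold's network on (scan_id, image, mask) slices.

    *held_out_scan_ids* is the leakage guard: any training slice from a
    held-out scan is a hard error. Images are expected on the [0, 1] brain
    window scale (see :func:`sdhseg.superpixel.rescale_brain_window`).
    """
    train_ids = {sid for sid, _, _ in training_slices}
    if held_out_scan_ids:
        overlap = train_ids & set(held_out_scan_ids)
        if overlap:
            raise ValueError(f"held-out scans present in training inputs: {sorted(overlap)}")
    rng = np.random.default_rng(spec.seed + fold_id)
    params = _init_params(spec, rng)
    mom = {k: np.zeros_like(v) for k, v in params.items()}
    vel = {k: np.zeros_like(v) for k, v in params.items()}
    step = 0
    history = []
    imgs = [img for _, img, _ in training_slices]
    msks = [m for _, _, m in training_slices]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    for _epoch in range(spec.epochs):
        X, T = _sample_patches(imgs, msks, spec.patch_size, patches_per_slice, rng)
        order = rng.permutation(len(X))
        epoch_loss = []
        for start in range(0, len(X), batch_size):
            idx = order[start : start + batch_size]
            loss, grads = _loss_and_grad(params, X[idx], T[idx])
            epoch_loss.append(loss)
            step += 1
            for k in params:
                g = grads[k]
                mom[k] = beta1 * mom[k] + (1 - beta1) * g
                vel[k] = beta2 * vel[k] + (1 - beta2) * g * g
                mhat = mom[k] / (1 - beta1**step)
                vhat = vel[k] / (1 - beta2**step)
                params[k] -= spec.lr * mhat / (np.sqrt(vhat) + eps)
        history.append(float(np.mean(epoch_loss)))
    return UnetArtifact(params=params, spec=spec, fold_id=fold_id, loss_history=history)


# ------------------------------------------------------------ extraction


def _pad_to_multiple(img: np.ndarray, m: int):
    h, w = img.shape
    H = -(-h // m) * m
    W = -(-w // m) * m
    return np.pad(img, ((0, H - h), (0, W - w)), mode="edge"), (h, w)


def extract_deep_features(
    artifact: UnetArtifact,
    volume: CTVolume,
    masks: HeadMasks,
    spmap: SuperpixelMap,
    scan_fold: int,
) -> pd.DataFrame:
    """64 tap-layer activations, mean-pooled over each superpixel.

    *scan_fold* is the scan's cross-validation fold; it must equal the
    artifact's fold (whose training set excluded that fold's scans).
    Inference runs on the ROI-masked, brain-window-rescaled slices for
    consistency with the hand-crafted features.
    """
    if scan_fold != artifact.fold_id:
        raise ValueError(
            f"fold mismatch: scan is in fold {scan_fold}, model trained for "
            f"held-out fold {artifact.fold_id}"
        )
    factor = 2 ** (artifact.spec.depth - 1)
    n = spmap.n_superpixels
    out = np.zeros((n, N_DEEP_FEATURES))
    for k in np.unique(spmap.slice_index):
        img = rescale_brain_window(volume.voxels[:, :, int(k)])
        img = np.where(masks.intracranial[:, :, int(k)], img, 0.0)
        padded, (h, w) = _pad_to_multiple(img, factor)
        _, tap = unet_forward(artifact.params, padded[None, None])
        tap = tap[0, :, :h, :w]  # (64, H, W)
        label_slice = spmap.label_image[:, :, int(k)]
        ids_here = np.nonzero(spmap.slice_index == k)[0]
        for i in ids_here:
            region = label_slice == (i + 1)
            out[i] = tap[:, region].mean(axis=1)
    return pd.DataFrame(out, columns=DEEP_COLUMNS)
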