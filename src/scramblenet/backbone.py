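"""Convolutional feature extraction from (encrypted) images.

The classifier never sees raw pixels: images are preprocessed to a fixed
square size and scaled to [0, 1], then pushed through a frozen convolutional
backbone whose classification head is removed, yielding one fixed-length
feature vector per image.

Three architectures are exposed:

``tiny``
    A small three-conv-block network (3x3 kernels, ReLU, 2x2 max pooling)
    with fixed, seeded He-initialized random filters.  It needs no download,
    runs in seconds on one CPU, and is the first-class backbone for all
    tests and experiments.  Random convolutional features followed by a
    trained classifier head are a long-standing, well-characterized baseline
    for image classification.

``vgg16`` / ``vgg19``
    The standard 16/19-layer VGG architectures (3x3 convs, stride-1, same
    padding, 2x2/stride-2 max pools, 512 final channels).  Their layer
    tables are encoded here so feature dimensionalities are derived
    analytically, but pretrained ImageNet weights require a download:
    requesting them raises an explicit error pointing at ``tiny``.

Feature reduction is either global average pooling over the final feature
map (channels-sized vector) or flattening it (channels x spatial^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skimage.transform import resize

__all__ = [
    "BackboneError",
    "BackboneSpec",
    "preprocess",
    "extract_features",
    "feature_dim",
]


class BackboneError(ValueError):
    """Invalid backbone configuration or unavailable weights."""


#: Channel progression of each conv block; the final entry is the channel
#: count of the feature map the head would have consumed.
_ARCHITECTURES = {
    # (channels per block, convs per block)
    "vgg16": ((64, 128, 256, 512, 512), (2, 2, 3, 3, 3)),
    "vgg19": ((64, 128, 256, 512, 512), (2, 2, 4, 4, 4)),
    "tiny": ((16, 32, 64), (1, 1, 1)),
}


@dataclass(frozen=True)
class BackboneSpec:
    """A frozen feature-extraction backbone.

    Attributes
    ----------
    architecture : {"tiny", "vgg16", "vgg19"}
    weights : {"random", "pretrained"}
        ``tiny`` supports only seeded random filters (no download);
        pretrained VGG weights are not bundled and raise an explicit error.
    reduction : {"global-average-pool", "flatten"}
        How the final feature map becomes a vector.  Pooling gives compact
        position-agnostic features; flattening preserves spatial layout
        (and hence sensitivity to *which* permutation scrambled the image).
    input_size : int
        Side length images are resized to before extraction (default 224).
    seed : int
        Seed for the random filters of ``tiny``.
    """

    architecture: Literal["tiny", "vgg16", "vgg19"] = "tiny"
    weights: Literal["random", "pretrained"] = "random"
    reduction: Literal["global-average-pool", "flatten"] = "global-average-pool"
    input_size: int = 224
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in _ARCHITECTURES:
            raise BackboneError(
                f"unknown architecture {self.architecture!r}; "
                f"choose from {sorted(_ARCHITECTURES)}"
            )
        if self.reduction not in ("global-average-pool", "flatten"):
            raise BackboneError(f"unknown reduction {self.reduction!r}")
        if self.weights not in ("random", "pretrained"):
            raise BackboneError(f"unknown weights source {self.weights!r}")
        if self.input_size < 8:
            raise BackboneError("input_size must be >= 8")


def feature_dim(spec: BackboneSpec) -> int:
    """Output dimensionality, derived from the architecture table.

    Each block halves the spatial side (2x2/stride-2 max pool); the final
    feature map has the last block's channel count.  For vgg16 at 224 with
    global average pooling this is 512; flattened it is 512 * 7 * 7 = 25088.
    """
    channels, _ = _ARCHITECTURES[spec.architecture]
    side = spec.input_size
    for _ in channels:
        side //= 2
    if side < 1:
        raise BackboneError(
            f"input_size {spec.input_size} too small for {spec.architecture}"
        )
    if spec.reduction == "global-average-pool":
        return channels[-1]
    return channels[-1] * side * side


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(image: np.ndarray, size: int = 224) -> np.ndarray:
    """Resize a square 8-bit image to ``size x size`` and scale to [0, 1].

    A ``size``-sided input passes through with no resampling (bit-faithful
    up to the 1/255 scaling); other sizes are resampled with anti-aliasing.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {img.shape}")
    img = img / 255.0
    if img.shape != (size, size):
        img = resize(img, (size, size), anti_aliasing=True, mode="reflect")
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# The tiny backbone: seeded random conv filters, exact and fast in numpy
# ---------------------------------------------------------------------------

def _conv3x3(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Same-padding 3x3 convolution, channels-first, via im2col + matmul.

    x: (C_in, H, W); weights: (C_out, C_in, 3, 3) -> (C_out, H, W).
    """
    c_in, h, w = x.shape
    padded = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    # gather the 9 shifted views into columns: (H*W, C_in*9)
    cols = np.empty((h * w, c_in * 9), dtype=x.dtype)
    k = 0
    for dy in range(3):
        for dx in range(3):
            view = padded[:, dy : dy + h, dx : dx + w]
            cols[:, k * c_in : (k + 1) * c_in] = view.reshape(c_in, -1).T
            k += 1
    # weight rows in the same (shift-major, channel-minor) order as cols
    w_mat = weights.transpose(2, 3, 1, 0).reshape(9 * c_in, -1)
    out = cols @ w_mat  # (H*W, C_out)
    return out.T.reshape(-1, h, w)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    """2x2/stride-2 max pooling, channels-first; odd trailing row/col dropped."""
    c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    x = x[:, : h2 * 2, : w2 * 2]
    return x.reshape(c, h2, 2, w2, 2).max(axis=(2, 4))


def _tiny_filters(spec: BackboneSpec) -> list:
    """He-initialized fixed random filters with random biases, deterministic
    given the seed.

    The biases matter: they put each channel's ReLU threshold at a
    different level, so after pooling the channels act as a bank of soft
    intensity/contrast thresholds -- the nonlinear statistics that survive
    pixel permutation.
    """
    rng = np.random.default_rng(spec.seed)
    channels, _ = _ARCHITECTURES["tiny"]
    layers = []
    c_in = 1
    for c_out in channels:
        std = np.sqrt(2.0 / (9 * c_in))
        w = rng.normal(0.0, std, size=(c_out, c_in, 3, 3))
        b = rng.normal(0.0, 0.5, size=c_out)
        layers.append((w, b))
        c_in = c_out
    return layers


def _tiny_forward(img: np.ndarray, layers: list) -> np.ndarray:
    x = img[np.newaxis, :, :]
    for w, b in layers:
        x = _conv3x3(x, w) + b[:, np.newaxis, np.newaxis]
        np.maximum(x, 0.0, out=x)  # ReLU
        x = _maxpool2(x)
    return x


def _reduce(fmap: np.ndarray, reduction: str) -> np.ndarray:
    if reduction == "global-average-pool":
        return fmap.mean(axis=(1, 2))
    return fmap.ravel()


def extract_features(
    images: Sequence[np.ndarray], spec: BackboneSpec | None = None
) -> np.ndarray:
    """Map preprocessed-or-raw images to fixed-length feature vectors.

    Accepts uint8 grids (preprocessed internally) or float [0, 1] arrays of
    the spec's input size.  Returns an ``(n_images, feature_dim)`` float64
    array.  Extraction is deterministic: identical images give bit-identical
    vectors.
    """
    if spec is None:
        spec = BackboneSpec()
    if spec.architecture in ("vgg16", "vgg19") and spec.weights == "pretrained":
        raise BackboneError(
            f"pretrained {spec.architecture} weights are not available in this "
            "environment (they require a download); use architecture='tiny', "
            "which needs no weights file"
        )
    if spec.architecture in ("vgg16", "vgg19"):
        raise BackboneError(
            f"{spec.architecture} inference requires a deep-learning runtime "
            "that is not installed; use architecture='tiny'"
        )
    filters = _tiny_filters(spec)
    out = np.empty((len(images), feature_dim(spec)), dtype=np.float64)
    for i, img in enumerate(images):
        arr = np.asarray(img)
        if arr.dtype == np.uint8 or arr.max() > 1.0:
            arr = preprocess(arr, size=spec.input_size)
        elif arr.shape != (spec.input_size, spec.input_size):
            arr = resize(arr, (spec.input_size, spec.input_size), anti_aliasing=True)
        fmap = _tiny_forward(arr, filters)
        out[i] = _reduce(fmap, spec.reduction)
    if not np.all(np.isfinite(out)):
        raise BackboneError("non-finite feature values")
    return out
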