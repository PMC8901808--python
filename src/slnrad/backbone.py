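"""Deep-learning-based (DLB) features from a frozen convolutional backbone.

Each tumor slice is rendered as a 224x224x3 tensor whose channels are the
masked, window-normalized wash-in, wash-out and SER maps scaled to 0-255,
then pushed through a frozen (never-updated) CNN; the activations of the
last fully connected layer (pre-softmax, width 1000) are the slice's feature
vector, and a subject's vector is the element-wise mean over its slices.

The backbone sits behind a single forward-pass contract and is pluggable:

* ``architecture_id="tiny"`` — a small strided CNN with seeded random
  weights; fast, fully offline, and the default for synthetic cohorts.
  Random frozen projections preserve class signal well enough to exercise
  the whole pipeline.
* ``architecture_id="vgg16"`` — the canonical 16-layer VGG configuration
  (13 conv + 3 fc, tap fc8).  Weights may be random-seeded, or loaded from a
  user-supplied ``.npz`` archive with arrays ``<layer>_W`` / ``<layer>_b``;
  pretrained weights are not bundled and cannot be fetched offline, so
  ``weights_source="pretrained"`` without ``weights_path`` raises.

All forward passes are plain numpy (im2col convolutions); weights are
created once and frozen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import DEFAULT_WINDOWS, KineticMapSet, ResamplingWindow
from .regions import apply_mask, crop_window

__all__ = [
    "BackboneConfig",
    "Backbone",
    "build_backbone",
    "preprocess_slices",
    "extract_slice_features",
    "aggregate_slices",
    "extract_dlb_vector",
]

INPUT_SIZE = 224


@dataclass(frozen=True)
class BackboneConfig:
    architecture_id: str = "vgg16"
    tap_point: str = "fc8"
    output_dim: int = 1000
    weights_source: str = "random_seeded"   # or "pretrained"
    weights_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture_id not in ("vgg16", "tiny"):
            raise ValueError(f"unknown architecture {self.architecture_id!r}")
        if self.weights_source not in ("pretrained", "random_seeded"):
            raise ValueError(f"unknown weights source {self.weights_source!r}")
        if self.tap_point != "fc8":
            raise ValueError("only the last fully connected layer can be tapped")


# ---------------------------------------------------------------------------
# numpy building blocks
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    """(C, H, W) -> (C*k*k, out_h*out_w) patch matrix."""
    c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    out_h = (x.shape[1] - k) // stride + 1
    out_w = (x.shape[2] - k) // stride + 1
    s0, s1, s2 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(c, out_h, out_w, k, k),
        strides=(s0, s1 * stride, s2 * stride, s1, s2),
    )
    cols = windows.transpose(0, 3, 4, 1, 2).reshape(c * k * k, out_h * out_w)
    return np.ascontiguousarray(cols), out_h, out_w


def _conv(x: np.ndarray, W: np.ndarray, b: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """W: (out_c, in_c, k, k)."""
    out_c, in_c, k, _ = W.shape
    cols, oh, ow = _im2col(x, k, stride, pad)
    out = W.reshape(out_c, -1) @ cols + b[:, None]
    return out.reshape(out_c, oh, ow)


def _maxpool(x: np.ndarray, k: int = 2) -> np.ndarray:
    c, h, w = x.shape
    h2, w2 = h // k, w // k
    return x[:, : h2 * k, : w2 * k].reshape(c, h2, k, w2, k).max(axis=(2, 4))


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


# layer specs: ("conv", out_c, k, stride, pad) | ("pool", k) | ("fc", out_dim)
_TINY_LAYERS = [
    ("conv", 8, 5, 4, 2),
    ("pool", 2),
    ("conv", 16, 3, 2, 1),
    ("pool", 2),
    ("fc", None),  # out_dim filled from config
]

_VGG16_LAYERS = [
    ("conv", 64, 3, 1, 1), ("conv", 64, 3, 1, 1), ("pool", 2),
    ("conv", 128, 3, 1, 1), ("conv", 128, 3, 1, 1), ("pool", 2),
    ("conv", 256, 3, 1, 1), ("conv", 256, 3, 1, 1), ("conv", 256, 3, 1, 1), ("pool", 2),
    ("conv", 512, 3, 1, 1), ("conv", 512, 3, 1, 1), ("conv", 512, 3, 1, 1), ("pool", 2),
    ("conv", 512, 3, 1, 1), ("conv", 512, 3, 1, 1), ("conv", 512, 3, 1, 1), ("pool", 2),
    ("fc", 4096), ("fc", 4096), ("fc", None),
]


class Backbone:
    """A frozen feed-forward CNN evaluated in numpy.

    Weights are fixed at construction; :meth:`forward` is deterministic.
    """

    def __init__(self, config: BackboneConfig):
        self.config = config
        template = _TINY_LAYERS if config.architecture_id == "tiny" else _VGG16_LAYERS
        self.layers = [
            ("fc", config.output_dim) if spec[0] == "fc" and spec[1] is None else spec
            for spec in template
        ]
        if config.weights_source == "pretrained":
            if not config.weights_path:
                raise ValueError(
                    "pretrained weights are not bundled; pass weights_path to an "
                    ".npz archive or use weights_source='random_seeded'"
                )
            self._weights = dict(np.load(config.weights_path))
        else:
            self._weights = self._random_weights(config.seed)
        self._check_tap()

    # -- weight generation ---------------------------------------------------
    def _shapes(self) -> list[tuple[str, tuple, tuple]]:
        """Per parametric layer: (name, W shape, b shape)."""
        shapes = []
        in_c, size = 3, INPUT_SIZE
        conv_i = fc_i = 0
        for spec in self.layers:
            kind = spec[0]
            if kind == "conv":
                _, out_c, k, stride, pad = spec
                conv_i += 1
                shapes.append((f"conv{conv_i}", (out_c, in_c, k, k), (out_c,)))
                size = (size + 2 * pad - k) // stride + 1
                in_c = out_c
            elif kind == "pool":
                size //= spec[1]
            elif kind == "fc":
                out_dim = spec[1]
                fc_i += 1
                in_dim = in_c * size * size if fc_i == 1 else in_c
                shapes.append((f"fc{fc_i}", (out_dim, in_dim), (out_dim,)))
                in_c, size = out_dim, 1
        return shapes

    def _random_weights(self, seed: int) -> dict[str, np.ndarray]:
        rng = np.random.default_rng(seed)
        weights = {}
        for name, w_shape, b_shape in self._shapes():
            fan_in = int(np.prod(w_shape[1:]))
            weights[f"{name}_W"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=w_shape
            ).astype(np.float32)
            weights[f"{name}_b"] = np.zeros(b_shape, dtype=np.float32)
        return weights

    def _check_tap(self) -> None:
        last_fc = [n for n, _, _ in self._shapes() if n.startswith("fc")][-1]
        w = self._weights[f"{last_fc}_W"]
        if w.shape[0] != self.config.output_dim:
            raise ValueError(
                f"tapped layer width {w.shape[0]} != output_dim {self.config.output_dim}"
            )

    # -- inference -----------------------------------------------------------
    def forward(self, tensor: np.ndarray) -> np.ndarray:
        """224x224x3 slice tensor -> tapped pre-softmax activations."""
        if tensor.shape != (INPUT_SIZE, INPUT_SIZE, 3):
            raise ValueError(f"expected {(INPUT_SIZE, INPUT_SIZE, 3)}, got {tensor.shape}")
        x = np.ascontiguousarray(tensor.transpose(2, 0, 1), dtype=np.float32)
        conv_i = fc_i = 0
        n_fc = sum(1 for s in self.layers if s[0] == "fc")
        for spec in self.layers:
            kind = spec[0]
            if kind == "conv":
                conv_i += 1
                W = self._weights[f"conv{conv_i}_W"]
                b = self._weights[f"conv{conv_i}_b"]
                x = _relu(_conv(x, W, b, stride=spec[3], pad=spec[4]))
            elif kind == "pool":
                x = _maxpool(x, spec[1])
            elif kind == "fc":
                fc_i += 1
                W = self._weights[f"fc{fc_i}_W"]
                b = self._weights[f"fc{fc_i}_b"]
                x = W @ x.reshape(-1) + b
                if fc_i < n_fc:  # hidden fc layers keep ReLU; the tap is linear
                    x = _relu(x)
        return np.asarray(x, dtype=np.float64)


def build_backbone(config: BackboneConfig) -> Backbone:
    return Backbone(config)


# ---------------------------------------------------------------------------
# preprocessing and aggregation
# ---------------------------------------------------------------------------

def preprocess_slices(
    maps: KineticMapSet,
    roi: np.ndarray,
    windows: dict[str, ResamplingWindow] | None = None,
    region_kind: str = "intratumoral",
    size: int = INPUT_SIZE,
) -> np.ndarray:
    """Render each ROI-intersecting slice as a size x size x 3 tensor.

    Per channel: mask (outside-ROI and invalid voxels to 0) -> clip to the
    absolute-resampling window -> map affinely to [0, 1] -> multiply by 255.
    The zeroed background passes through the same affine map, so windows
    with a negative lower bound give a nonzero background level — faithful
    to the masking-before-normalization order.

    Returns an array of shape (n_slices, size, size, 3) with channels
    ordered (wash_in, wash_out, ser), slices ascending.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    channels = []
    for kind in ("wash_in", "wash_out", "ser"):
        window = (windows or {}).get(kind) or DEFAULT_WINDOWS[(kind, region_kind)]
        if window.width <= 0:
            raise ValueError("zero-width window")
        vol = maps.by_kind(kind)
        vol = np.where(np.isfinite(vol), vol, 0.0)
        vol = apply_mask(vol, roi)
        vol = np.clip(vol, window.lower, window.upper)
        vol = (vol - window.lower) / window.width * 255.0
        crops, _ = crop_window(vol, roi, size=size)
        channels.append(crops)
    return np.stack(channels, axis=-1)


def extract_slice_features(tensor: np.ndarray, backbone: Backbone) -> np.ndarray:
    """Forward one slice tensor through the frozen backbone."""
    vec = backbone.forward(tensor)
    if vec.shape != (backbone.config.output_dim,):
        raise ValueError("backbone output width mismatch")
    return vec


def aggregate_slices(rows: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean of the per-slice feature vectors."""
    if len(rows) == 0:
        raise ValueError("no slice vectors to aggregate")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("ragged slice vectors")
    return np.mean(np.stack(rows), axis=0)


def extract_dlb_vector(
    maps: KineticMapSet,
    roi: np.ndarray,
    backbone: Backbone,
    region_kind: str = "intratumoral",
) -> dict[str, float]:
    """One subject's DLB feature row for one region, keyed canonically."""
    tensors = preprocess_slices(maps, roi, region_kind=region_kind)
    vecs = [extract_slice_features(t, backbone) for t in tensors]
    agg = aggregate_slices(vecs)
    return {f"DLB:{region_kind}:fc8:{i:04d}": float(v) for i, v in enumerate(agg)}
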