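"""Preprocessing, ROI handling, segmentation model and GAW extraction.

The inference pipeline mirrors clinical practice for automatic glottis
segmentation: color frames are reduced to the luminance channel (Rec.601),
normalized to [-1, 1], optionally cropped to a region of interest whose
width and height are divisible by 32 (so the encoder-decoder's pooling and
up-sampling stages line up), passed through the network, and the sigmoid
output is scaled by 255 into 8-bit probability masks.  The glottal area
waveform (GAW) is the per-frame count of segmented pixels.

The model here is a from-scratch, desk-scale encoder-decoder (depth 3,
base 8 channels by default); a clinical-scale configuration is available
via the same constructor but is deliberately not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, UNet, dice_bce_loss_and_grad, dice_loss_and_grad
from .errors import ConfigurationError, DimensionError, GeometryError
from .videoio import Recording, ROIBox

__all__ = [
    "MaskSequence",
    "GAW",
    "SegModel",
    "to_luminance",
    "normalize_intensity",
    "adjust_roi",
    "build_model",
    "train_model",
    "predict_masks",
    "compute_gaw",
    "save_model",
    "load_model",
]

_LUMA = np.array([0.299, 0.587, 0.114])  # Rec.601


def to_luminance(frame: np.ndarray) -> np.ndarray:
    """Rec.601 luminance of an 8-bit color frame, rounded back to uint8."""
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise DimensionError(
            f"expected a (H, W, 3) color frame, got shape {frame.shape}"
        )
    return np.rint(frame.astype(np.float64) @ _LUMA).clip(0, 255).astype(np.uint8)


def normalize_intensity(img: np.ndarray) -> np.ndarray:
    """Map 8-bit intensities linearly onto [-1, 1] (0 → -1, 255 → +1)."""
    return (np.asarray(img, dtype=np.float32) / 127.5) - 1.0


def adjust_roi(roi: ROIBox, frame_shape: tuple[int, int]) -> ROIBox:
    """Smallest 32-divisible ROI containing the request, kept in-frame.

    Each dimension is rounded up to the next multiple of 32, the box is
    grown symmetrically around the request and then shifted inward (never
    shrunk) to stay inside the ``(H, W)`` frame.  Raises
    :class:`GeometryError` when the frame itself cannot host the required
    multiple.
    """
    H, W = frame_shape
    if roi.x0 >= W or roi.y0 >= H:
        raise GeometryError("ROI does not intersect the frame")
    new_w = -(-roi.width // 32) * 32
    new_h = -(-roi.height // 32) * 32
    if new_w > W or new_h > H:
        raise GeometryError(
            f"frame {H}x{W} too small for a 32-multiple ROI of {new_h}x{new_w}"
        )
    x0 = roi.x0 - (new_w - roi.width) // 2
    y0 = roi.y0 - (new_h - roi.height) // 2
    x0 = min(max(x0, 0), W - new_w)
    y0 = min(max(y0, 0), H - new_h)
    return ROIBox(x0=x0, y0=y0, width=new_w, height=new_h)


@dataclass
class MaskSequence:
    """Per-frame 8-bit glottis probability masks (0 background, 255 glottis).

    Stored after the x255 scaling of the sigmoid output; ``threshold`` is
    the binarization cut on the unit scale.
    """

    masks: np.ndarray  # (T, H, W) uint8
    threshold: float = 0.5

    def __post_init__(self):
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 3:
            raise DimensionError(f"masks must be (T, H, W), got {self.masks.shape}")
        if self.masks.dtype == bool:
            self.masks = self.masks.astype(np.uint8) * 255
        if self.masks.dtype != np.uint8:
            raise ValueError("masks must be uint8 (or bool)")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")

    def binarize(self) -> np.ndarray:
        """Boolean masks: pixel counted as glottis when value/255 > threshold."""
        return self.masks.astype(np.float64) / 255.0 > self.threshold

    def __len__(self) -> int:
        return self.masks.shape[0]


@dataclass
class GAW:
    """Glottal area waveform: per-frame glottal area in pixels²."""

    areas: np.ndarray

    def __post_init__(self):
        self.areas = np.asarray(self.areas)
        if self.areas.ndim != 1:
            raise DimensionError("GAW must be a 1-D area trace")
        if (self.areas < 0).any():
            raise ValueError("areas must be non-negative")

    def __len__(self) -> int:
        return self.areas.shape[0]


@dataclass
class SegModel:
    """A seeded encoder-decoder glottis segmenter.

    Input H and W must be multiples of 32; output is a per-pixel sigmoid
    value in (0, 1) at the input resolution.
    """

    net: UNet
    depth: int
    base_channels: int
    seed: int
    loss_history: list[float] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters

    def copy(self) -> "SegModel":
        return SegModel(
            net=self.net.copy(),
            depth=self.depth,
            base_channels=self.base_channels,
            seed=self.seed,
            loss_history=list(self.loss_history),
        )


def build_model(depth: int = 3, base_channels: int = 8, seed: int = 0) -> SegModel:
    """Construct a seeded segmenter; identical seeds give identical weights."""
    return SegModel(
        net=UNet(depth=depth, base_channels=base_channels, seed=seed),
        depth=depth,
        base_channels=base_channels,
        seed=seed,
    )


def _check_dims32(H: int, W: int) -> None:
    if H % 32 or W % 32:
        raise GeometryError(
            f"frame dimensions must be divisible by 32, got {H}x{W}"
        )


def _prep_images(images: np.ndarray) -> np.ndarray:
    """Accept (N,H,W) 8-bit luminance or (N,H,W,3) color; return normalized
    float32 (N,H,W) in [-1,1]."""
    images = np.asarray(images)
    if images.ndim == 4 and images.shape[-1] == 3:
        lum = np.rint(images.astype(np.float64) @ _LUMA).clip(0, 255)
        return normalize_intensity(lum.astype(np.uint8))
    if images.ndim != 3:
        raise DimensionError(f"expected (N,H,W) or (N,H,W,3), got {images.shape}")
    if images.dtype == np.uint8:
        return normalize_intensity(images)
    return images.astype(np.float32)


def train_model(
    model: SegModel,
    images: np.ndarray,
    masks: np.ndarray,
    epochs: int = 20,
    learning_rate: float = 1e-4,
    seed: int = 0,
    batch_size: int = 8,
    bce_weight: float = 0.5,
) -> SegModel:
    """Train (in place) with soft Dice + weighted BCE loss and Adam.

    ``images``: (N,H,W) 8-bit luminance, (N,H,W,3) color, or pre-normalized
    float; ``masks``: (N,H,W) binary (bool or {0,1} or 0/255), or float in
    [0,1] for soft targets.  ``bce_weight=0`` recovers pure soft Dice.
    Per-epoch mean losses are appended to ``model.loss_history``.
    Deterministic per seed.
    """
    x = _prep_images(images)
    g = np.asarray(masks)
    if g.shape != x.shape:
        raise DimensionError(f"masks {g.shape} must match images {x.shape}")
    if x.shape[0] == 0:
        raise ConfigurationError("empty training set")
    _check_dims32(x.shape[1], x.shape[2])
    if g.dtype != bool and g.max(initial=0) > 1:
        g = g > 127
    g = g.astype(np.float32)

    rng = np.random.default_rng(seed)
    opt = Adam(model.net.params, lr=learning_rate)
    n = x.shape[0]
    # Even partition: a tiny trailing batch would get an outsized update
    # weight (losses are batch-normalized), which destabilizes fine-tuning.
    n_batches = max(1, -(-n // batch_size))
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for sel in np.array_split(order, n_batches):
            prob, cache = model.net.forward(x[sel], want_cache=True)
            if bce_weight > 0:
                loss, dprob = dice_bce_loss_and_grad(
                    prob, g[sel], bce_weight=bce_weight
                )
            else:
                loss, dprob = dice_loss_and_grad(prob, g[sel])
            losses.append(loss)
            if learning_rate > 0:
                grads = model.net.backward(cache, dprob)
                opt.step(model.net.params, grads)
        model.loss_history.append(float(np.mean(losses)))
    return model


def predict_masks(
    model: SegModel,
    rec: Recording | np.ndarray,
    roi: ROIBox | None = None,
    threshold: float = 0.5,
    batch_size: int = 16,
) -> MaskSequence:
    """Run inference over all frames of a recording.

    Per frame: luminance extraction → [-1,1] normalization → optional ROI
    crop → forward pass → x255 into uint8.  With an ROI, pixels outside it
    are 0 in the returned full-frame masks.  The ROI dimensions must be
    divisible by 32 (use :func:`adjust_roi` first).
    """
    frames = rec.frames if isinstance(rec, Recording) else np.asarray(frames_arr(rec))
    T, H, W = frames.shape[:3]
    if roi is not None:
        if roi.width % 32 or roi.height % 32:
            raise GeometryError(
                f"ROI {roi.height}x{roi.width} not divisible by 32; "
                "run adjust_roi first"
            )
        if roi.x1 > W or roi.y1 > H:
            raise GeometryError("ROI extends beyond the frame")
        ys, xs = roi.as_slices()
        work = frames[:, ys, xs]
    else:
        _check_dims32(H, W)
        work = frames
    x = _prep_images(work)
    out = np.zeros((T, H, W), dtype=np.uint8)
    for s in range(0, T, batch_size):
        prob = model.net.forward(x[s : s + batch_size])
        block = np.rint(prob * 255.0).clip(0, 255).astype(np.uint8)
        if roi is not None:
            out[s : s + batch_size, ys, xs] = block
        else:
            out[s : s + batch_size] = block
    return MaskSequence(masks=out, threshold=threshold)


def frames_arr(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim not in (3, 4):
        raise DimensionError(f"expected a frame stack, got shape {x.shape}")
    return x


def compute_gaw(masks: MaskSequence) -> GAW:
    """GAW by summing segmented pixels in each frame (area in pixels²)."""
    return GAW(areas=masks.binarize().sum(axis=(1, 2)).astype(np.int64))


def save_model(model: SegModel, path) -> None:
    """Save a checkpoint (architecture meta + weights) as an .npz file."""
    np.savez(
        path,
        __depth=model.depth,
        __base_channels=model.base_channels,
        __seed=model.seed,
        **model.net.params,
    )


def load_model(path) -> SegModel:
    """Load a checkpoint written by :func:`save_model`."""
    with np.load(path) as data:
        model = build_model(
            depth=int(data["__depth"]),
            base_channels=int(data["__base_channels"]),
            seed=int(data["__seed"]),
        )
        for k in model.net.params:
            model.net.params[k] = data[k].astype(np.float32)
    return model
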