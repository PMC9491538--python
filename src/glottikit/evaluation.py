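"""Segmentation metrics, automated artifact detection, and GAW agreement.

Metrics operate on binary ground-truth / prediction pairs (G, P):

* IoU = |G ∩ P| / |G ∪ P|
* Dice = 2|G ∩ P| / (|G| + |P|)  (algebraically 2·IoU/(1+IoU))
* pixel accuracy = (TP + TN) / all pixels
* boundary IoU — IoU restricted to thin bands within ``band_px`` of each
  mask's contour, sensitive to boundary errors that region IoU washes out.

When both masks are empty (closed glottis) the overlap metrics default to
1 — perfect agreement on absence — because closed-phase frames dominate the
low-score tail otherwise; ``empty_value`` makes the alternative (NaN)
available.

Artifact detection formalizes the two failure modes seen in long-term
clinical segmentation: (1) *spurious* masks — a connected component lying
entirely outside a prior region where the glottis may legitimately appear —
and (2) *empty* masks in frames whose temporal neighbors on both sides are
non-empty ("empty while open").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import pearsonr

from .errors import DimensionError
from .segmentation import GAW, MaskSequence
from .videoio import ROIBox

__all__ = [
    "ArtifactReport",
    "EvalReport",
    "iou",
    "dice",
    "pixel_accuracy",
    "boundary_iou",
    "detect_artifacts",
    "gaw_agreement",
    "evaluate_masks",
]


def _pair(G, P) -> tuple[np.ndarray, np.ndarray]:
    G, P = np.asarray(G), np.asarray(P)
    if G.shape != P.shape:
        raise DimensionError(f"mask shapes differ: {G.shape} vs {P.shape}")
    return G.astype(bool), P.astype(bool)


def iou(G, P, empty_value: float = 1.0) -> float:
    """Intersection over union of two binary masks."""
    G, P = _pair(G, P)
    union = np.logical_or(G, P).sum()
    if union == 0:
        return empty_value
    return float(np.logical_and(G, P).sum() / union)


def dice(G, P, empty_value: float = 1.0) -> float:
    """Dice coefficient 2|G∩P| / (|G|+|P|)."""
    G, P = _pair(G, P)
    denom = int(G.sum()) + int(P.sum())
    if denom == 0:
        return empty_value
    return float(2.0 * np.logical_and(G, P).sum() / denom)


def pixel_accuracy(G, P) -> float:
    """Fraction of pixels labeled identically in both masks."""
    G, P = _pair(G, P)
    return float((G == P).mean())


def _boundary_band(M: np.ndarray, band_px: int) -> np.ndarray:
    """Pixels of M within band_px (Euclidean) of its contour.

    Equivalently M minus its erosion by a disk of radius band_px; the frame
    border counts as background, so masks touching the edge keep a band
    there too.
    """
    if not M.any():
        return M
    padded = np.pad(M, 1)
    dist = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    return M & (dist <= band_px)


def boundary_iou(G, P, band_px: int = 2) -> float:
    """IoU restricted to thin bands around each mask's contour."""
    if band_px < 1:
        raise ValueError("band_px must be >= 1")
    G, P = _pair(G, P)
    Gb = _boundary_band(G, band_px)
    Pb = _boundary_band(P, band_px)
    union = np.logical_or(Gb, Pb).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(Gb, Pb).sum() / union)


@dataclass
class ArtifactReport:
    """Frame-level artifact flags for one mask sequence.

    ``video_flag`` is raised when the fraction of flagged frames exceeds
    ``flag_fraction`` — the per-video analogue of a reviewer rejecting the
    whole recording.
    """

    empty_frames: list[int]
    spurious_frames: list[int]
    n_frames: int
    flag_fraction: float

    @property
    def artifact_count(self) -> int:
        return len(set(self.empty_frames) | set(self.spurious_frames))

    @property
    def video_flag(self) -> bool:
        if self.n_frames == 0:
            return False
        return self.artifact_count / self.n_frames > self.flag_fraction


def _prior_mask(prior, shape: tuple[int, int]) -> np.ndarray:
    if isinstance(prior, ROIBox):
        m = np.zeros(shape, dtype=bool)
        ys, xs = prior.as_slices()
        m[ys, xs] = True
        return m
    m = np.asarray(prior).astype(bool)
    if m.shape != shape:
        raise DimensionError(f"prior shape {m.shape} != mask shape {shape}")
    return m


def detect_artifacts(
    masks: MaskSequence | np.ndarray,
    prior: ROIBox | np.ndarray,
    min_component_px: int = 20,
    neighbor_k: int = 2,
    flag_fraction: float = 0.1,
) -> ArtifactReport:
    """Flag spurious and empty-while-open frames in a mask sequence.

    A frame is *spurious* when any 8-connected component of at least
    ``min_component_px`` pixels lies entirely outside the prior region.
    A frame is *empty* when its mask has no pixels while at least one frame
    within ``neighbor_k`` on each side is non-empty.
    """
    binm = masks.binarize() if isinstance(masks, MaskSequence) else np.asarray(
        masks
    ).astype(bool)
    T = binm.shape[0]
    prior_m = _prior_mask(prior, binm.shape[1:])
    structure = np.ones((3, 3), dtype=bool)

    nonempty = binm.any(axis=(1, 2))
    spurious = []
    for t in range(T):
        if not nonempty[t]:
            continue
        labels, n = ndimage.label(binm[t], structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        inside = np.bincount(labels.ravel(), weights=prior_m.ravel())[1:]
        if np.any((sizes >= min_component_px) & (inside == 0)):
            spurious.append(t)

    empty = []
    for t in range(T):
        if nonempty[t]:
            continue
        lo = nonempty[max(0, t - neighbor_k) : t].any()
        hi = nonempty[t + 1 : t + 1 + neighbor_k].any()
        if lo and hi:
            empty.append(t)

    return ArtifactReport(
        empty_frames=empty,
        spurious_frames=spurious,
        n_frames=T,
        flag_fraction=flag_fraction,
    )


def gaw_agreement(a: GAW | np.ndarray, b: GAW | np.ndarray) -> dict[str, float]:
    """Agreement between two glottal area waveforms.

    Returns Pearson r (NaN for constant inputs, with a warning), maximum
    absolute deviation, and RMSE.
    """
    av = a.areas if isinstance(a, GAW) else np.asarray(a)
    bv = b.areas if isinstance(b, GAW) else np.asarray(b)
    if av.shape != bv.shape:
        raise DimensionError(f"GAW lengths differ: {av.shape} vs {bv.shape}")
    av = av.astype(np.float64)
    bv = bv.astype(np.float64)
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        warnings.warn("constant GAW: Pearson correlation undefined", stacklevel=2)
        r = float("nan")
    else:
        r = float(pearsonr(av, bv).statistic)
    diff = av - bv
    return {
        "pearson_r": r,
        "max_abs_deviation": float(np.abs(diff).max()),
        "rmse": float(np.sqrt(np.mean(diff**2))),
    }


@dataclass
class EvalReport:
    """Per-frame metric bundle for one predicted vs ground-truth sequence."""

    iou_per_frame: np.ndarray
    boundary_iou_per_frame: np.ndarray
    dice_per_frame: np.ndarray
    pixel_accuracy_per_frame: np.ndarray
    artifacts: ArtifactReport | None
    gaw_stats: dict[str, float]

    @property
    def median_iou(self) -> float:
        return float(np.median(self.iou_per_frame))

    @property
    def mean_iou(self) -> float:
        return float(np.mean(self.iou_per_frame))

    @property
    def median_dice(self) -> float:
        return float(np.median(self.dice_per_frame))

    def summary(self) -> dict[str, float]:
        out = {
            "median_iou": self.median_iou,
            "mean_iou": self.mean_iou,
            "median_boundary_iou": float(np.median(self.boundary_iou_per_frame)),
            "median_dice": self.median_dice,
            "median_pixel_accuracy": float(
                np.median(self.pixel_accuracy_per_frame)
            ),
        }
        if self.artifacts is not None:
            out["artifact_count"] = float(self.artifacts.artifact_count)
        out.update({f"gaw_{k}": v for k, v in self.gaw_stats.items()})
        return out


def evaluate_masks(
    pred: MaskSequence | np.ndarray,
    truth: MaskSequence | np.ndarray,
    prior: ROIBox | np.ndarray | None = None,
    band_px: int = 2,
    **artifact_kwargs,
) -> EvalReport:
    """Full metric bundle between predicted and ground-truth sequences."""
    P = pred.binarize() if isinstance(pred, MaskSequence) else np.asarray(pred) > 0
    G = truth.binarize() if isinstance(truth, MaskSequence) else np.asarray(truth) > 0
    if P.shape != G.shape:
        raise DimensionError(f"shapes differ: {P.shape} vs {G.shape}")
    T = P.shape[0]
    ious = np.array([iou(G[t], P[t]) for t in range(T)])
    bious = np.array([boundary_iou(G[t], P[t], band_px) for t in range(T)])
    dices = np.array([dice(G[t], P[t]) for t in range(T)])
    accs = np.array([pixel_accuracy(G[t], P[t]) for t in range(T)])
    artifacts = (
        detect_artifacts(P, prior, **artifact_kwargs) if prior is not None else None
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gaw_stats = gaw_agreement(
            G.sum(axis=(1, 2)).astype(float), P.sum(axis=(1, 2)).astype(float)
        )
    return EvalReport(
        iou_per_frame=ious,
        boundary_iou_per_frame=bious,
        dice_per_frame=dices,
        pixel_accuracy_per_frame=accs,
        artifacts=artifacts,
        gaw_stats=gaw_stats,
    )
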