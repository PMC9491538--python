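"""Continual learning: batch scheduling, pseudo-label fine-tuning, evaluation.

New recordings arrive over months.  Two scheduling strategies bundle them
into continual-training batches: *fixed time* (every 7, 14 or 30 days) and
*fixed quantity* (every 10, 20 or 40 videos).  At each step the current
model's own predictions on the new batch serve as pseudo-label ground
truth; recordings whose predictions are artifact-flagged are excluded so
the model is fine-tuned only on artifact-free material.  Fine-tuning runs
for a small number of epochs at a low learning rate (defaults: 10 epochs,
Adam, 1e-6) and the model is evaluated on a frozen ground-truth eval set
after every step.

Each step trains only on its own batch — not cumulatively — which matches
a point-of-care deployment and deliberately exposes the scheme's
forgetting tendency; a cumulative mode is available behind a flag.
"""

from __future__ import annotations

import datetime as _dt
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .evaluation import ArtifactReport, EvalReport, detect_artifacts, evaluate_masks
from .phantom import PhantomRecording, default_prior
from .segmentation import SegModel, predict_masks, to_luminance, train_model
from .videoio import Recording, ROIBox

__all__ = [
    "ContinualStrategy",
    "FineTuneConfig",
    "Schedule",
    "ContinualRunResult",
    "make_schedule",
    "pseudo_label_batch",
    "continual_step",
    "run_experiment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContinualStrategy:
    """Batch scheduling policy.

    ``fixed_time`` groups recordings into consecutive calendar windows of
    ``period_days`` (typically 7, 14 or 30) anchored at the earliest date;
    ``fixed_quantity`` takes consecutive chunks of exactly ``batch_size``
    recordings (typically 10, 20 or 40) in date order.
    """

    kind: str
    period_days: int | None = None
    batch_size: int | None = None

    def __post_init__(self):
        if self.kind not in ("fixed_time", "fixed_quantity"):
            raise ConfigurationError(
                f"kind must be 'fixed_time' or 'fixed_quantity', got {self.kind!r}"
            )
        if self.kind == "fixed_time":
            if not self.period_days or self.period_days <= 0 or self.batch_size:
                raise ConfigurationError(
                    "fixed_time needs a positive period_days and no batch_size"
                )
        else:
            if not self.batch_size or self.batch_size <= 0 or self.period_days:
                raise ConfigurationError(
                    "fixed_quantity needs a positive batch_size and no period_days"
                )

    @classmethod
    def parse(cls, text: str) -> "ContinualStrategy":
        """Parse 'time:7' or 'quantity:10' style strings."""
        try:
            key, val = text.split(":")
            val = int(val)
        except ValueError as exc:
            raise ConfigurationError(
                f"cannot parse strategy {text!r}; expected 'time:N' or 'quantity:N'"
            ) from exc
        if key == "time":
            return cls(kind="fixed_time", period_days=val)
        if key == "quantity":
            return cls(kind="fixed_quantity", batch_size=val)
        raise ConfigurationError(f"unknown strategy kind {key!r}")


@dataclass(frozen=True)
class FineTuneConfig:
    """Continual fine-tuning hyperparameters (defaults: 10 epochs, Adam 1e-6)."""

    epochs: int = 10
    learning_rate: float = 1e-6
    seed: int = 0
    batch_size: int = 8

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ConfigurationError("learning_rate must be >= 0")


def _date_of(item) -> _dt.date:
    if isinstance(item, PhantomRecording):
        return item.rec.date
    d = getattr(item, "date", None)
    if d is None:
        raise ConfigurationError(f"item {item!r} carries no acquisition date")
    return d


@dataclass
class Schedule:
    """Ordered batches plus the trailing remainder that is not yet a batch."""

    batches: list[list]
    pending: list

    def __iter__(self):
        return iter(self.batches)

    def __len__(self):
        return len(self.batches)


def make_schedule(items, strategy: ContinualStrategy) -> Schedule:
    """Group date-carrying recordings into continual-training batches.

    Items are sorted by date (stable).  Fixed-quantity: consecutive chunks
    of exactly ``batch_size``; the trailing remainder is held pending.
    Fixed-time: consecutive ``period_days`` windows anchored at the
    earliest date; empty windows are skipped with a logged notice.
    """
    items = sorted(items, key=_date_of)
    if not items:
        return Schedule(batches=[], pending=[])
    if strategy.kind == "fixed_quantity":
        bs = strategy.batch_size
        n_full = len(items) // bs
        batches = [items[i * bs : (i + 1) * bs] for i in range(n_full)]
        return Schedule(batches=batches, pending=items[n_full * bs :])
    # fixed_time
    start = _date_of(items[0])
    end = _date_of(items[-1])
    period = _dt.timedelta(days=strategy.period_days)
    batches = []
    w0 = start
    idx = 0
    while w0 <= end:
        w1 = w0 + period
        batch = []
        while idx < len(items) and w0 <= _date_of(items[idx]) < w1:
            batch.append(items[idx])
            idx += 1
        if batch:
            batches.append(batch)
        else:
            logger.info("fixed_time window %s .. %s is empty; skipped", w0, w1)
        w0 = w1
    return Schedule(batches=batches, pending=[])


def _rec_of(item) -> Recording:
    return item.rec if isinstance(item, PhantomRecording) else item


def pseudo_label_batch(
    model: SegModel,
    batch: list,
    artifact_filter: bool = True,
    prior: ROIBox | np.ndarray | None = None,
    threshold: float = 0.5,
    max_frames_per_recording: int | None = None,
    min_component_px: int = 20,
    flag_fraction: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Predict masks over a batch and turn them into training pairs.

    Runs full-frame inference on each recording; when ``artifact_filter``
    is on, recordings whose :class:`ArtifactReport` raises ``video_flag``
    contribute nothing.  Pseudo-labels are binarized at ``threshold``.
    Returns ``(frames, masks, excluded_names)`` where frames are 8-bit
    luminance of shape (N,H,W) and masks are boolean.  An empty result is
    returned with a warning when the batch is empty or fully filtered.
    """
    if not batch:
        warnings.warn("empty batch: no pseudo-label pairs produced", stacklevel=2)
        return np.empty((0, 0, 0), np.uint8), np.empty((0, 0, 0), bool), []
    if artifact_filter and prior is None:
        # Derive a prior from the first phantom item when possible.
        first = batch[0]
        if isinstance(first, PhantomRecording):
            prior = default_prior(first.spec)
        else:
            raise ConfigurationError(
                "artifact_filter requires a prior region for non-phantom batches"
            )
    frames_out, masks_out, excluded = [], [], []
    for item in batch:
        rec = _rec_of(item)
        ms = predict_masks(model, rec, threshold=threshold)
        if artifact_filter:
            report = detect_artifacts(
                ms,
                prior,
                min_component_px=min_component_px,
                flag_fraction=flag_fraction,
            )
            if report.video_flag:
                excluded.append(rec.name or "<unnamed>")
                logger.info(
                    "excluded %s from continual training: %d/%d artifact frames",
                    rec.name,
                    report.artifact_count,
                    report.n_frames,
                )
                continue
        lum = np.stack([to_luminance(f) for f in rec.frames])
        binm = ms.binarize()
        if max_frames_per_recording is not None and len(lum) > max_frames_per_recording:
            step = len(lum) / max_frames_per_recording
            sel = (np.arange(max_frames_per_recording) * step).astype(int)
            lum, binm = lum[sel], binm[sel]
        frames_out.append(lum)
        masks_out.append(binm)
    if not frames_out:
        warnings.warn(
            "all recordings in the batch were artifact-flagged; empty pair set",
            stacklevel=2,
        )
        return np.empty((0, 0, 0), np.uint8), np.empty((0, 0, 0), bool), excluded
    return np.concatenate(frames_out), np.concatenate(masks_out), excluded


def continual_step(
    model: SegModel, pairs: tuple[np.ndarray, np.ndarray], config: FineTuneConfig
) -> SegModel:
    """One fine-tuning step on pseudo-label pairs; no-op on empty input."""
    frames, masks = pairs[0], pairs[1]
    if frames.size == 0:
        warnings.warn("no training pairs: model returned unchanged", stacklevel=2)
        return model
    return train_model(
        model,
        frames,
        masks,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        seed=config.seed,
        batch_size=config.batch_size,
    )


@dataclass
class ContinualRunResult:
    """Per-step evaluation of a continual-learning run.

    ``baseline_report`` is the frozen eval set scored before any step;
    ``step_reports`` has one entry per executed (non-empty) batch.
    """

    baseline_report: EvalReport
    step_reports: list[EvalReport]
    excluded_per_step: list[list[str]]
    final_model: SegModel
    checkpoints: list[SegModel] = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return len(self.step_reports)


def _evaluate_set(
    model: SegModel,
    eval_set: list[PhantomRecording],
    prior,
    threshold: float,
    max_eval_frames: int | None,
) -> EvalReport:
    """Score the eval set: frame metrics pooled, artifacts per recording.

    Artifact detection runs within each recording separately — the
    empty-while-open temporal rule must not look across recording
    boundaries — and the flag lists are merged with pooled frame indices.
    """
    preds, truths = [], []
    empty_frames: list[int] = []
    spurious_frames: list[int] = []
    offset = 0
    for pr in eval_set:
        ms = predict_masks(model, pr.rec, threshold=threshold)
        binm = ms.binarize()
        gt = pr.gt_masks
        if max_eval_frames is not None:
            binm, gt = binm[:max_eval_frames], gt[:max_eval_frames]
        if prior is not None:
            rep = detect_artifacts(binm, prior)
            empty_frames += [offset + t for t in rep.empty_frames]
            spurious_frames += [offset + t for t in rep.spurious_frames]
        offset += binm.shape[0]
        preds.append(binm)
        truths.append(gt)
    pooled = evaluate_masks(np.concatenate(preds), np.concatenate(truths))
    if prior is not None:
        pooled.artifacts = ArtifactReport(
            empty_frames=empty_frames,
            spurious_frames=spurious_frames,
            n_frames=offset,
            flag_fraction=0.1,
        )
    return pooled


def run_experiment(
    cohort: list[PhantomRecording],
    strategy: ContinualStrategy,
    config: FineTuneConfig,
    eval_set: list[PhantomRecording],
    model: SegModel,
    prior: ROIBox | np.ndarray | None = None,
    artifact_filter: bool = True,
    threshold: float = 0.5,
    flag_fraction: float = 0.1,
    min_component_px: int = 20,
    max_frames_per_recording: int | None = None,
    max_eval_frames: int | None = None,
    cumulative: bool = False,
    keep_checkpoints: bool = False,
    max_steps: int | None = None,
) -> ContinualRunResult:
    """Run the full continual-learning loop from a baseline model.

    Iterates schedule → pseudo-labels → fine-tune, scoring the frozen
    ``eval_set`` (which must be disjoint from the cohort by recording
    name) after every step.  The input ``model`` is copied; the baseline
    is never mutated.  ``max_eval_frames`` restricts scoring to the first
    frames of each eval recording (the eval-set size is a parameter, not a
    constant); ``max_steps`` truncates the schedule after that many
    batches, for budgeted desk-scale runs.
    """
    cohort_names = {pr.rec.name for pr in cohort}
    eval_names = {pr.rec.name for pr in eval_set}
    overlap = cohort_names & eval_names
    if overlap:
        raise ConfigurationError(
            f"eval set overlaps the training cohort: {sorted(overlap)}"
        )
    if prior is None and eval_set:
        prior = default_prior(eval_set[0].spec)

    current = model.copy()
    schedule = make_schedule(cohort, strategy)
    baseline_report = _evaluate_set(
        current, eval_set, prior, threshold, max_eval_frames
    )
    step_reports: list[EvalReport] = []
    excluded_per_step: list[list[str]] = []
    checkpoints: list[SegModel] = []
    seen: list[PhantomRecording] = []
    batches = schedule.batches
    if max_steps is not None:
        batches = batches[:max_steps]
    for i, batch in enumerate(batches):
        seen.extend(batch)
        train_items = seen if cumulative else batch
        frames, masks, excluded = pseudo_label_batch(
            current,
            train_items,
            artifact_filter=artifact_filter,
            prior=prior,
            threshold=threshold,
            flag_fraction=flag_fraction,
            min_component_px=min_component_px,
            max_frames_per_recording=max_frames_per_recording,
        )
        step_cfg = FineTuneConfig(
            epochs=config.epochs,
            learning_rate=config.learning_rate,
            seed=config.seed + i,
            batch_size=config.batch_size,
        )
        current = continual_step(current, (frames, masks), step_cfg)
        step_reports.append(
            _evaluate_set(current, eval_set, prior, threshold, max_eval_frames)
        )
        excluded_per_step.append(excluded)
        if keep_checkpoints:
            checkpoints.append(current.copy())
    return ContinualRunResult(
        baseline_report=baseline_report,
        step_reports=step_reports,
        excluded_per_step=excluded_per_step,
        final_model=current,
        checkpoints=checkpoints,
    )
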