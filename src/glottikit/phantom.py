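"""Synthetic laryngeal high-speed-video phantom with ground truth.

Real laryngeal high-speed videoendoscopy shows the two vocal folds opening
and closing hundreds of times per second inside a circular endoscopic field.
The phantom emulates the features that matter for segmentation assessment:

* an oscillating glottal opening, modelled as a vertically elongated dark
  ellipse whose area follows a clamped sinusoid (open and closed phases,
  controlled by an open quotient);
* a tissue-textured pinkish background inside a circular vignette with
  black corners;
* manual quality tiers — 2 (excellent, clean), 1 (okay, blur + noise),
  0 (insufficient, heavy fog and an occlusion over the glottis);
* acquisition dates spread over months, for scheduling experiments;
* injectable domain shift (illumination tint, brightness shift, or dark
  elongated distractor patches) that provokes segmentation artifacts while
  leaving the ground-truth masks untouched.

Every output is bitwise reproducible from ``(spec, seed)``.  The ground
truth GAW is always the *rasterized* mask pixel count, never the analytic
ellipse area, so that downstream pixel-summation GAW extraction reproduces
it exactly.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from math import cos, pi

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import AliasingError, ConfigurationError
from .videoio import Recording, ROIBox

__all__ = [
    "PhantomSpec",
    "DomainShift",
    "PhantomRecording",
    "CohortEntry",
    "gaw_profile",
    "render_frame",
    "generate_recording",
    "inject_shift",
    "sample_cohort",
    "generate_cohort",
    "default_prior",
]

SHIFT_KINDS = ("illumination_tint", "brightness_shift", "distractor_patches")


@dataclass(frozen=True)
class DomainShift:
    """A controlled appearance change applied to rendered frames only.

    ``magnitude = 0`` reproduces the unshifted phantom exactly.  Ground
    truth masks are never affected: distractor patches are drawn into the
    image but remain background in the masks, which is precisely what makes
    them provoke spurious segmentations.
    """

    kind: str
    magnitude: float = 1.0
    n_patches: int = 3

    def __post_init__(self):
        if self.kind not in SHIFT_KINDS:
            raise ConfigurationError(
                f"unknown shift kind {self.kind!r}; expected one of {SHIFT_KINDS}"
            )
        if not 0.0 <= self.magnitude <= 1.0:
            raise ConfigurationError("shift magnitude must lie in [0, 1]")
        if self.n_patches < 0:
            raise ConfigurationError("n_patches must be non-negative")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic recording.

    Defaults follow the acquisition regime of clinical high-speed
    videoendoscopy (nominal 4,000 fps, ≥1,000 frames, fundamental frequency
    in the phonation range) at a desk-scale 128x128 frame size.
    """

    H: int = 128
    W: int = 128
    T: int = 1000
    fps: float = 4000.0
    f0: float = 250.0  # Hz; one glottal cycle every fps/f0 frames
    A_peak: float = 600.0  # pixels^2
    open_quotient: float = 0.6
    axis_a: float = 20.0  # glottis half-length, pixels
    center: tuple[float, float] | None = None  # (row, col); default mid-frame
    noise_sigma: float = 0.0
    tier: int = 2
    shift: DomainShift | None = None
    seed: int = 0

    def __post_init__(self):
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if not 0 < self.f0 < self.fps / 2:
            raise AliasingError(
                f"f0={self.f0} Hz must satisfy 0 < f0 < fps/2 = {self.fps / 2} Hz"
            )
        if not 0 < self.open_quotient <= 1:
            raise ValueError("open_quotient must lie in (0, 1]")
        if self.A_peak > pi * self.axis_a * (self.W / 4):
            raise ValueError(
                "A_peak too large for the frame: peak half-width would exceed W/4"
            )
        if self.tier not in (0, 1, 2):
            raise ValueError("tier must be 0, 1 or 2")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    @property
    def center_rc(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return (self.H / 2.0, self.W / 2.0)


@dataclass
class PhantomRecording:
    """A synthetic recording bundled with its ground truth.

    ``gt_gaw[t]`` is exactly the pixel count of ``gt_masks[t]``.
    """

    rec: Recording
    gt_masks: np.ndarray  # (T, H, W) bool
    gt_gaw: np.ndarray  # (T,) int64, pixels^2
    spec: PhantomSpec

    @property
    def name(self) -> str | None:
        return self.rec.name


def gaw_profile(spec: PhantomSpec) -> np.ndarray:
    """Analytic glottal-area waveform of the phantom, in pixels².

    A(t) = A_peak · max(0, (sin(2π f0 t / fps) − c) / (1 − c)) with
    c = cos(π · open_quotient), so the glottis is open for exactly the
    requested fraction of every cycle and the waveform is periodic with
    period fps/f0 frames.
    """
    if spec.f0 >= spec.fps / 2:  # defensive; the spec constructor also checks
        raise AliasingError("f0 must be below the Nyquist frequency fps/2")
    c = cos(pi * spec.open_quotient)
    t = np.arange(spec.T, dtype=np.float64)
    s = np.sin(2 * pi * spec.f0 * t / spec.fps)
    return spec.A_peak * np.maximum(0.0, (s - c) / (1.0 - c))


class _Scene:
    """Per-recording static content: background, vignette, distractors."""

    def __init__(self, spec: PhantomSpec):
        H, W = spec.H, spec.W
        rng = np.random.default_rng(spec.seed)
        # Tissue texture: smooth low-frequency random field on a pink base.
        field_ = gaussian_filter(rng.standard_normal((H, W)), sigma=max(2, H // 16))
        field_ = (field_ - field_.min()) / (np.ptp(field_) + 1e-12)
        base = np.array([185.0, 115.0, 105.0])
        var = np.array([45.0, 35.0, 30.0])
        bg = base[None, None, :] + (field_[..., None] - 0.5) * 2 * var[None, None, :]
        # Fine speckle so the texture is not band-limited.
        bg = bg + rng.normal(0.0, 3.0, size=(H, W, 3))
        yy, xx = np.mgrid[0:H, 0:W]
        self.yy, self.xx = yy, xx
        # Faint vascular shadows: every larynx shows thin dark-red vessel
        # structures away from the glottal midline.  They are part of the
        # normal scene (weaker and redder than drift distractors), so a
        # segmenter trained on clean phantoms must already discriminate
        # "dark elongated off-center" from the glottis.
        vrng = np.random.default_rng((spec.seed * 40503 + 7) % (2**31))
        gcy, gcx = spec.center_rc
        vessel_color = np.array([95.0, 40.0, 42.0])
        placed = 0
        attempts = 0
        while placed < 2 and attempts < 100:
            attempts += 1
            py = vrng.uniform(0.15 * H, 0.85 * H)
            px = vrng.uniform(0.15 * W, 0.85 * W)
            # reject positions overlapping the glottis zone; tiny frames may
            # have no admissible spot, in which case vessels are skipped
            if (
                abs(py - gcy) < spec.axis_a + 8
                and abs(px - gcx) < spec.A_peak / (pi * spec.axis_a) + 8
            ):
                continue
            pa = vrng.uniform(7, 14)
            pb = vrng.uniform(1.5, 3.0)
            ang = vrng.uniform(0, pi)
            dy, dx = yy - py, xx - px
            u = dy * np.cos(ang) + dx * np.sin(ang)
            v = -dy * np.sin(ang) + dx * np.cos(ang)
            inside = (u / pa) ** 2 + (v / pb) ** 2 <= 1.0
            strength = vrng.uniform(0.35, 0.55)
            bg[inside] = (1 - strength) * bg[inside] + strength * vessel_color
            placed += 1
        # Circular endoscopic vignette with a soft rim; corners go black.
        cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
        r = np.hypot(yy - cy, xx - cx)
        radius = 0.48 * min(H, W)
        vign = np.clip((radius - r) / (0.06 * min(H, W)) + 1.0, 0.0, 1.0)
        self.background = np.clip(bg * vign[..., None], 0, 255)
        self.vignette = vign

        # Distractor patches: static dark elongated ellipses placed outside
        # the true glottis, drawn from an independent stream so that the
        # per-frame noise stream is identical with and without the shift.
        self.distractors: list[tuple[float, float, float, float, float]] = []
        shift = spec.shift
        if (
            shift is not None
            and shift.kind == "distractor_patches"
            and shift.magnitude > 0
            and shift.n_patches > 0
        ):
            drng = np.random.default_rng((spec.seed * 2654435761 + 97) % (2**31))
            gcy, gcx = spec.center_rc
            placed = 0
            attempts = 0
            while placed < shift.n_patches and attempts < 100 * (shift.n_patches + 1):
                attempts += 1
                py = drng.uniform(0.15 * H, 0.85 * H)
                px = drng.uniform(0.15 * W, 0.85 * W)
                # keep clear of the glottis ellipse (with jitter margin)
                if (
                    abs(py - gcy) < spec.axis_a + 8
                    and abs(px - gcx) < spec.A_peak / (pi * spec.axis_a) + 8
                ):
                    continue
                pa = drng.uniform(6, 12)  # half-length
                pb = drng.uniform(1.5, 3.5)  # half-width
                ang = drng.uniform(0, pi)
                self.distractors.append((py, px, pa, pb, ang))
                placed += 1

    def draw_distractors(self, frame: np.ndarray, magnitude: float) -> None:
        for py, px, pa, pb, ang in self.distractors:
            dy = self.yy - py
            dx = self.xx - px
            u = dy * np.cos(ang) + dx * np.sin(ang)
            v = -dy * np.sin(ang) + dx * np.cos(ang)
            inside = (u / pa) ** 2 + (v / pb) ** 2 <= 1.0
            inside &= self.vignette > 0
            # Darken toward glottis-like near-black tissue shadow.
            dark = np.array([28.0, 12.0, 14.0])
            frame[inside] = (
                (1 - magnitude) * frame[inside] + magnitude * dark[None, :]
            )


def _ellipse_mask(
    yy: np.ndarray, xx: np.ndarray, cy: float, cx: float, a: float, b: float
) -> np.ndarray:
    if a <= 0 or b <= 0:
        return np.zeros(yy.shape, dtype=bool)
    return ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0


def render_frame(
    spec: PhantomSpec,
    area: float,
    rng: np.random.Generator,
    scene: _Scene | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one frame and its binary ground-truth mask.

    The glottis is a filled vertical ellipse of half-length ``axis_a`` and
    half-width ``b = area / (π axis_a)`` at the spec center with seeded
    jitter of at most 2 px.  Tier 1 adds blur and noise; tier 0 adds heavy
    fog and an occlusion over the glottis.  Domain shift is applied to the
    image only — the returned mask is always the unshifted glottis.
    """
    if not 0 <= area <= spec.A_peak + 1e-9:
        raise ValueError(f"area {area} outside [0, A_peak={spec.A_peak}]")
    if scene is None:
        scene = _Scene(spec)
    H, W = spec.H, spec.W
    frame = scene.background.copy()

    # Per-frame jitter consumed from the streaming rng even when closed,
    # so frame-to-frame rng alignment does not depend on the waveform.
    jit = rng.uniform(-2.0, 2.0, size=2)
    cy, cx = spec.center_rc
    cy, cx = cy + jit[0], cx + jit[1]

    b = area / (pi * spec.axis_a)
    mask = _ellipse_mask(scene.yy, scene.xx, cy, cx, spec.axis_a, b)
    if area <= 0:
        mask = np.zeros((H, W), dtype=bool)
    if mask.any():
        # Dark glottal gap with a slight soft edge for realism.
        dark = np.array([25.0, 10.0, 12.0])
        frame[mask] = dark[None, :]

    shift = spec.shift
    if shift is not None and shift.kind == "distractor_patches":
        scene.draw_distractors(frame, shift.magnitude)

    if spec.tier == 1:
        frame = gaussian_filter(frame, sigma=(1.0, 1.0, 0))
        frame = frame + rng.normal(0.0, 6.0, size=frame.shape)
    elif spec.tier == 0:
        frame = gaussian_filter(frame, sigma=(2.0, 2.0, 0))
        fog = np.array([160.0, 150.0, 150.0])
        frame = 0.45 * frame + 0.55 * fog[None, None, :]
        occ = _ellipse_mask(
            scene.yy, scene.xx, cy, cx, spec.axis_a * 1.8, spec.axis_a * 1.2
        )
        frame[occ] = 0.25 * frame[occ] + 0.75 * fog[None, :]
        frame = frame + rng.normal(0.0, 8.0, size=frame.shape)

    if spec.noise_sigma > 0:
        frame = frame + rng.normal(0.0, spec.noise_sigma, size=frame.shape)

    if shift is not None and shift.magnitude > 0:
        if shift.kind == "brightness_shift":
            frame = frame + 80.0 * shift.magnitude
        elif shift.kind == "illumination_tint":
            tint = 1.0 + shift.magnitude * np.array([0.25, -0.12, -0.18])
            frame = frame * tint[None, None, :]

    frame = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
    return frame, mask


def generate_recording(spec: PhantomSpec) -> PhantomRecording:
    """Render a full phantom recording along the analytic GAW profile.

    The stored ground-truth GAW is recomputed as each rasterized mask's
    pixel count; the analytic profile only drives the requested areas.
    Deterministic per ``spec.seed``.
    """
    profile = gaw_profile(spec)
    scene = _Scene(spec)
    rng = np.random.default_rng(spec.seed + 1)
    frames = np.empty((spec.T, spec.H, spec.W, 3), dtype=np.uint8)
    masks = np.empty((spec.T, spec.H, spec.W), dtype=bool)
    for t in range(spec.T):
        frames[t], masks[t] = render_frame(spec, float(profile[t]), rng, scene)
    gaw = masks.sum(axis=(1, 2)).astype(np.int64)
    rec = Recording(
        frames=frames,
        fps=spec.fps,
        date=None,
        mode="raw",
        quality_tier=spec.tier,
        name=f"phantom-{spec.seed}",
    )
    return PhantomRecording(rec=rec, gt_masks=masks, gt_gaw=gaw, spec=spec)


def inject_shift(spec: PhantomSpec, shift: DomainShift) -> PhantomSpec:
    """Return a copy of ``spec`` carrying the given domain shift."""
    if not isinstance(shift, DomainShift):
        raise ConfigurationError("shift must be a DomainShift")
    return replace(spec, shift=shift)


def default_prior(spec: PhantomSpec, margin: float = 8.0) -> ROIBox:
    """Box where the glottis may legitimately appear for this phantom.

    Covers the ellipse at peak area plus jitter and ``margin`` pixels.
    Used as the prior region for artifact detection.
    """
    cy, cx = spec.center_rc
    b_max = spec.A_peak / (pi * spec.axis_a)
    half_h = spec.axis_a + 2 + margin
    half_w = b_max + 2 + margin
    y0 = max(0, int(np.floor(cy - half_h)))
    x0 = max(0, int(np.floor(cx - half_w)))
    y1 = min(spec.H, int(np.ceil(cy + half_h)))
    x1 = min(spec.W, int(np.ceil(cx + half_w)))
    return ROIBox(x0=x0, y0=y0, width=x1 - x0, height=y1 - y0)


@dataclass(frozen=True)
class CohortEntry:
    """Lightweight cohort manifest row: a spec plus an acquisition date."""

    recording_id: str
    date: _dt.date
    spec: PhantomSpec


def sample_cohort(
    n: int,
    date_range: tuple[_dt.date, _dt.date],
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    f0_range: tuple[float, float] = (180.0, 320.0),
    tier_probs: tuple[float, float, float] = (0.0, 0.2, 0.8),
    shift: DomainShift | None = None,
    shift_magnitude_range: tuple[float, float] | None = None,
) -> list[CohortEntry]:
    """Sample ``n`` cohort manifest entries with dates over ``date_range``.

    Dates are drawn non-uniformly (a mild clustering toward the start of
    the range, mimicking an irregular patient stream) and returned sorted.
    Per-recording f0 and tier are sampled; everything is reproducible per
    ``seed``.  Rendering is deferred to :func:`generate_cohort`.

    When both ``shift`` and ``shift_magnitude_range`` are given, each
    recording draws its own shift magnitude uniformly from the range —
    a gradual-onset drift in which the confusing appearance change varies
    in strength across the patient stream.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    start, end = date_range
    span = (end - start).days
    if span < 0 or (span == 0 and n > 0):
        raise ConfigurationError("date_range must span at least one day")
    rng = np.random.default_rng(seed)
    base = base_spec if base_spec is not None else PhantomSpec()
    # Beta(1.2, 1.6) skews acquisition mildly toward the early period.
    offsets = np.sort(np.floor(rng.beta(1.2, 1.6, size=n) * (span + 1)).astype(int))
    offsets = np.clip(offsets, 0, span)
    tiers = rng.choice([0, 1, 2], size=n, p=np.asarray(tier_probs) / sum(tier_probs))
    entries = []
    for i in range(n):
        f0 = float(rng.uniform(*f0_range))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        rec_shift = shift
        if shift is not None and shift_magnitude_range is not None:
            rec_shift = replace(
                shift, magnitude=float(rng.uniform(*shift_magnitude_range))
            )
        spec = replace(
            base, f0=f0, tier=int(tiers[i]), seed=sub_seed, shift=rec_shift
        )
        entries.append(
            CohortEntry(
                recording_id=f"rec-{seed:04d}-{i:03d}",
                date=start + _dt.timedelta(days=int(offsets[i])),
                spec=spec,
            )
        )
    return entries


def generate_cohort(
    n: int,
    date_range: tuple[_dt.date, _dt.date],
    seed: int = 0,
    **kwargs,
) -> list[PhantomRecording]:
    """Render a full cohort of phantom recordings with acquisition dates."""
    out = []
    for entry in sample_cohort(n, date_range, seed=seed, **kwargs):
        pr = generate_recording(entry.spec)
        pr.rec.date = entry.date
        pr.rec.name = entry.recording_id
        out.append(pr)
    return out
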