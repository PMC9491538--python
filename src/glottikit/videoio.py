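"""Recording storage in two compression dialects plus ROI sidecar I/O.

Laryngeal high-speed recordings are archived twice: a *lossless* copy that
recovers the raw sensor frames bit-exactly, and a much smaller *lossy* copy
used for routine viewing and downstream segmentation.  Here both dialects
live in a frame-packed ZIP container: one image file per frame plus a JSON
manifest carrying frame rate, acquisition date, quality tier and the exact
encoder settings.  The lossless dialect stores PNG (RGB, bit-exact); the
lossy dialect stores JPEG with 4:2:0 chroma subsampling, which is why it
requires even frame dimensions, and exposes a single integer ``quality``
knob on a variable-bitrate-style scale (1 best … 31 worst, default 5).  The
knob-to-JPEG-quality mapping is recorded in the manifest so a given file is
reproducible from its own metadata.

ROI sidecars are plain JSON objects ``{"x0", "y0", "width", "height"}``
with 0-based, half-open pixel coordinates (x rightward, y downward).
"""

from __future__ import annotations

import datetime as _dt
import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image as _PILImage

from .errors import DimensionError, FormatError, ParseError

__all__ = [
    "Recording",
    "ROIBox",
    "encode_recording",
    "decode_recording",
    "lossy_roundtrip",
    "save_roi",
    "load_roi",
    "quality_to_jpeg_quality",
]

_MAGIC = "glottikit-framepack"
_VERSION = 1

MODES = ("lossy", "lossless", "raw")


@dataclass
class Recording:
    """A stack of color video frames with acquisition metadata.

    frames : uint8 array of shape (T, H, W, 3)
    fps : nominal frame rate (high-speed endoscopy runs at ~4,000 fps)
    date : acquisition date (may be None for synthetic material)
    mode : storage provenance, one of {"lossy", "lossless", "raw"}
    quality_tier : manual quality rating, 0 (insufficient) / 1 (okay) /
        2 (excellent)
    name : optional stable identifier (used for cohort bookkeeping)
    """

    frames: np.ndarray
    fps: float = 4000.0
    date: _dt.date | None = None
    mode: str = "raw"
    quality_tier: int = 2
    name: str | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise DimensionError(
                f"frames must have shape (T, H, W, 3), got {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise DimensionError("a recording needs at least one frame")
        if self.frames.dtype != np.uint8:
            if self.frames.min() < 0 or self.frames.max() > 255:
                raise ValueError("frame intensities must lie in [0, 255]")
            self.frames = self.frames.astype(np.uint8)
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.quality_tier not in (0, 1, 2):
            raise ValueError(f"quality_tier must be 0, 1 or 2, got {self.quality_tier}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class ROIBox:
    """Rectangular region of interest, 0-based and half-open.

    Pixel columns covered are ``x0 … x0 + width - 1`` and likewise for rows.
    """

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self):
        for key in ("x0", "y0", "width", "height"):
            v = getattr(self, key)
            if int(v) != v:
                raise ValueError(f"ROI field {key} must be an integer, got {v!r}")
            setattr(self, key, int(v))
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI corner must be non-negative")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("ROI width and height must be positive")

    @property
    def x1(self) -> int:
        return self.x0 + self.width

    @property
    def y1(self) -> int:
        return self.y0 + self.height

    def as_slices(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y1), slice(self.x0, self.x1)


def quality_to_jpeg_quality(quality: int) -> int:
    """Map the variable-bitrate quality knob (1 best … 31 worst) to a JPEG
    quality factor.  Linear map pinned at knob 1 → 98 and knob 31 → 8."""
    if not 1 <= quality <= 31:
        raise ValueError(f"quality must be in [1, 31], got {quality}")
    return int(round(98 - (quality - 1) * 3.0))


def _encode_frame(frame: np.ndarray, codec: str, jpeg_quality: int) -> bytes:
    img = _PILImage.fromarray(frame, mode="RGB")
    buf = io.BytesIO()
    if codec == "png":
        img.save(buf, format="PNG", optimize=False, compress_level=6)
    else:
        img.save(buf, format="JPEG", quality=jpeg_quality, subsampling=2)
    return buf.getvalue()


def encode_recording(
    rec: Recording,
    mode: str,
    path: str | Path,
    quality: int = 5,
) -> Path:
    """Write a recording to ``path`` in the requested compression dialect.

    ``mode="lossless"`` stores PNG frames and round-trips bit-exactly;
    ``mode="lossy"`` stores chroma-subsampled JPEG frames (H and W must be
    even) and produces far smaller files for non-constant content.  Returns
    the written path.
    """
    if mode not in ("lossy", "lossless"):
        raise ValueError(f"mode must be 'lossy' or 'lossless', got {mode!r}")
    T, H, W = rec.n_frames, *rec.frame_shape
    if mode == "lossy" and (H % 2 or W % 2):
        raise DimensionError(
            f"lossy dialect uses 4:2:0 chroma subsampling and needs even "
            f"frame dimensions, got {H}x{W}"
        )
    codec = "png" if mode == "lossless" else "jpeg"
    jpeg_q = quality_to_jpeg_quality(quality)
    manifest = {
        "format": _MAGIC,
        "version": _VERSION,
        "mode": mode,
        "codec": codec,
        "n_frames": T,
        "height": H,
        "width": W,
        "fps": rec.fps,
        "date": rec.date.isoformat() if rec.date is not None else None,
        "quality_tier": rec.quality_tier,
        "name": rec.name,
        "encoder_settings": (
            {"pixel_format": "rgb24", "compress_level": 6}
            if codec == "png"
            else {
                "pixel_format_analog": "yuv420p",
                "quality_knob": quality,
                "jpeg_quality": jpeg_q,
                "subsampling": "4:2:0",
            }
        ),
    }
    path = Path(path)
    ext = ".png" if codec == "png" else ".jpg"
    try:
        with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
            zf.writestr("manifest.json", json.dumps(manifest, indent=1))
            for t in range(T):
                zf.writestr(
                    f"frames/{t:06d}{ext}",
                    _encode_frame(rec.frames[t], codec, jpeg_q),
                )
    except OSError as exc:
        raise OSError(f"cannot write recording to {path}: {exc}") from exc
    return path


def decode_recording(path: str | Path) -> Recording:
    """Read a recording container written by :func:`encode_recording`.

    Frame count and dimensions are recovered from the manifest; ``mode`` is
    inferred from the stored encoder metadata.  Raises :class:`FormatError`
    for corrupt, truncated or foreign files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with zipfile.ZipFile(path) as zf:
            try:
                manifest = json.loads(zf.read("manifest.json"))
            except KeyError as exc:
                raise FormatError(f"{path}: missing manifest.json") from exc
            if manifest.get("format") != _MAGIC:
                raise FormatError(f"{path}: not a {_MAGIC} container")
            T = manifest["n_frames"]
            ext = ".png" if manifest["codec"] == "png" else ".jpg"
            frames = np.empty(
                (T, manifest["height"], manifest["width"], 3), dtype=np.uint8
            )
            for t in range(T):
                raw = zf.read(f"frames/{t:06d}{ext}")
                img = _PILImage.open(io.BytesIO(raw))
                frames[t] = np.asarray(img.convert("RGB"), dtype=np.uint8)
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError, OSError) as exc:
        if isinstance(exc, FileNotFoundError):
            raise
        raise FormatError(f"{path}: corrupt or unsupported container ({exc})") from exc
    date = manifest.get("date")
    return Recording(
        frames=frames,
        fps=float(manifest.get("fps", 4000.0)),
        date=_dt.date.fromisoformat(date) if date else None,
        mode=manifest["mode"],
        quality_tier=int(manifest.get("quality_tier", 2)),
        name=manifest.get("name"),
    )


def lossy_roundtrip(rec: Recording, quality: int = 5) -> Recording:
    """In-memory lossy encode→decode of a recording.

    Produces the pixel content a consumer of the lossy dialect would see,
    without touching the filesystem.  Frame dimensions must be even (4:2:0
    chroma subsampling).
    """
    H, W = rec.frame_shape
    if H % 2 or W % 2:
        raise DimensionError(
            f"lossy dialect needs even frame dimensions, got {H}x{W}"
        )
    jq = quality_to_jpeg_quality(quality)
    frames = np.empty_like(rec.frames)
    for t in range(rec.n_frames):
        raw = _encode_frame(rec.frames[t], "jpeg", jq)
        frames[t] = np.asarray(
            _PILImage.open(io.BytesIO(raw)).convert("RGB"), dtype=np.uint8
        )
    return Recording(
        frames=frames,
        fps=rec.fps,
        date=rec.date,
        mode="lossy",
        quality_tier=rec.quality_tier,
        name=rec.name,
    )


_ROI_KEYS = ("x0", "y0", "width", "height")


def save_roi(roi: ROIBox, path: str | Path) -> Path:
    """Persist an ROI sidecar as JSON with keys x0, y0, width, height."""
    # Re-validate: dataclass fields may have been mutated after construction.
    ROIBox(roi.x0, roi.y0, roi.width, roi.height)
    path = Path(path)
    path.write_text(
        json.dumps({k: getattr(roi, k) for k in _ROI_KEYS}, indent=1) + "\n"
    )
    return path


def load_roi(path: str | Path) -> ROIBox:
    """Load an ROI sidecar; raises :class:`ParseError` naming missing keys."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(payload, dict):
        raise ParseError(f"{path}: expected a JSON object")
    missing = [k for k in _ROI_KEYS if k not in payload]
    if missing:
        raise ParseError(
            f"{path}: ROI sidecar missing keys: {', '.join(missing)}", missing=missing
        )
    return ROIBox(**{k: payload[k] for k in _ROI_KEYS})
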