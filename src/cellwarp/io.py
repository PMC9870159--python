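"""Reading and writing movie stacks, masks and deformation fields.

All containers follow a single documented convention:

* arrays are ``(time, row, col)``; the row index increases downward;
* displacement fields store component 0 as the row-direction displacement
  and component 1 as the column-direction displacement, in pixels;
* coordinates are 0-based with pixel centers at integer positions.

Movies are stored as multi-page grayscale TIFF (uint8/uint16/float32), one
stack per channel, frames aligned across channels by page index. Physical
metadata (``pixel_size`` in micrometers/pixel, ``frame_interval`` in
seconds/frame) travels in a small JSON sidecar next to the TIFF.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "MovieStack",
    "FieldStack",
    "FormatError",
    "read_movie",
    "write_movie",
    "read_fields",
    "write_fields",
    "read_mask_stack",
    "write_mask_stack",
]


class FormatError(ValueError):
    """Raised for malformed on-disk containers."""


@dataclass
class MovieStack:
    """A time-ordered stack of 2D intensity frames for one channel.

    Parameters
    ----------
    frames : ndarray, shape (T, rows, cols)
        Non-negative, finite intensities.
    channel_name : str
        Free-text channel label (e.g. ``"actin"``, ``"profilin"``).
    pixel_size : float
        Micrometers per pixel.
    frame_interval : float
        Seconds per frame.
    """

    frames: np.ndarray
    channel_name: str = ""
    pixel_size: float = 1.0
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (time, rows, cols); got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("movie stack must contain at least one frame")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if np.any(self.frames < 0):
            raise ValueError("frame intensities must be non-negative")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def __len__(self) -> int:
        return self.n_frames

    def with_frames(self, frames: np.ndarray, channel_name: str | None = None) -> "MovieStack":
        """Copy of this stack with new frame data, metadata preserved."""
        return MovieStack(
            frames=frames,
            channel_name=self.channel_name if channel_name is None else channel_name,
            pixel_size=self.pixel_size,
            frame_interval=self.frame_interval,
        )


@dataclass
class FieldStack:
    """Per-frame displacement fields mapping each frame onto a reference frame.

    ``fields`` has shape (T, 2, rows, cols); component 0 is the row
    displacement, component 1 the column displacement, both in pixels.
    """

    fields: np.ndarray
    reference_index: int = 0

    def __post_init__(self) -> None:
        self.fields = np.asarray(self.fields, dtype=np.float64)
        if self.fields.ndim != 4 or self.fields.shape[1] != 2:
            raise ValueError(
                f"fields must be (time, 2, rows, cols); got shape {self.fields.shape}"
            )
        if not np.all(np.isfinite(self.fields)):
            raise ValueError("displacement fields must be finite")
        if not 0 <= self.reference_index < self.fields.shape[0]:
            raise ValueError("reference_index outside the stack")

    @property
    def n_frames(self) -> int:
        return self.fields.shape[0]

    def __len__(self) -> int:
        return self.n_frames


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _load_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        return json.loads(sidecar.read_text())
    return {}


def read_movie(
    path,
    channel: str = "",
    pixel_size: float | None = None,
    frame_interval: float | None = None,
) -> MovieStack:
    """Read a (multi-page) grayscale TIFF as a :class:`MovieStack`.

    Metadata resolution order: explicit arguments, then JSON sidecar
    (``<name>.tif.meta.json``), then 1.0 with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"movie file not found: {path}")
    try:
        frames = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"could not read TIFF {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise FormatError(
            f"{path}: expected grayscale pages of identical shape, got array of "
            f"shape {frames.shape}"
        )
    meta = _load_sidecar(path)
    if pixel_size is None:
        pixel_size = meta.get("pixel_size")
    if frame_interval is None:
        frame_interval = meta.get("frame_interval")
    if pixel_size is None:
        logger.warning("%s: pixel_size unknown, defaulting to 1.0 um/px", path)
        pixel_size = 1.0
    if frame_interval is None:
        logger.warning("%s: frame_interval unknown, defaulting to 1.0 s/frame", path)
        frame_interval = 1.0
    if not channel:
        channel = meta.get("channel_name", path.stem)
    return MovieStack(
        frames=frames,
        channel_name=channel,
        pixel_size=float(pixel_size),
        frame_interval=float(frame_interval),
    )


def write_movie(stack: MovieStack, path) -> Path:
    """Write a :class:`MovieStack` as a multi-page TIFF plus JSON sidecar.

    Integer data round-trips bit-exactly; floating point data is stored as
    float32 (round-trip error below 1e-6 relative for typical intensities).
    """
    path = Path(path)
    data = stack.frames
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    try:
        tifffile.imwrite(path, data)
    except OSError as exc:
        raise IOError(f"could not write TIFF {path}: {exc}") from exc
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "channel_name": stack.channel_name,
                "pixel_size": stack.pixel_size,
                "frame_interval": stack.frame_interval,
            },
            indent=2,
        )
    )
    return path


def write_fields(stack: FieldStack, path) -> Path:
    """Persist deformation fields as float32 TIFF, two pages per frame.

    Pages are time-major: frame 0 row-component, frame 0 col-component,
    frame 1 row-component, ... The sidecar records the reference frame index
    and the component convention.
    """
    path = Path(path)
    t, _, rows, cols = stack.fields.shape
    pages = stack.fields.reshape(t * 2, rows, cols).astype(np.float32)
    tifffile.imwrite(path, pages)
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "reference_index": int(stack.reference_index),
                "n_frames": int(t),
                "component_order": ["row", "col"],
            },
            indent=2,
        )
    )
    return path


def read_fields(path) -> FieldStack:
    """Read deformation fields written by :func:`write_fields`."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"field file not found: {path}")
    pages = np.asarray(tifffile.imread(path))
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] % 2 != 0:
        raise FormatError(
            f"{path}: field container needs two pages per frame, got "
            f"{pages.shape[0]} pages"
        )
    meta = _load_sidecar(path)
    t = pages.shape[0] // 2
    if "n_frames" in meta and meta["n_frames"] != t:
        raise FormatError(
            f"{path}: sidecar declares {meta['n_frames']} frames but TIFF holds {t}"
        )
    fields = pages.reshape(t, 2, *pages.shape[1:])
    return FieldStack(fields=fields, reference_index=int(meta.get("reference_index", 0)))


def write_mask_stack(masks: np.ndarray, path) -> Path:
    """Write per-frame binary masks as uint8 (0/255) multi-page TIFF."""
    masks = np.asarray(masks)
    if masks.ndim == 2:
        masks = masks[None]
    tifffile.imwrite(Path(path), (masks > 0).astype(np.uint8) * 255)
    return Path(path)


def read_mask_stack(path) -> np.ndarray:
    """Read a binary mask stack written by :func:`write_mask_stack`."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"mask file not found: {path}")
    masks = np.asarray(tifffile.imread(path))
    if masks.ndim == 2:
        masks = masks[None]
    return masks > 0
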