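"""Cell masks and the boundary-distance gradient that regularizes registration.

The registration treats the cell segmentation as a second "image": wherever
the moving and target masks disagree, a force proportional to the gradient of
the target mask's boundary-distance field pulls the moving cell toward
overlap with the target cell. This module produces the per-frame binary
masks, the signed distance map (positive inside, negative outside) and its
unit-normalized gradient, plus the simple threshold + hole-fill segmentation
used for bright intracellular structures such as transverse actin arcs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import disk

logger = logging.getLogger(__name__)

__all__ = [
    "CellMask",
    "MaskGradientField",
    "SegmentationError",
    "segment_cell",
    "segment_movie",
    "mask_gradient",
    "segment_structures",
    "boundary_pixels",
]


class SegmentationError(RuntimeError):
    """Raised when no usable cell foreground can be found."""


@dataclass
class CellMask:
    """Binary foreground of one frame; exactly one connected component."""

    mask: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class MaskGradientField:
    """Signed boundary-distance map and its unit-normalized gradient.

    ``distance_map`` is positive inside the cell, negative outside, zero on
    boundary pixels. ``grad`` has shape (2, rows, cols) with component 0 the
    row derivative; its direction points from the exterior toward the
    interior, magnitude ≤ 1 after normalization.
    """

    grad: np.ndarray
    distance_map: np.ndarray

    def __post_init__(self) -> None:
        self.grad = np.asarray(self.grad, dtype=np.float64)
        self.distance_map = np.asarray(self.distance_map, dtype=np.float64)
        if self.grad.ndim != 3 or self.grad.shape[0] != 2:
            raise ValueError("grad must be (2, rows, cols)")
        if self.grad.shape[1:] != self.distance_map.shape:
            raise ValueError("grad and distance_map shapes disagree")


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least one 4-adjacent background pixel.

    The frame edge itself does not create boundary: a mask cut off by the
    image border (a cell partially out of view) has no cell outline there.
    """
    mask = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=1
    )
    return mask & ~interior


def segment_cell(
    frame: np.ndarray,
    sigma: float = 2.0,
    threshold: float | None = None,
    closing_radius: int = 2,
    border_margin: int = 2,
    frame_index: int = 0,
) -> CellMask:
    """Segment the single-cell foreground of one intensity frame.

    Pipeline: Gaussian pre-smooth (``sigma`` px) → global threshold (Otsu by
    default, or a fixed ``threshold``) → morphological closing → hole fill →
    keep the largest connected component.

    Raises
    ------
    SegmentationError
        If the thresholded foreground is empty; pass an explicit manual
        ``threshold`` in that case.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("frame must be 2D")
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame must be finite")
    smoothed = ndimage.gaussian_filter(frame, sigma) if sigma > 0 else frame
    if threshold is None:
        if np.ptp(smoothed) == 0:
            raise SegmentationError(
                "frame has no contrast; supply a manual threshold"
            )
        threshold = threshold_otsu(smoothed)
    fg = smoothed > threshold
    if not fg.any():
        raise SegmentationError(
            "empty foreground after thresholding; supply a manual threshold"
        )
    if closing_radius > 0:
        fg = ndimage.binary_closing(fg, structure=disk(closing_radius))
    fg = ndimage.binary_fill_holes(fg)
    labels = label(fg)
    if labels.max() > 1:
        sizes = np.bincount(labels.ravel())[1:]
        fg = labels == (int(np.argmax(sizes)) + 1)
    border = np.zeros_like(fg)
    m = border_margin
    border[:m, :] = border[-m:, :] = border[:, :m] = border[:, -m:] = True
    if (fg & border).any():
        logger.warning(
            "frame %d: cell mask touches the image border (margin %d px)",
            frame_index,
            border_margin,
        )
    return CellMask(mask=fg, frame_index=frame_index)


def segment_movie(stack, **kwargs) -> list[CellMask]:
    """Apply :func:`segment_cell` to every frame of a movie stack."""
    return [
        segment_cell(frame, frame_index=t, **kwargs)
        for t, frame in enumerate(stack.frames)
    ]


def mask_gradient(mask: CellMask | np.ndarray) -> MaskGradientField:
    """Signed boundary-distance map of a cell mask and its unit gradient.

    Euclidean distances to the nearest boundary pixel are computed for the
    interior and exterior separately and combined into one signed map
    (positive inside). The gradient is taken with central differences on a
    replicate-padded map and normalized to unit length wherever its
    magnitude is nonzero, so the mask force stays bounded exactly like the
    intensity force.
    """
    m = mask.mask if isinstance(mask, CellMask) else np.asarray(mask, dtype=bool)
    if m.all():
        raise ValueError("mask covers the whole image; distance field degenerate")
    if not m.any():
        raise ValueError("mask is empty")
    boundary = boundary_pixels(m)
    # distance of every pixel to its nearest boundary pixel
    dist = ndimage.distance_transform_edt(~boundary)
    signed = np.where(m, dist, -dist)

    padded = np.pad(signed, 1, mode="edge")
    g1 = (padded[2:, 1:-1] - padded[:-2, 1:-1]) / 2.0
    g2 = (padded[1:-1, 2:] - padded[1:-1, :-2]) / 2.0
    mag = np.hypot(g1, g2)
    nz = mag > 1e-12
    g1 = np.where(nz, g1 / np.where(nz, mag, 1.0), 0.0)
    g2 = np.where(nz, g2 / np.where(nz, mag, 1.0), 0.0)
    return MaskGradientField(grad=np.stack([g1, g2]), distance_map=signed)


def segment_structures(frame: np.ndarray, threshold: float) -> np.ndarray:
    """Bright-structure segmentation: intensity threshold plus hole filling.

    Used for circumferential actin arcs and similar contiguous bright
    structures in a remapped movie.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("frame must be 2D")
    binary = frame >= threshold
    return ndimage.binary_fill_holes(binary)
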