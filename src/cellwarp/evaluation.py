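"""Remapping-accuracy metrics.

Live-cell movies come without landmarks or ground truth, so registration
quality is measured by internal consistency:

* **to-target accuracy** — mean squared intensity difference (SSD) between
  the fully remapped moving frame and the target frame;
* **half-distance accuracy** — halve the deformation field estimated over
  two frame intervals and compare the half-remapped frame to the skipped
  middle frame; valid when the deformation path is approximately linear in
  time;
* **boundary mismatch** — symmetric-difference area of two cell masks
  normalized by the target mask perimeter (pixels), the convergence measure
  of the registration loop;
* **boundary displacement** — total cell-edge displacement per frame
  interval, integrated over the boundary, for morphodynamic phase analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .demons import DeformationField, DemonsConfig, register_pair, warp_image
from .io import MovieStack
from .masking import CellMask, boundary_pixels

__all__ = [
    "AccuracyRecord",
    "ssd",
    "zero_background",
    "half_distance_field",
    "transform_accuracy",
    "boundary_mismatch",
    "boundary_displacement_series",
    "split_phases",
    "compare_groups",
]


@dataclass
class AccuracyRecord:
    """SSD accuracies for one (moving, target) frame pair."""

    frame_pair: tuple[int, int]
    ssd_baseline: float
    ssd_to_target: float
    ssd_half_distance: float | None = None

    def __post_init__(self) -> None:
        for v in (self.ssd_baseline, self.ssd_to_target):
            if v < 0:
                raise ValueError("SSD values must be non-negative")


def ssd(image_a: np.ndarray, image_b: np.ndarray, mask=None) -> float:
    """Mean squared intensity difference between two frames.

    With a mask, the mean runs over mask pixels only; otherwise over the
    whole frame (callers zero the background first for baselines, per
    :func:`zero_background`).
    """
    a = np.asarray(image_a, dtype=np.float64)
    b = np.asarray(image_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shapes differ: {a.shape} vs {b.shape}")
    sq = (a - b) ** 2
    if mask is not None:
        m = mask.mask if isinstance(mask, CellMask) else np.asarray(mask, dtype=bool)
        if not m.any():
            raise ValueError("empty evaluation mask")
        return float(sq[m].mean())
    return float(sq.mean())


def zero_background(image: np.ndarray, mask) -> np.ndarray:
    """Set pixels outside the cell mask to zero."""
    m = mask.mask if isinstance(mask, CellMask) else np.asarray(mask, dtype=bool)
    return np.where(m, np.asarray(image, dtype=np.float64), 0.0)


def half_distance_field(fld: DeformationField) -> DeformationField:
    """Halve the magnitude of a deformation field.

    Halving preserves axis-wise monotonicity: the halved sampling
    coordinates are the midpoint of the identity mesh and the full mesh,
    both monotone.
    """
    return DeformationField(0.5 * fld.u1, 0.5 * fld.u2)


def transform_accuracy(
    movie: MovieStack,
    masks: list[CellMask],
    config: DemonsConfig | None = None,
    stride: int = 2,
    signal: MovieStack | None = None,
    half_distance: bool = True,
) -> list[AccuracyRecord]:
    """To-target and half-distance SSD accuracies over strided frame pairs.

    For every pair ``(t, t+stride)`` the movie (acting as its own fiducial)
    is registered moving→target; the signal channel (defaults to the movie
    itself) is remapped with the full field for the to-target accuracy and
    with the halved field against the skipped middle frame for the
    half-distance accuracy. Baselines are unregistered frame pairs with the
    background set to zero. ``stride`` must be even when the half-distance
    test is requested.
    """
    config = config or DemonsConfig.half_distance_eval()
    if stride < 2:
        raise ValueError("stride must be >= 2")
    if half_distance and stride % 2 != 0:
        raise ValueError("half-distance accuracy needs an even stride")
    signal = signal or movie
    if signal.n_frames != movie.n_frames:
        raise ValueError("signal and fiducial movies must be frame-aligned")
    records = []
    for t in range(movie.n_frames - stride):
        tt = t + stride
        fld, _ = register_pair(
            movie.frames[t],
            movie.frames[tt],
            mask_moving=masks[t],
            mask_target=masks[tt],
            config=config,
            record_convergence=False,
        )
        mov_sig = zero_background(signal.frames[t], masks[t])
        tgt_sig = zero_background(signal.frames[tt], masks[tt])
        baseline = ssd(mov_sig, tgt_sig)
        remapped = warp_image(mov_sig, fld)
        to_target = ssd(remapped, tgt_sig)
        half = None
        if half_distance:
            mid = t + stride // 2
            mid_sig = zero_background(signal.frames[mid], masks[mid])
            half_remap = warp_image(mov_sig, half_distance_field(fld))
            half = ssd(half_remap, mid_sig)
        records.append(
            AccuracyRecord(
                frame_pair=(t, tt),
                ssd_baseline=baseline,
                ssd_to_target=to_target,
                ssd_half_distance=half,
            )
        )
    return records


def boundary_mismatch(mask_a, mask_b) -> float:
    """Perimeter-normalized boundary mismatch between two cell masks.

    Count of symmetric-difference pixels divided by the target (``mask_b``)
    perimeter, measured as its 8-connected boundary pixel count.
    """
    a = mask_a.mask if isinstance(mask_a, CellMask) else np.asarray(mask_a, dtype=bool)
    b = mask_b.mask if isinstance(mask_b, CellMask) else np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    if not b.any():
        raise ValueError("target mask is empty")
    # 8-connected boundary: foreground pixels with any background neighbor
    interior = ndimage.binary_erosion(
        b, structure=np.ones((3, 3), dtype=bool), border_value=0
    )
    perimeter = int((b & ~interior).sum())
    return float(np.logical_xor(a, b).sum() / max(perimeter, 1))


def boundary_displacement_series(
    masks: list[CellMask],
    pixel_size: float = 1.0,
    frame_interval: float = 1.0,
) -> pd.DataFrame:
    """Total cell-edge displacement integrated over the boundary, per frame.

    For each consecutive mask pair, sums over the later mask's boundary
    pixels the Euclidean distance to the earlier mask's boundary, scaled to
    micrometers. Returns a DataFrame with columns ``time_s`` and
    ``displacement_um``.
    """
    if len(masks) < 2:
        raise ValueError("need at least two masks")
    rows = []
    for t in range(len(masks) - 1):
        a = masks[t].mask if isinstance(masks[t], CellMask) else masks[t]
        b = masks[t + 1].mask if isinstance(masks[t + 1], CellMask) else masks[t + 1]
        ba = boundary_pixels(a)
        bb = boundary_pixels(b)
        if not (ba.any() and bb.any()):
            raise ValueError(f"empty mask at frame {t} or {t + 1}")
        dist_to_a = ndimage.distance_transform_edt(~ba)
        disp = float(dist_to_a[bb].sum() * pixel_size)
        rows.append({"time_s": (t + 1) * frame_interval, "displacement_um": disp})
    return pd.DataFrame(rows)


def split_phases(series: pd.DataFrame, scheme: str = "thirds") -> pd.DataFrame:
    """Label a displacement time course with morphodynamic phases.

    ``scheme="thirds"`` marks the first third of the movie as phase 1 (high
    morphodynamic activity, e.g. during symmetry breaking) and the last
    third as phase 2 (steady state); the middle third is unlabeled (0).
    """
    if scheme != "thirds":
        raise ValueError(f"unknown phase scheme: {scheme}")
    n = len(series)
    phase = np.zeros(n, dtype=int)
    phase[: n // 3] = 1
    phase[n - n // 3 :] = 2
    out = series.copy()
    out["phase"] = phase
    return out


def compare_groups(*groups) -> tuple[float, float]:
    """One-way ANOVA across value groups; returns (F statistic, p-value)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    res = stats.f_oneway(*[np.asarray(g, dtype=np.float64) for g in groups])
    return float(res.statistic), float(res.pvalue)
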