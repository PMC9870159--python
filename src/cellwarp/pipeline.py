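"""Whole-movie registration: map every frame onto a fixed reference frame.

A movie is registered by estimating, for every frame, a diffeomorphic
displacement field that resamples that frame onto the geometry of a chosen
reference frame (the center frame by default). The fields are estimated on a
*location fiducial* channel — a membrane marker, a diffuse cytoplasmic
protein, or a lowpass-filtered copy of the signal itself — and then applied
unchanged to every co-imaged signal channel.

Frames are processed outward from the reference. Each frame's field is
warm-started from its already-registered temporal neighbor and refined with
``n_iterations`` demons iterations against the reference, so frames farther
from the reference accumulate proportionally more iterations while each
frame costs only one iteration block.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .demons import DeformationField, DemonsConfig, register_pair, warp_image
from .io import FieldStack, MovieStack
from .masking import CellMask

__all__ = [
    "RegistrationResult",
    "make_lowpass_fiducial",
    "register_sequence",
    "remap_channels",
]


@dataclass
class RegistrationResult:
    """Fields, remapped channels and convergence traces of one registration."""

    fields: FieldStack
    reference_index: int
    remapped: dict[str, MovieStack] = dc_field(default_factory=dict)
    convergence: dict[int, list[float]] = dc_field(default_factory=dict)

    def field_for_frame(self, t: int) -> DeformationField:
        arr = self.fields.fields[t]
        return DeformationField(arr[0], arr[1])


def make_lowpass_fiducial(stack: MovieStack, sigma: float = 20.0) -> MovieStack:
    """Lowpass-filtered copy of a signal channel for use as location fiducial.

    Applies a per-frame Gaussian blur (default σ = 20 px), separating the
    coarse-scale distribution used for registration from the informative
    high-frequency fluctuations that remain untouched in the signal channel.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    blurred = np.stack(
        [ndimage.gaussian_filter(f.astype(np.float64), sigma) for f in stack.frames]
    )
    return stack.with_frames(blurred, channel_name=f"{stack.channel_name}_lowpass")


def register_sequence(
    fiducial: MovieStack,
    masks: list[CellMask],
    reference_index: int | None = None,
    config: DemonsConfig | None = None,
    record_convergence: bool = True,
) -> RegistrationResult:
    """Estimate frame→reference deformation fields for a whole movie.

    Parameters
    ----------
    fiducial : MovieStack
        The location-fiducial channel (length ≥ 2).
    masks : list of CellMask
        One per frame, same order as the movie.
    reference_index : int, optional
        Defaults to the center frame, ``len(movie) // 2``.
    config : DemonsConfig, optional

    Returns
    -------
    RegistrationResult
        With ``fields`` populated (zero field at the reference frame) and
        per-frame convergence traces; ``remapped`` is filled by
        :func:`remap_channels`.
    """
    config = config or DemonsConfig()
    n = fiducial.n_frames
    if n < 2:
        raise ValueError("registration needs at least two frames")
    if len(masks) != n:
        raise ValueError(f"got {len(masks)} masks for {n} frames")
    if reference_index is None:
        reference_index = n // 2
    if not 0 <= reference_index < n:
        raise ValueError("reference_index outside the movie")

    shape = fiducial.frame_shape
    frames = fiducial.frames.astype(np.float64)
    ref_frame = frames[reference_index]
    ref_mask = masks[reference_index]

    fields = np.zeros((n, 2, *shape), dtype=np.float64)
    convergence: dict[int, list[float]] = {}

    for direction in (-1, +1):
        prev_field: DeformationField | None = None
        t = reference_index + direction
        while 0 <= t < n:
            fld, trace = register_pair(
                frames[t],
                ref_frame,
                mask_moving=masks[t],
                mask_target=ref_mask,
                config=config,
                init_field=prev_field,
                record_convergence=record_convergence,
            )
            fields[t] = fld.as_array()
            if record_convergence:
                convergence[t] = trace
            prev_field = fld
            t += direction

    return RegistrationResult(
        fields=FieldStack(fields=fields, reference_index=reference_index),
        reference_index=reference_index,
        convergence=convergence,
    )


def remap_channels(
    result: RegistrationResult, channels: dict[str, MovieStack]
) -> RegistrationResult:
    """Warp every frame of each signal channel with its frame's field.

    Channels must be frame-aligned with the fiducial the fields were
    estimated on; remapped stacks are stored in ``result.remapped`` under
    their channel name.
    """
    n = result.fields.n_frames
    for name, stack in channels.items():
        if stack.n_frames != n:
            raise ValueError(
                f"channel '{name}' has {stack.n_frames} frames; fields have {n}"
            )
        warped = np.stack(
            [
                warp_image(stack.frames[t].astype(np.float64), result.field_for_frame(t))
                for t in range(n)
            ]
        )
        result.remapped[name] = stack.with_frames(warped, channel_name=name)
    return result
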