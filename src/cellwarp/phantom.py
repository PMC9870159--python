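"""Synthetic cell movies with exact ground truth.

The generator builds a reference "cell" (a Fourier-perturbed ellipse with a
domed interior thickness profile), renders fluorescence-like channels on it —

* ``diffuse``   — thickness × a smooth multiplicative texture (a diffuse
  cytoplasmic fiducial, membrane-marker/profilin-like);
* ``punctate``  — fixed random bright dots plus a faint diffuse component
  (adhesion-protein-like);
* ``signal``    — curvilinear fibers plus a diffuse pool (actin-like);

— and deforms them over time with an analytically constructed family of
diffeomorphic displacement fields. Frame ``t`` is rendered as
``ref ∘ g_t⁻¹`` with ``g_t(x) = x + U_t(x)``, where ``g_t⁻¹`` is computed by
fixed-point iteration (a contraction because sup‖∇U‖ < 0.5). The stored
frame→reference fields ``U_t`` are therefore *exact*: warping frame ``t``
with ``U_t`` reproduces the reference up to interpolation error only. Noise
is added last, so masks and fields are noise-free ground truth.

Ground-truth masks threshold the noise-free rendered thickness map at half
its rim plateau, i.e. they are the thresholded support of the noise-free
diffuse fiducial. At the reference frame (no resampling) the mask equals
the fiducial's exact support; warped frames place the mask boundary at the
midpoint of the one-pixel bilinear transition skirt.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .demons import DeformationField, is_diffeomorphic
from .io import FieldStack, MovieStack
from .masking import CellMask

__all__ = [
    "PhantomSpec",
    "PhantomMovie",
    "generate_phantom",
    "plant_coherence",
    "plant_entropy_phases",
    "preset_spec",
]

WARP_KINDS = ("translation", "dilation", "protrusion", "smooth-random", "linear-path")
FIDUCIAL_KINDS = ("diffuse", "punctate", "lowpass-of-signal")

# sup-norm bound on the displacement-field Jacobian that guarantees both the
# axis-wise monotonicity of the mesh and contraction of the inversion
_GRAD_SAFETY = 0.5

# ground-truth mask level: half the thickness rim plateau (0.7)
_MASK_LEVEL = 0.35


@dataclass
class PhantomSpec:
    """Stated imaging conditions of a phantom movie.

    Defaults emulate the published acquisition regime: 256×256 crops,
    0.06 μm/px (6.5 μm camera pixels at 108× magnification), 5 s/frame,
    smooth sub-Nyquist shape change of a few pixels per frame interval and
    ~2% camera noise.
    """

    image_size: int = 256
    n_frames: int = 64
    pixel_size: float = 0.06
    frame_interval: float = 5.0
    fiducial_kind: str = "diffuse"
    warp_kind: str = "smooth-random"
    warp_amplitude: float = 3.0
    noise_sigma: float = 0.02
    poisson_photons: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.fiducial_kind not in FIDUCIAL_KINDS:
            raise ValueError(f"fiducial_kind must be one of {FIDUCIAL_KINDS}")
        if self.warp_kind not in WARP_KINDS:
            raise ValueError(f"warp_kind must be one of {WARP_KINDS}")
        if self.warp_amplitude < 0:
            raise ValueError("warp_amplitude must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class PhantomMovie:
    """Channels, ground-truth masks and exact frame→reference fields."""

    channels: dict[str, MovieStack]
    masks: list[CellMask]
    true_fields: FieldStack
    spec: PhantomSpec
    planted: dict = dc_field(default_factory=dict)

    @property
    def reference_index(self) -> int:
        return self.true_fields.reference_index

    @property
    def fiducial(self) -> MovieStack:
        """The channel designated as location fiducial by the spec."""
        if self.spec.fiducial_kind == "diffuse":
            return self.channels["diffuse"]
        if self.spec.fiducial_kind == "punctate":
            return self.channels["punctate"]
        # lowpass-of-signal: blurred copy of the structured channel
        sig = self.channels["signal"]
        blurred = np.stack(
            [ndimage.gaussian_filter(f, 20.0) for f in sig.frames]
        )
        return sig.with_frames(blurred, channel_name="signal_lowpass")

    def true_field(self, t: int) -> DeformationField:
        arr = self.true_fields.fields[t]
        return DeformationField(arr[0], arr[1])


def _reference_cell(spec: PhantomSpec, rng: np.random.Generator):
    """Reference mask, thickness map and texture on the pixel grid."""
    n = spec.image_size
    rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    cy = cx = (n - 1) / 2.0
    dy, dx = rr - cy, cc - cx
    theta = np.arctan2(dx, dy)
    radius = np.hypot(dy, dx)
    a, b = 0.40 * n, 0.34 * n
    r_ell = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    perturb = np.ones_like(theta)
    for k in range(3, 7):
        eps = rng.uniform(0.0, 0.05)
        phi = rng.uniform(0, 2 * np.pi)
        perturb += eps * np.cos(k * theta + phi)
    contour = r_ell * perturb
    mask = radius < contour

    # domed thickness with a bright plateau at the rim so the footprint has
    # a crisp, segmentable edge
    interior_depth = ndimage.distance_transform_edt(mask)
    dome = interior_depth / max(interior_depth.max(), 1.0)
    thick = np.where(mask, 0.7 + 0.3 * dome, 0.0)

    texture = ndimage.gaussian_filter(rng.standard_normal((n, n)), 3.0)
    texture = 1.0 + 0.3 * texture / max(np.abs(texture).max(), 1e-12)
    return mask, thick, texture


def _render_fibers(mask: np.ndarray, rng: np.random.Generator, n_fibers: int = 12):
    """Curvilinear bright fibers inside the cell footprint."""
    n = mask.shape[0]
    canvas = np.zeros_like(mask, dtype=np.float64)
    inside = np.argwhere(mask)
    for _ in range(n_fibers):
        r, c = inside[rng.integers(len(inside))]
        ang = rng.uniform(0, 2 * np.pi)
        curv = rng.uniform(-0.03, 0.03)
        pos = np.array([r, c], dtype=np.float64)
        for _ in range(int(0.5 * n)):
            ri, ci = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= ri < n and 0 <= ci < n) or not mask[ri, ci]:
                break
            canvas[ri, ci] = 1.0
            pos += np.array([np.cos(ang), np.sin(ang)])
            ang += curv
    return ndimage.gaussian_filter(canvas, 1.2)


def _render_puncta(mask: np.ndarray, rng: np.random.Generator, n_dots: int = 60):
    canvas = np.zeros_like(mask, dtype=np.float64)
    inside = np.argwhere(ndimage.binary_erosion(mask, iterations=3))
    idx = rng.choice(len(inside), size=min(n_dots, len(inside)), replace=False)
    for r, c in inside[idx]:
        canvas[r, c] = rng.uniform(0.7, 1.3)
    return ndimage.gaussian_filter(canvas, 1.5) * (2 * np.pi * 1.5**2)


def _base_fields(spec: PhantomSpec, mask: np.ndarray, rng: np.random.Generator):
    """Spatial base displacement fields B (list of (2,H,W) arrays)."""
    n = spec.image_size
    amp = spec.warp_amplitude
    rr, cc = np.meshgrid(
        np.arange(n, dtype=np.float64), np.arange(n, dtype=np.float64), indexing="ij"
    )
    kind = spec.warp_kind
    if kind == "translation":
        ang = rng.uniform(0, 2 * np.pi)
        b = np.stack(
            [np.full((n, n), amp * np.cos(ang)), np.full((n, n), amp * np.sin(ang))]
        )
        return [b]
    if kind == "dilation":
        c0 = (n - 1) / 2.0
        r_ref = 0.4 * n
        return [np.stack([amp * (rr - c0) / r_ref, amp * (cc - c0) / r_ref])]
    if kind == "protrusion":
        from .masking import boundary_pixels, mask_gradient

        bpix = np.argwhere(boundary_pixels(mask))
        p = bpix[rng.integers(len(bpix))]
        g = mask_gradient(mask).grad[:, p[0], p[1]]  # unit, points inward
        sigma_p = n / 8.0
        bump = np.exp(-((rr - p[0]) ** 2 + (cc - p[1]) ** 2) / (2 * sigma_p**2))
        return [np.stack([amp * bump * g[0], amp * bump * g[1]])]
    # smooth-random / linear-path: lowpass-filtered white noise per component
    fields = []
    n_comp = 2 if kind == "smooth-random" else 1
    for _ in range(n_comp):
        raw = np.stack(
            [
                ndimage.gaussian_filter(rng.standard_normal((n, n)), n / 6.0)
                for _ in range(2)
            ]
        )
        mag = np.hypot(raw[0], raw[1]).max()
        fields.append(raw * (amp / max(mag, 1e-12)))
    return fields


def _check_safety(u: np.ndarray) -> float:
    """Maximum axis-aligned displacement derivative of a (2,H,W) field."""
    g11 = np.abs(np.diff(u[0], axis=0)).max() if u.shape[1] > 1 else 0.0
    g22 = np.abs(np.diff(u[1], axis=1)).max() if u.shape[2] > 1 else 0.0
    return max(g11, g22)


def _invert_field(u: np.ndarray, tol: float = 1e-8, max_iter: int = 60):
    """Fixed-point inverse sampling grid x = g⁻¹(y) for g(x) = x + u(x)."""
    n1, n2 = u.shape[1:]
    rr, cc = np.meshgrid(
        np.arange(n1, dtype=np.float64), np.arange(n2, dtype=np.float64), indexing="ij"
    )
    x1, x2 = rr.copy(), cc.copy()
    for _ in range(max_iter):
        e1 = ndimage.map_coordinates(u[0], [x1, x2], order=1, mode="nearest")
        e2 = ndimage.map_coordinates(u[1], [x1, x2], order=1, mode="nearest")
        nx1, nx2 = rr - e1, cc - e2
        delta = max(np.abs(nx1 - x1).max(), np.abs(nx2 - x2).max())
        x1, x2 = nx1, nx2
        if delta < tol:
            break
    return x1, x2


def generate_phantom(spec: PhantomSpec | None = None, **kwargs) -> PhantomMovie:
    """Generate a phantom movie with exact ground-truth fields and masks.

    Fully deterministic given ``spec.seed``. Raises ``ValueError`` when the
    requested warp amplitude violates the diffeomorphism safety bound
    (sup-norm field gradient ≥ 0.5).
    """
    if spec is None:
        spec = PhantomSpec(**kwargs)
    rng = np.random.default_rng(spec.seed)
    n, T = spec.image_size, spec.n_frames
    ref_idx = T // 2

    mask_ref, thick, texture = _reference_cell(spec, rng)
    channels_ref = {
        "diffuse": thick * texture,
        "punctate": _render_puncta(mask_ref, rng) + 0.15 * thick,
        "signal": _render_fibers(mask_ref, rng) + 0.3 * thick,
    }

    bases = _base_fields(spec, mask_ref, rng)
    # temporal schedule: linear ramp away from the reference frame, plus a
    # slow oscillation for the smooth-random kind
    half_span = max(ref_idx, T - 1 - ref_idx, 1)
    lam = (np.arange(T) - ref_idx) / half_span

    fields = np.zeros((T, 2, n, n), dtype=np.float64)
    for t in range(T):
        u = lam[t] * bases[0]
        if spec.warp_kind == "smooth-random" and len(bases) > 1:
            u = u + 0.4 * np.sin(np.pi * lam[t]) * bases[1]
        fields[t] = u
    worst = max(_check_safety(fields[t]) for t in range(T))
    if worst >= _GRAD_SAFETY:
        raise ValueError(
            f"warp amplitude {spec.warp_amplitude} exceeds the diffeomorphism "
            f"safety bound (max field gradient {worst:.3f} >= {_GRAD_SAFETY})"
        )

    frames = {name: np.zeros((T, n, n)) for name in channels_ref}
    mask_frames = np.zeros((T, n, n), dtype=bool)
    for t in range(T):
        if t == ref_idx:
            for name, ref in channels_ref.items():
                frames[name][t] = ref
            mask_frames[t] = thick >= _MASK_LEVEL
            continue
        x1, x2 = _invert_field(fields[t])
        thick_t = ndimage.map_coordinates(thick, [x1, x2], order=1, mode="nearest")
        mask_frames[t] = thick_t >= _MASK_LEVEL
        for name, ref in channels_ref.items():
            frames[name][t] = ndimage.map_coordinates(
                ref, [x1, x2], order=1, mode="nearest"
            )

    for name in frames:
        arr = frames[name]
        if spec.poisson_photons:
            arr = rng.poisson(np.clip(arr, 0, None) * spec.poisson_photons) / float(
                spec.poisson_photons
            )
        if spec.noise_sigma > 0:
            arr = arr + rng.normal(0.0, spec.noise_sigma, size=arr.shape)
        frames[name] = np.clip(arr, 0.0, None)

    channels = {
        name: MovieStack(
            frames=frames[name],
            channel_name=name,
            pixel_size=spec.pixel_size,
            frame_interval=spec.frame_interval,
        )
        for name in frames
    }
    masks = [CellMask(mask=mask_frames[t], frame_index=t) for t in range(T)]
    return PhantomMovie(
        channels=channels,
        masks=masks,
        true_fields=FieldStack(fields=fields, reference_index=ref_idx),
        spec=spec,
        planted={"warp_kind": spec.warp_kind, "warp_amplitude": spec.warp_amplitude},
    )


def plant_coherence(
    movie: PhantomMovie,
    zones: np.ndarray,
    rho: float,
    switch_frame: int | None = None,
    channel: str = "planted_coherence",
    baseline: float = 1.0,
    amplitude: float = 0.1,
) -> PhantomMovie:
    """Add a channel with known pairwise time-series correlation in zones.

    Within each labeled zone the pixel series are a shared latent standard
    normal mixed with independent noise, with mixture weight √ρ so the
    expected pairwise Pearson correlation is exactly ``rho``. Pixels inside
    the cell mask but outside all zones carry independent noise; background
    is zero. With ``switch_frame``, frames before the switch are fully
    independent everywhere (a planted change-point). The channel is written
    in reference-frame geometry (it emulates an already-remapped signal).
    """
    if not 0 <= rho <= 1:
        raise ValueError("rho must be in [0, 1]")
    zones = np.asarray(zones)
    ref_mask = movie.masks[movie.reference_index].mask
    if zones.shape != ref_mask.shape:
        raise ValueError("zone labels must match the frame shape")
    if np.any((zones > 0) & ~ref_mask):
        raise ValueError("zones must lie inside the reference cell mask")
    T = movie.spec.n_frames
    rng = np.random.default_rng(movie.spec.seed + 7919)
    series = np.zeros((T, *ref_mask.shape))
    noise = rng.standard_normal((T, *ref_mask.shape))
    series[:, ref_mask] = noise[:, ref_mask]
    w = np.sqrt(rho)
    start = 0 if switch_frame is None else int(switch_frame)
    for zone in np.unique(zones[zones > 0]):
        sel = zones == zone
        latent = rng.standard_normal(T)
        mixed = w * latent[:, None] + np.sqrt(1.0 - rho) * noise[:, sel]
        series[start:, sel] = mixed[start:]
    intensity = np.where(
        ref_mask[None], np.clip(baseline + amplitude * series, 0.0, None), 0.0
    )
    movie.channels[channel] = MovieStack(
        frames=intensity,
        channel_name=channel,
        pixel_size=movie.spec.pixel_size,
        frame_interval=movie.spec.frame_interval,
    )
    movie.planted["coherence"] = {
        "rho": rho,
        "switch_frame": switch_frame,
        "channel": channel,
    }
    return movie


def plant_entropy_phases(
    movie: PhantomMovie,
    region: np.ndarray,
    high_phase: tuple[int, int],
    channel: str = "planted_entropy",
) -> PhantomMovie:
    """Add a channel with a high-entropy phase planted in a region.

    Outside ``region`` (and outside the phase window) every pixel's series
    is exactly constant (0 bits). Inside the region during
    ``high_phase = (t0, t1)`` the series are i.i.d. uniform on [0, 1]
    (maximal-entropy draws for equal-width binning).
    """
    region = np.asarray(region, dtype=bool)
    ref_mask = movie.masks[movie.reference_index].mask
    if region.shape != ref_mask.shape:
        raise ValueError("region must match the frame shape")
    t0, t1 = high_phase
    T = movie.spec.n_frames
    if not 0 <= t0 < t1 <= T:
        raise ValueError("high_phase must lie within the movie")
    rng = np.random.default_rng(movie.spec.seed + 104729)
    frames = np.full((T, *ref_mask.shape), 0.5)
    frames[t0:t1, region] = rng.uniform(0.0, 1.0, size=(t1 - t0, int(region.sum())))
    frames[:, ~ref_mask] = 0.0
    movie.channels[channel] = MovieStack(
        frames=frames,
        channel_name=channel,
        pixel_size=movie.spec.pixel_size,
        frame_interval=movie.spec.frame_interval,
    )
    movie.planted["entropy"] = {"high_phase": (t0, t1), "channel": channel}
    return movie


def preset_spec(name: str, seed: int = 7, **overrides) -> PhantomSpec:
    """Named phantom presets mirroring the imaging scenarios of interest."""
    presets = {
        "diffuse-fiducial": dict(fiducial_kind="diffuse", warp_kind="smooth-random"),
        "punctate-fiducial": dict(fiducial_kind="punctate", warp_kind="smooth-random"),
        "symmetry-breaking": dict(
            fiducial_kind="diffuse", warp_kind="protrusion", warp_amplitude=5.0
        ),
    }
    if name not in presets:
        raise ValueError(f"unknown preset '{name}'; choose from {sorted(presets)}")
    params = {**presets[name], "seed": seed, **overrides}
    return PhantomSpec(**params)
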