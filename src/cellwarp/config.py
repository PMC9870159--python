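"""Run configuration: validation, YAML round-trip, provenance record.

A :class:`RunConfig` bundles every tunable of a registration + analysis run
— demons parameters, masking parameters, fluctuation-analysis parameters,
physical metadata and the random seed — validates them before any
computation, and writes a serialized copy (``run_config.yaml``) into the
output directory so any run can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .demons import DemonsConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All parameters of a registration/analysis run.

    Defaults mirror the published pipeline parameters: α = 1,
    K_diff = 1.5 px, n = 200 iterations per target frame (100 for the
    sequential preset, 2000 for first-to-last jumps), lowpass fiducial
    σ = 20 px, rolling windows of 25 frames, 8 entropy bins, zone bands
    0–1.2 / 3.6–6 / 8.4–12 μm from the cell edge.
    """

    # demons
    alpha: float = 1.0
    k_diff_sigma: float = 1.5
    n_iterations: int = 200
    enforce_diffeomorphism: bool = True
    use_mask_term: bool = True
    mask_weight: float = 1.0
    interpolation: str = "linear"
    # registration
    reference_index: int | None = None  # None -> center frame
    lowpass_sigma: float = 20.0
    # masking
    mask_smooth_sigma: float = 2.0
    mask_threshold: float | None = None  # None -> Otsu
    # fluctuation analysis
    window: int = 25
    n_bins: int = 8
    superpixel: int = 1
    zones_um: tuple = ((0.0, 1.2), (3.6, 6.0), (8.4, 12.0))
    max_lag: int = 5
    phases: str | None = None  # e.g. "thirds"
    # physical metadata
    pixel_size: float = 1.0
    frame_interval: float = 1.0
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        self.demons()  # validates the demons block
        if self.lowpass_sigma <= 0:
            raise ValueError("lowpass_sigma must be > 0")
        if self.window < 3:
            raise ValueError("window must be >= 3")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.superpixel < 1:
            raise ValueError("superpixel must be >= 1")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    def demons(self) -> DemonsConfig:
        """The demons-engine view of this configuration."""
        return DemonsConfig(
            alpha=self.alpha,
            k_diff_sigma=self.k_diff_sigma,
            n_iterations=self.n_iterations,
            enforce_diffeomorphism=self.enforce_diffeomorphism,
            use_mask_term=self.use_mask_term,
            mask_weight=self.mask_weight,
            interpolation=self.interpolation,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["zones_um"] = [list(z) for z in self.zones_um]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "zones_um" in d:
            d = {**d, "zones_um": tuple(tuple(z) for z in d["zones_um"])}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise IOError(f"config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def save(self, out_dir) -> Path:
        """Write the provenance copy ``run_config.yaml`` into ``out_dir``."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "run_config.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path
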