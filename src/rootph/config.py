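"""Run configuration.

The defaults encode the measurement geometry used throughout: ratios are
sampled in a band 10-25 px off the root surface and averaged in bins that
are 20 px long along the root axis (by construction 15 px deep radially,
the full band width).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import InputError


@dataclass
class RunConfig:
    """Parameters shared by the whole pipeline.

    Attributes
    ----------
    band_min_px, band_max_px
        Radial extent of the surface sampling band, in pixels off the
        segmented root surface (Euclidean distance).
    bin_length_px
        Longitudinal bin length along the midline, in pixels.
    background_488, background_405
        Constant per-channel background offsets subtracted before any
        ratio is formed.
    threshold_method
        Segmentation threshold for the summed channels ("otsu" only).
    flatfield_sigma_px
        Scale of the pseudo-flat-field correction: the summed image is
        divided by its own large-Gaussian blur before thresholding,
        which makes segmentation robust to smooth illumination
        gradients (0 disables).
    min_area_px
        Smallest connected dark component accepted as a root.
    closing_radius_px
        Radius of the morphological closing applied to the raw mask.
    min_bin_pixels
        Bins with fewer pixels are flagged invalid and excluded from
        statistics (stabilises means near the tip).
    max_distance_um
        Profiles are truncated at this distance from the tip.
    pixel_size_um, frame_interval_min
        Spatial/temporal sampling; overridden by TIFF metadata when
        present there.
    channel_488, channel_405
        Index of each excitation channel in the stored stack; explicit
        mapping, never inferred from intensities.
    max_tip_jump_um
        Frame-to-frame tip displacement above which tracking flags the
        frame as failed.
    random_seed
        Seed for every stochastic step (bootstrap, simulation).
    """

    band_min_px: int = 10
    band_max_px: int = 25
    bin_length_px: int = 20
    background_488: float = 0.0
    background_405: float = 0.0
    threshold_method: str = "otsu"
    flatfield_sigma_px: float = 50.0
    min_area_px: int = 200
    closing_radius_px: int = 2
    min_bin_pixels: int = 30
    max_distance_um: float = 1000.0
    pixel_size_um: Optional[float] = None
    frame_interval_min: Optional[float] = None
    channel_488: int = 0
    channel_405: int = 1
    max_tip_jump_um: float = 100.0
    calibration_path: Optional[str] = None
    random_seed: Optional[int] = None

    @property
    def band_width_px(self) -> int:
        """Radial bin depth: the full band width (default 25-10 = 15 px)."""
        return self.band_max_px - self.band_min_px

    def __post_init__(self) -> None:
        if not (0 < self.band_min_px < self.band_max_px):
            raise InputError(
                f"band bounds must satisfy 0 < band_min_px < band_max_px, "
                f"got ({self.band_min_px}, {self.band_max_px})"
            )
        if self.bin_length_px < 1:
            raise InputError("bin_length_px must be >= 1")
        if self.background_488 < 0 or self.background_405 < 0:
            raise InputError("backgrounds must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
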