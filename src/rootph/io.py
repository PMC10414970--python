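"""Readers and writers for the pipeline's external formats.

Image stacks are multi-page TIFF interpreted as (T, C, Y, X) or (C, Y, X)
with the two excitation channels (488 nm, 405 nm) mapped by explicit
config indices.  Tables are plain CSV with fixed headers; nested results
(kinetics, manifests) are JSON.  Loading never rescales or clips
intensity values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .config import RunConfig
from .errors import FormatError, InputError, InsufficientStandardsError, StructuralError

logger = logging.getLogger("rootph")

#: gravity points along +y (image "down") unless stated otherwise
DEFAULT_GRAVITY = np.array([1.0, 0.0])  # (dy, dx)


@dataclass
class ChannelStack:
    """Two-excitation-channel image time series.

    ``data`` has shape (T, 2, Y, X) with channel 0 = excitation 488 nm
    and channel 1 = excitation 405 nm, in arbitrary nonnegative units.
    ``gravity_vector`` is a unit (dy, dx) vector in image coordinates.
    """

    data: np.ndarray
    pixel_size_um: float = 1.0
    frame_interval_min: Optional[float] = None
    gravity_vector: np.ndarray = field(default_factory=lambda: DEFAULT_GRAVITY.copy())

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[None]
        if self.data.ndim != 4 or self.data.shape[1] != 2:
            raise StructuralError(
                f"stack must have shape (T, 2, Y, X); got {self.data.shape}"
            )
        if self.data.min() < 0:
            raise StructuralError("stack intensities must be >= 0")
        if self.pixel_size_um <= 0:
            raise InputError("pixel_size_um must be > 0")
        g = np.asarray(self.gravity_vector, dtype=float)
        n = np.linalg.norm(g)
        if n == 0:
            raise InputError("gravity_vector must be nonzero")
        self.gravity_vector = g / n

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape[2:]

    def frame(self, t: int) -> np.ndarray:
        """(2, Y, X) array of frame ``t`` (488 first, 405 second)."""
        return self.data[t]

    def i488(self, t: int = 0) -> np.ndarray:
        return self.data[t, 0]

    def i405(self, t: int = 0) -> np.ndarray:
        return self.data[t, 1]

    def times_min(self) -> np.ndarray:
        dt = self.frame_interval_min if self.frame_interval_min else 1.0
        return np.arange(self.n_frames) * dt


def load_stack(path: str | Path, config: Optional[RunConfig] = None) -> ChannelStack:
    """Read a two-channel TIFF stack.

    Accepts (T, C, Y, X) or (C, Y, X) layouts; the config's
    ``channel_488``/``channel_405`` indices select the excitation
    channels.  Pixel size and frame interval come from the TIFF's shaped
    metadata when present, otherwise from the config; a missing pixel
    size falls back to 1 um/px with a logged warning (positions are then
    effectively in pixels).
    """
    config = config or RunConfig()
    path = Path(path)
    if not path.exists():
        raise InputError(f"stack file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            meta = {}
            if tf.shaped_metadata:
                meta = dict(tf.shaped_metadata[0])
    except (tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"unreadable TIFF {path}: {exc}") from exc

    if arr.ndim == 2:
        raise StructuralError(
            f"{path}: single-channel image; the 405 nm excitation channel is missing"
        )
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4:
        raise StructuralError(f"{path}: cannot interpret shape {arr.shape} as (T,C,Y,X)")
    n_chan = arr.shape[1]
    if n_chan % 2 != 0:
        raise StructuralError(f"{path}: odd channel count {n_chan}")
    if max(config.channel_488, config.channel_405) >= n_chan:
        raise StructuralError(
            f"{path}: channel mapping ({config.channel_488}, {config.channel_405}) "
            f"exceeds channel count {n_chan}"
        )
    data = np.stack(
        [arr[:, config.channel_488], arr[:, config.channel_405]], axis=1
    )

    pixel_size = meta.get("pixel_size_um") or config.pixel_size_um
    if pixel_size is None:
        logger.warning(
            "%s: no pixel size in metadata or config; using 1 um/px "
            "(positions will be in pixels)", path
        )
        pixel_size = 1.0
    interval = meta.get("frame_interval_min", config.frame_interval_min)
    gravity = meta.get("gravity_vector")
    gravity = np.asarray(gravity, float) if gravity is not None else DEFAULT_GRAVITY.copy()
    return ChannelStack(
        data=data,
        pixel_size_um=float(pixel_size),
        frame_interval_min=float(interval) if interval is not None else None,
        gravity_vector=gravity,
    )


def save_stack(stack: ChannelStack, path: str | Path) -> None:
    """Write a stack as shaped (T, 2, Y, X) TIFF with metadata.

    Arrays are written verbatim (no dtype change), so a save/load round
    trip is bit-identical.
    """
    meta = {
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_min": stack.frame_interval_min,
        "gravity_vector": [float(v) for v in stack.gravity_vector],
    }
    tifffile.imwrite(Path(path), stack.data, metadata=meta)


PROFILE_COLUMNS = ["position_um", "side", "n_pixels", "mean_ratio", "sd_ratio", "pH"]


def save_profile(profile, path: str | Path) -> None:
    """Write a :class:`~rootph.profiling.PHProfile` as CSV.

    Columns: position_um, side, n_pixels, mean_ratio, sd_ratio, pH (the
    pH column stays empty when the profile is uncalibrated).  Read-back
    reproduces values to full float precision.
    """
    df = profile.to_frame()
    if len(df) == 0:
        raise InputError("refusing to write an empty profile")
    out = df[PROFILE_COLUMNS].copy()
    out.to_csv(Path(path), index=False, float_format="%.17g")


def load_profile(path: str | Path):
    from .profiling import PHProfile

    path = Path(path)
    if not path.exists():
        raise InputError(f"profile file not found: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error variety
        raise FormatError(f"cannot parse profile CSV {path}: {exc}") from exc
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise StructuralError(f"{path}: missing profile columns {sorted(missing)}")
    if "valid" not in df.columns:
        # the CSV schema does not carry the flag; re-derive it with the
        # default minimum bin occupancy
        df["valid"] = np.isfinite(df.mean_ratio) & (
            df.n_pixels >= RunConfig().min_bin_pixels
        )
    return PHProfile(df)


def load_calibration_table(path: str | Path) -> pd.DataFrame:
    """Read (pH, ratio) standards from CSV.

    Standards are sorted by pH; duplicate pH rows are averaged.  At
    least three distinct pH values are required.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"calibration file not found: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"cannot parse calibration CSV {path}: {exc}") from exc
    cols = {c.lower(): c for c in df.columns}
    if "ph" not in cols or "ratio" not in cols:
        raise StructuralError(f"{path}: calibration CSV needs columns pH, ratio")
    df = df.rename(columns={cols["ph"]: "pH", cols["ratio"]: "ratio"})[["pH", "ratio"]]
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric calibration cells: {exc}") from exc
    df = df.groupby("pH", as_index=False)["ratio"].mean().sort_values("pH")
    if len(df) < 3:
        raise InsufficientStandardsError(
            f"{path}: need >= 3 distinct pH standards, got {len(df)}"
        )
    return df.reset_index(drop=True)


PENETRATION_COLUMNS = ["genotype", "pore_size_um", "n_penetrated", "n_total", "replicate"]


def load_penetration_table(path: str | Path) -> pd.DataFrame:
    """Read a mesh-penetration count table (genotype x pore size x replicate)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"penetration table not found: {path}")
    df = pd.read_csv(path)
    missing = set(PENETRATION_COLUMNS) - set(df.columns)
    if missing:
        raise StructuralError(f"{path}: missing columns {sorted(missing)}")
    if ((df.n_penetrated < 0) | (df.n_penetrated > df.n_total)).any():
        raise StructuralError(f"{path}: need 0 <= n_penetrated <= n_total")
    return df


def save_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)


def load_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
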