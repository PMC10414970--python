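"""Time-series analysis: tracking, elongation, tip angle, flank asymmetry.

The tip angle is the unsigned angle between the tip tangent (least-
squares line through the 25 midline points nearest the tip) and the
gravity vector: after a 90 deg rotation a gravistimulated root starts
near 90 deg and approaches 0 as it realigns.  Flank ("lower"/"upper")
ratios are band means within a longitudinal window, split by the sign of
each pixel's displacement from the midline projected on gravity, so the
same code serves vertical and gravistimulated sessions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal

from .config import RunConfig
from .errors import (
    AnalysisError,
    InsufficientSeriesError,
    TrackingLostError,
    WindowError,
)
from .geometry import RootGeometry, SurfaceBand, compute_geometry, extract_surface_band, segment_root
from .io import ChannelStack

logger = logging.getLogger("rootph")

MAX_CONSECUTIVE_FAILURES = 2


@dataclass
class KineticsTrack:
    """Per-frame geometry plus the stack it came from."""

    stack: ChannelStack
    config: RunConfig
    times_min: np.ndarray
    geometries: list            # RootGeometry or None per frame
    failed: np.ndarray          # bool per frame
    bands: list = field(default_factory=list)  # lazy SurfaceBand cache

    @property
    def n_frames(self) -> int:
        return len(self.times_min)

    def valid_frames(self) -> np.ndarray:
        return np.nonzero(~self.failed)[0]

    def band(self, t: int) -> SurfaceBand:
        if not self.bands:
            self.bands = [None] * self.n_frames
        if self.bands[t] is None:
            if self.geometries[t] is None:
                raise AnalysisError(f"frame {t} has no geometry (tracking failed)")
            self.bands[t] = extract_surface_band(
                self.geometries[t], self.stack.frame(t), self.config
            )
        return self.bands[t]


def track_root(stack: ChannelStack, config: Optional[RunConfig] = None) -> KineticsTrack:
    """Segment every frame independently and link tips across frames.

    Frames where segmentation or geometry fails, or where the tip jumps
    more than ``max_tip_jump_um``, are flagged; up to two consecutive
    flagged frames are tolerated (scalar series interpolate over them),
    more raise :class:`TrackingLostError`.
    """
    config = config or RunConfig()
    if stack.n_frames < 2:
        raise AnalysisError("tracking needs >= 2 frames")
    px = stack.pixel_size_um
    geoms: list = []
    failed = np.zeros(stack.n_frames, dtype=bool)
    prev_tip = None
    for t in range(stack.n_frames):
        try:
            mask = segment_root(stack.frame(t), config)
            geo = compute_geometry(mask, px, stack.gravity_vector)
        except AnalysisError as exc:
            logger.warning("frame %d failed: %s", t, exc)
            geoms.append(None)
            failed[t] = True
            continue
        if prev_tip is not None:
            jump_um = np.linalg.norm(geo.tip - prev_tip) * px
            if jump_um > config.max_tip_jump_um:
                logger.warning("frame %d: tip jumped %.1f um; flagged", t, jump_um)
                geoms.append(None)
                failed[t] = True
                continue
        geoms.append(geo)
        prev_tip = geo.tip
    # consecutive-failure guard
    run = 0
    for f in failed:
        run = run + 1 if f else 0
        if run > MAX_CONSECUTIVE_FAILURES:
            raise TrackingLostError(
                f"more than {MAX_CONSECUTIVE_FAILURES} consecutive frames failed"
            )
    if failed.all():
        raise TrackingLostError("no frame could be tracked")
    return KineticsTrack(
        stack=stack, config=config, times_min=stack.times_min(),
        geometries=geoms, failed=failed,
    )


def _interp_series(times: np.ndarray, values: np.ndarray, failed: np.ndarray) -> np.ndarray:
    out = values.astype(float).copy()
    if failed.any() and (~failed).sum() >= 2:
        out[failed] = np.interp(times[failed], times[~failed], values[~failed])
    return out


def elongation_rate(track: KineticsTrack) -> float:
    """Total midline length increment between first and last valid frames
    divided by the elapsed minutes (um/min)."""
    valid = track.valid_frames()
    if len(valid) < 2:
        raise AnalysisError("elongation rate needs >= 2 valid frames")
    first, last = valid[0], valid[-1]
    l0 = track.geometries[first].length_um
    l1 = track.geometries[last].length_um
    dt = track.times_min[last] - track.times_min[first]
    if dt <= 0:
        raise AnalysisError("non-increasing time axis")
    if l1 - l0 < -0.05 * l0:
        warnings.warn(
            f"root length decreased by {l0 - l1:.1f} um; possible registration failure",
            stacklevel=2,
        )
    return (l1 - l0) / dt


def tip_angle_series(track: KineticsTrack, smooth: bool = False) -> pd.DataFrame:
    """Unsigned tip angle vs gravity per frame, degrees in [0, 180]."""
    g = track.stack.gravity_vector
    angles = np.full(track.n_frames, np.nan)
    for t in track.valid_frames():
        tangent = track.geometries[t].tip_tangent
        cosang = np.clip(tangent @ g, -1.0, 1.0)
        angles[t] = np.degrees(np.arccos(cosang))
    angles = _interp_series(track.times_min, angles, track.failed)
    if smooth and track.n_frames >= 3:
        angles = signal.medfilt(angles, 3)
    return pd.DataFrame({"time_min": track.times_min, "angle_deg": angles})


def angular_rate(series: pd.DataFrame) -> float:
    """Least-squares slope of the tip-angle series (deg/min)."""
    return float(np.polyfit(series.time_min, series.angle_deg, 1)[0])


def flank_ratio_series(
    track: KineticsTrack,
    window_um: tuple[float, float] = (200.0, 500.0),
    gravity_vector: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Lower/upper flank mean ratios within a longitudinal window.

    Per frame, band pixels with arc length in ``window_um`` are split by
    the sign of their midline displacement projected on gravity (positive
    = lower flank); flank means are ratios of summed intensities.
    """
    g = gravity_vector if gravity_vector is not None else track.stack.gravity_vector
    lo, hi = window_um
    rows = []
    for t in range(track.n_frames):
        rec = dict(time_min=track.times_min[t], lower_mean_ratio=np.nan,
                   upper_mean_ratio=np.nan, lower_over_upper=np.nan,
                   flagged=bool(track.failed[t]))
        if not track.failed[t]:
            band = track.band(t)
            if band.s_um.max() < lo:
                raise WindowError(
                    f"window {window_um} um lies beyond the measured root "
                    f"extent ({band.s_um.max():.0f} um) at frame {t}"
                )
            sel = (band.s_um >= lo) & (band.s_um < hi)
            sub = band.select(sel)
            proj = sub.offset_yx @ g
            for name, mask in (("lower", proj > 0), ("upper", proj < 0)):
                if mask.sum() == 0 or sub.i405[mask].sum() <= 0:
                    rec["flagged"] = True
                    continue
                rec[f"{name}_mean_ratio"] = sub.i488[mask].sum() / sub.i405[mask].sum()
            if np.isfinite(rec["lower_mean_ratio"]) and np.isfinite(rec["upper_mean_ratio"]):
                rec["lower_over_upper"] = rec["lower_mean_ratio"] / rec["upper_mean_ratio"]
        rows.append(rec)
    return pd.DataFrame(rows)


def detect_flank_onset(
    series: pd.DataFrame,
    baseline_frames: int = 3,
    sd_floor: float = 0.002,
    n_consecutive: int = 2,
) -> Optional[float]:
    """First time the lower/upper ratio exceeds 1 + 3*(baseline SD).

    The threshold must be exceeded for ``n_consecutive`` frames; the
    baseline SD comes from the first ``baseline_frames`` frames with a
    small floor so a noise-free symmetric series does not trigger on
    rounding error.  Returns the onset time in minutes, or None.
    """
    r = series.lower_over_upper.to_numpy()
    t = series.time_min.to_numpy()
    base = r[:baseline_frames]
    base = base[np.isfinite(base)]
    if len(base) == 0:
        raise AnalysisError("no finite baseline frames for onset detection")
    thr = 1.0 + 3.0 * max(float(np.std(base)), sd_floor)
    above = np.isfinite(r) & (r > thr)
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= n_consecutive:
            return float(t[i - n_consecutive + 1])
    return None


def oscillation_trace(
    track: KineticsTrack,
    window_um: tuple[float, float] = (200.0, 500.0),
) -> dict:
    """Detrended windowed ratio trace and its dominant period.

    Needs >= 64 frames at a fixed interval.  Returns the per-frame mean
    ratio in the window, the linearly detrended trace, the periodogram
    peak period (minutes) and amplitude, and a left/right asymmetry
    trace.
    """
    if track.n_frames < 64:
        raise InsufficientSeriesError(
            f"oscillation analysis needs >= 64 frames, got {track.n_frames}"
        )
    lo, hi = window_um
    mean_ratio = np.full(track.n_frames, np.nan)
    lr_ratio = np.full(track.n_frames, np.nan)
    for t in track.valid_frames():
        band = track.band(t)
        sel = (band.s_um >= lo) & (band.s_um < hi)
        sub = band.select(sel)
        if len(sub) and sub.i405.sum() > 0:
            mean_ratio[t] = sub.i488.sum() / sub.i405.sum()
        for_side = {}
        for name, sd in (("left", 1), ("right", -1)):
            m = sub.side == sd
            for_side[name] = (sub.i488[m].sum() / sub.i405[m].sum()
                              if m.any() and sub.i405[m].sum() > 0 else np.nan)
        lr_ratio[t] = for_side["left"] / for_side["right"]
    mean_ratio = _interp_series(track.times_min, mean_ratio, ~np.isfinite(mean_ratio))
    detrended = signal.detrend(mean_ratio)
    dt = float(np.median(np.diff(track.times_min)))
    freqs, power = signal.periodogram(detrended, fs=1.0 / dt)
    k = int(np.argmax(power[1:])) + 1
    period = 1.0 / freqs[k] if freqs[k] > 0 else np.inf
    amplitude = float(np.sqrt(2.0 * power[k] * freqs[1]))
    return {
        "time_min": track.times_min,
        "mean_ratio": mean_ratio,
        "detrended": detrended,
        "dominant_period_min": float(period),
        "amplitude": amplitude,
        "left_over_right": lr_ratio,
    }
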