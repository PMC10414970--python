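"""Synthetic microscopy phantoms with accessible ground truth.

A phantom emulates a dye-stained imaging session: a dark (dye-excluded)
root embedded in bright stained medium, a longitudinal surface-pH field
(acidic tip dip, Gaussian alkaline halo around the transition zone,
acidic baseline relative to the medium), pH-dependent per-channel
emission derived from a forward logistic calibration so that
I488/I405 = ratio(pH), a shared multiplicative illumination field,
and Poisson + Gaussian read noise.  Time series add growth (tipward
extension) and gravitropic bending about an elongation-zone pivot, with
an optional lower-flank pH offset switching on at a programmed time.

The surface pH is held constant through a radial plateau that covers the
sampling band (10-25 px) and decays exponentially beyond it, so the
band reports the programmed pH(s) exactly when noise is off.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from .calibration import logistic_ratio
from .errors import PhantomSpecError
from .io import ChannelStack

PH_DOMAIN = (4.0, 7.5)  # plausible dye response range enforced on specs


@dataclass
class PhantomSpec:
    """Full description of a synthetic acquisition (all units stated)."""

    # geometry
    image_shape: tuple = (768, 256)        # (Y, X) pixels
    pixel_size_um: float = 1.0
    root_radius_px: float = 15.0
    tip_taper_um: float = 60.0             # radius ramps up over this arc length
    root_length_um: float = 650.0
    initial_angle_deg: float = 0.0         # tip axis vs gravity (+y)
    pivot_um: float = 450.0                # bend pivot, distance from tip
    # surface pH field
    medium_ph: float = 5.7
    baseline_ph: float = 5.2
    halo_center_um: float = 350.0
    halo_sigma_um: float = 60.0
    halo_amplitude_ph: float = 0.5
    tip_dip_amplitude_ph: float = -0.25
    tip_dip_center_um: float = 30.0
    tip_dip_sigma_um: float = 25.0
    halo_plateau_px: float = 30.0          # radial extent of undiluted surface pH
    halo_decay_px: float = 30.0
    flank_offset_ph: float = 0.0           # added to the lower flank...
    flank_onset_min: float = 0.0           # ...from this time on
    treatment_offset_ph: float = 0.0       # step offset inside a window...
    treatment_window_um: tuple = (200.0, 500.0)  # ...of arc length from tip
    oscillation_rel_amplitude: float = 0.0  # relative halo-amplitude modulation
    oscillation_period_min: float = 2.0
    # forward optics
    cal_r_lo: float = 0.2
    cal_r_hi: float = 2.7
    cal_pka: float = 6.4
    cal_slope: float = 1.0
    i405_counts: float = 400.0
    root_counts: float = 10.0
    background_488: float = 0.0
    background_405: float = 0.0
    illumination: str = "none"             # "none" | "gradient"
    illum_min: float = 0.5
    illum_max: float = 1.5
    noise: bool = True
    read_noise_sd: float = 2.0
    # dynamics
    n_frames: int = 1
    frame_interval_min: float = 1.0
    growth_px_per_frame: float = 0.0
    bend_rate_deg_per_min: float = 0.0
    seed: int = 0

    def forward_ratio(self, ph):
        """The phantom's forward optics: F488/405 ratio at a given pH."""
        return logistic_ratio(np.asarray(ph, float),
                              self.cal_r_lo, self.cal_r_hi,
                              self.cal_pka, self.cal_slope)

    def to_yaml(self, path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in dataclasses.asdict(self).items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise PhantomSpecError(f"unknown phantom spec keys: {sorted(unknown)}")
        for key in ("image_shape", "treatment_window_um"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-frame truth exposed alongside the rendered stack."""

    spec: PhantomSpec
    masks: list = field(default_factory=list)
    centerlines: list = field(default_factory=list)   # (N, 2), tip-first
    tips: list = field(default_factory=list)
    angles_deg: list = field(default_factory=list)    # tip axis vs gravity
    lengths_um: list = field(default_factory=list)

    def ph_at(self, s_um, frame: int = 0) -> np.ndarray:
        """Programmed surface pH at arc length ``s_um`` (no flank offset)."""
        t_min = frame * self.spec.frame_interval_min
        return _surface_ph(self.spec, np.asarray(s_um, float), t_min)

    def to_json_dict(self) -> dict:
        return {
            "angles_deg": [float(a) for a in self.angles_deg],
            "lengths_um": [float(v) for v in self.lengths_um],
            "tips": [t.tolist() for t in self.tips],
            "spec": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in dataclasses.asdict(self.spec).items()},
        }


def _direction(angle_deg: float) -> np.ndarray:
    """Unit (dy, dx) vector at a given unsigned angle from gravity (+y)."""
    a = np.deg2rad(angle_deg)
    return np.array([np.cos(a), np.sin(a)])


def _surface_ph(spec: PhantomSpec, s_um: np.ndarray, t_min: float) -> np.ndarray:
    amp = spec.halo_amplitude_ph
    if spec.oscillation_rel_amplitude:
        amp = amp * (1.0 + spec.oscillation_rel_amplitude
                     * np.sin(2 * np.pi * t_min / spec.oscillation_period_min))
    ph = (spec.baseline_ph
          + amp * np.exp(-0.5 * ((s_um - spec.halo_center_um) / spec.halo_sigma_um) ** 2)
          + spec.tip_dip_amplitude_ph
          * np.exp(-0.5 * ((s_um - spec.tip_dip_center_um) / spec.tip_dip_sigma_um) ** 2))
    if spec.treatment_offset_ph:
        lo, hi = spec.treatment_window_um
        ph = ph + np.where((s_um >= lo) & (s_um < hi), spec.treatment_offset_ph, 0.0)
    return ph


def _centerline(spec: PhantomSpec, t: int) -> tuple[np.ndarray, float]:
    """Polyline from entry border to tip for frame ``t``; returns (points, angle)."""
    px = spec.pixel_size_um
    theta = spec.initial_angle_deg + spec.bend_rate_deg_per_min * t * spec.frame_interval_min
    total0 = spec.root_length_um / px
    pivot = min(spec.pivot_um / px, 0.8 * total0)
    base_len = total0 - pivot
    distal_len = pivot + spec.growth_px_per_frame * t

    h, w = spec.image_shape
    d0 = _direction(spec.initial_angle_deg)
    if abs(spec.initial_angle_deg) < 45:
        entry = np.array([0.0, w / 2.0])
    else:
        entry = np.array([h / 3.0, 0.0])
    dt = _direction(theta)
    n_base = max(int(np.ceil(base_len)), 1)
    n_dist = max(int(np.ceil(distal_len)), 1)
    base = entry + np.outer(np.linspace(0, base_len, n_base + 1), d0)
    pivot_pt = base[-1]
    dist = pivot_pt + np.outer(np.linspace(0, distal_len, n_dist + 1)[1:], dt)
    pts = np.vstack([base, dist])

    margin = 35.0  # room for the sampling band around the tip
    tip = pts[-1]
    if not (margin <= tip[0] < h - margin and margin <= tip[1] < w - margin):
        need_h = int(tip[0] + 2 * margin)
        need_w = int(tip[1] + 2 * margin)
        raise PhantomSpecError(
            f"frame {t}: root tip {tip.round(1)} leaves the usable field "
            f"{spec.image_shape}; try image_shape >= ({need_h}, {need_w})"
        )
    return pts, float(theta)


def _render_frame(spec: PhantomSpec, t: int, rng: np.random.Generator,
                  truth: GroundTruth) -> np.ndarray:
    px = spec.pixel_size_um
    h, w = spec.image_shape
    pts, theta = _centerline(spec, t)

    # arc length from tip, in um
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    s_from_tip_um = (arc[-1] - arc) * px

    yy, xx = np.mgrid[0:h, 0:w]
    coords = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    tree = cKDTree(pts)
    dist, idx = tree.query(coords)
    s_um = s_from_tip_um[idx]

    taper_um = max(spec.tip_taper_um, 1e-9)
    radius = spec.root_radius_px * np.sqrt(np.clip(s_um / taper_um, 0.0, 1.0))
    mask = (dist <= radius).reshape(h, w)

    d_surf = np.clip(dist - radius, 0.0, None)
    ph_surf = _surface_ph(spec, s_um, t * spec.frame_interval_min)
    if spec.flank_offset_ph and t * spec.frame_interval_min >= spec.flank_onset_min:
        offset = coords - pts[idx]
        lower = offset[:, 0] > 0  # gravity is +y
        ph_surf = ph_surf + np.where(lower, spec.flank_offset_ph, 0.0)

    lo, hi = PH_DOMAIN
    if ph_surf.min() < lo or ph_surf.max() > hi or not lo <= spec.medium_ph <= hi:
        raise PhantomSpecError(
            f"programmed pH range [{ph_surf.min():.2f}, {ph_surf.max():.2f}] "
            f"leaves the dye response domain {PH_DOMAIN}"
        )

    wgt = np.exp(-np.clip(d_surf - spec.halo_plateau_px, 0.0, None) / spec.halo_decay_px)
    ph = spec.medium_ph + (ph_surf - spec.medium_ph) * wgt
    ratio = spec.forward_ratio(ph)

    if spec.illumination == "gradient":
        ramp = (yy + xx).astype(float) / (h + w - 2)
        illum = spec.illum_min + (spec.illum_max - spec.illum_min) * ramp
    elif spec.illumination == "none":
        illum = np.ones((h, w))
    else:
        raise PhantomSpecError(f"unknown illumination model: {spec.illumination!r}")

    i405 = (spec.i405_counts * illum).ravel()
    i488 = i405 * ratio
    flat_mask = mask.ravel()
    i405 = np.where(flat_mask, spec.root_counts, i405)
    i488 = np.where(flat_mask, spec.root_counts, i488)
    i488 = i488 + spec.background_488
    i405 = i405 + spec.background_405

    frame = np.stack([i488.reshape(h, w), i405.reshape(h, w)])
    if spec.noise:
        frame = rng.poisson(frame).astype(float)
        frame = frame + rng.normal(0.0, spec.read_noise_sd, frame.shape)
        frame = np.clip(frame, 0.0, None)

    truth.masks.append(mask)
    tip_first = pts[::-1].copy()
    truth.centerlines.append(tip_first)
    truth.tips.append(pts[-1].copy())
    truth.angles_deg.append(abs(theta))
    truth.lengths_um.append(float(arc[-1] * px))
    return frame.astype(np.float32)


def make_phantom(spec: Optional[PhantomSpec] = None) -> tuple[ChannelStack, GroundTruth]:
    """Render a phantom stack and its ground truth (bit-reproducible by seed)."""
    spec = spec or PhantomSpec()
    if spec.n_frames < 1:
        raise PhantomSpecError("n_frames must be >= 1")
    rng = np.random.default_rng(spec.seed)
    truth = GroundTruth(spec=spec)
    frames = [_render_frame(spec, t, rng, truth) for t in range(spec.n_frames)]
    stack = ChannelStack(
        data=np.stack(frames),
        pixel_size_um=spec.pixel_size_um,
        frame_interval_min=spec.frame_interval_min if spec.n_frames > 1 else None,
        gravity_vector=np.array([1.0, 0.0]),
    )
    return stack, truth


def make_gravitropic_series(spec: Optional[PhantomSpec] = None) -> tuple[ChannelStack, GroundTruth]:
    """Phantom time series with bending and optional flank asymmetry.

    Same renderer as :func:`make_phantom`; this entry point validates
    that the spec describes a time series (>= 2 frames).
    """
    spec = spec or PhantomSpec(
        image_shape=(512, 768), initial_angle_deg=90.0,
        bend_rate_deg_per_min=-1.125, n_frames=21, frame_interval_min=2.0,
    )
    if spec.n_frames < 2:
        raise PhantomSpecError("a gravitropic series needs >= 2 frames")
    return make_phantom(spec)


def make_calibration_standards(
    spec: Optional[PhantomSpec] = None,
    ph_grid: Optional[np.ndarray] = None,
    noise_rel: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic (pH, ratio) standards from the forward optics.

    The default grid is pH 4.5-6.0 in 0.5 steps, the grid used for
    calibration media in this kind of assay; optional multiplicative
    Gaussian noise on the ratios is seeded.
    """
    spec = spec or PhantomSpec()
    ph_grid = np.asarray(
        ph_grid if ph_grid is not None else np.arange(4.5, 6.01, 0.5), float
    )
    ratio = spec.forward_ratio(ph_grid)
    if noise_rel:
        rng = np.random.default_rng(seed)
        ratio = ratio * (1.0 + noise_rel * rng.standard_normal(ph_grid.shape))
    return pd.DataFrame({"pH": ph_grid, "ratio": ratio})
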