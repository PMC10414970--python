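"""Shared fixtures: phantoms are rendered once per session and reused."""

from __future__ import annotations

import numpy as np
import pytest

import rootph as rp


def profile_from_stack(stack, config=None, calibration=None, frame=0):
    """Run the standard pipeline on one frame: segment -> band -> profile."""
    config = config or rp.RunConfig()
    mask = rp.segment_root(stack.frame(frame), config)
    geo = rp.compute_geometry(mask, stack.pixel_size_um, stack.gravity_vector)
    band = rp.extract_surface_band(geo, stack.frame(frame), config)
    return rp.bin_profile(band, config, stack.pixel_size_um, calibration=calibration)


@pytest.fixture(scope="session")
def run_profile():
    """The standard per-frame pipeline as a callable fixture."""
    return profile_from_stack


@pytest.fixture(scope="session")
def default_config():
    return rp.RunConfig()


@pytest.fixture(scope="session")
def forward_curve():
    """Calibration curve fitted to noise-free standards of the default optics."""
    std = rp.make_calibration_standards(rp.PhantomSpec(), np.arange(4.2, 6.81, 0.2))
    return rp.fit_calibration(std)


@pytest.fixture(scope="session")
def halo_phantom():
    """Static phantom: flat 5.2 baseline + alkaline halo (350 um, sigma 60,
    amplitude 0.5 pH), default noise."""
    spec = rp.PhantomSpec(tip_dip_amplitude_ph=0.0, seed=11)
    stack, truth = rp.make_phantom(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def halo_profile(halo_phantom, forward_curve, default_config):
    _, stack, _ = halo_phantom
    return profile_from_stack(stack, default_config, calibration=forward_curve)


@pytest.fixture(scope="session")
def bending_track():
    """Gravistimulated series: 90 deg start, -1.125 deg/min, 2 min frames."""
    spec = rp.PhantomSpec(
        image_shape=(560, 820), initial_angle_deg=90.0,
        bend_rate_deg_per_min=-1.125, n_frames=21, frame_interval_min=2.0,
        seed=21,
    )
    stack, truth = rp.make_gravitropic_series(spec)
    return truth, rp.track_root(stack)


@pytest.fixture(scope="session")
def flank_track():
    """Horizontal root with +0.4 pH on the lower flank from t = 5 min."""
    spec = rp.PhantomSpec(
        initial_angle_deg=90.0, image_shape=(560, 820),
        flank_offset_ph=0.4, flank_onset_min=5.0,
        n_frames=12, frame_interval_min=1.0, seed=6,
    )
    stack, truth = rp.make_phantom(spec)
    return truth, rp.track_root(stack)


@pytest.fixture(scope="session")
def symmetric_track():
    spec = rp.PhantomSpec(
        initial_angle_deg=90.0, image_shape=(560, 820),
        n_frames=6, frame_interval_min=1.0, seed=7,
    )
    stack, _ = rp.make_phantom(spec)
    return rp.track_root(stack)


def _group_profiles(n, seed0, offset):
    cfg = rp.RunConfig()
    out = []
    for k in range(n):
        spec = rp.PhantomSpec(seed=seed0 + k, tip_dip_amplitude_ph=0.0,
                              treatment_offset_ph=offset)
        stack, _ = rp.make_phantom(spec)
        out.append(profile_from_stack(stack, cfg))
    return out


@pytest.fixture(scope="session")
def comparison_groups():
    """Control group and a group with +0.3 pH only in 200-500 um, 10 roots each."""
    control = _group_profiles(10, 1000, 0.0)
    treated = _group_profiles(10, 2000, 0.3)
    return control, treated
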