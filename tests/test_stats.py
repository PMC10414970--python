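"""Rank statistics, alkalinization factor, domain detection, penetration."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rootph as rp
from rootph.errors import AlignmentError, AnalysisError, WindowError


def brute_force_effect(x, y):
    return sum((xi < yj) + 0.5 * (xi == yj) for xi in x for yj in y) / (len(x) * len(y))


def synth_profile(values, positions=None, side="both", n_pixels=200):
    positions = positions if positions is not None else 10.0 + 20.0 * np.arange(len(values))
    df = pd.DataFrame({
        "position_um": positions, "side": side, "n_pixels": n_pixels,
        "mean_ratio": values, "sd_ratio": 0.0, "pH": np.nan, "valid": True,
    })
    return rp.PHProfile(df)


def make_group(n, seed, bump=0.0, window=(200.0, 500.0), n_bins=33, sd=0.02):
    """Profiles: flat 0.35 ratio + between-root noise + optional window bump."""
    rng = np.random.default_rng(seed)
    pos = 10.0 + 20.0 * np.arange(n_bins)
    out = []
    for _ in range(n):
        v = 0.35 + sd * rng.standard_normal(n_bins)
        v = v + np.where((pos >= window[0]) & (pos < window[1]), bump, 0.0)
        out.append(synth_profile(v, pos))
    return out


class TestRankTest:
    def test_identical_samples(self):
        x = np.arange(10.0)
        eff, stat, p = rp.rank_test_two_sample(x, x.copy())
        assert eff == 0.5
        assert p > 0.9

    def test_all_tied_degenerate(self):
        eff, stat, p = rp.rank_test_two_sample(np.ones(6), np.ones(7))
        assert (eff, stat, p) == (0.5, 0.0, 1.0)

    def test_complete_separation(self):
        eff, stat, p = rp.rank_test_two_sample(np.arange(5.0), np.arange(10.0, 15.0))
        assert eff == 1.0
        assert p == 0.0

    def test_textbook_example_matches_enumeration(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 3, 4, 5, 6])
        eff, _, _ = rp.rank_test_two_sample(x, y)
        assert eff == brute_force_effect(x, y)

    @pytest.mark.parametrize("seed", range(8))
    def test_effect_equals_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = rng.integers(5, 9, 2)
        x = rng.integers(0, 5, nx).astype(float)
        y = rng.integers(0, 5, ny).astype(float)
        eff, _, _ = rp.rank_test_two_sample(x, y)
        assert eff == pytest.approx(brute_force_effect(x, y), abs=1e-12)

    def test_small_sample_rejected(self):
        with pytest.raises(AnalysisError):
            rp.rank_test_two_sample(np.arange(3.0), np.arange(8.0))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(8)
        y = rng.standard_normal(9) + 0.5
        eff0, _, p0 = rp.rank_test_two_sample(x, y)
        fx, fy = np.exp(3 * x), np.exp(3 * y)  # strictly monotone transform
        eff1, _, p1 = rp.rank_test_two_sample(fx, fy)
        assert eff1 == pytest.approx(eff0, abs=1e-12)
        assert p1 == pytest.approx(p0, rel=1e-9)


class TestAlkalinizationFactor:
    def test_self_comparison_is_unity(self):
        group = make_group(5, 0)
        af = rp.alkalinization_factor(group, group, n_boot=100, seed=1)
        assert np.allclose(af.af, 1.0)
        assert (af.ci_lo <= af.af).all() and (af.af <= af.ci_hi).all()

    def test_windowed_offset_detected(self):
        control = make_group(6, 1)
        treated = make_group(6, 2, bump=0.1)
        af = rp.alkalinization_factor(treated, control, n_boot=100, seed=2)
        inside = af[(af.position_um >= 220) & (af.position_um < 480)]
        outside = af[(af.position_um < 180) | (af.position_um >= 520)]
        assert (inside.af > 1.2).all()
        assert np.abs(outside.af - 1.0).max() < 0.1

    def test_scale_invariance(self):
        control = make_group(5, 3)
        treated = make_group(5, 4, bump=0.1)
        af1 = rp.alkalinization_factor(treated, control, n_boot=50, seed=5)
        scale = lambda ps: [synth_profile(p.values() * 7.3, p.positions()) for p in ps]
        af2 = rp.alkalinization_factor(scale(treated), scale(control), n_boot=50, seed=5)
        assert np.allclose(af1.af, af2.af)

    def test_disjoint_ranges_raise(self):
        a = [synth_profile(np.full(10, 0.4), 10.0 + 20 * np.arange(10))] * 3
        b = [synth_profile(np.full(10, 0.4), 400.0 + 20 * np.arange(10))] * 3
        with pytest.raises(AlignmentError):
            rp.alkalinization_factor(a, b)

    def test_too_few_profiles(self):
        g = make_group(2, 0)
        with pytest.raises(AnalysisError):
            rp.alkalinization_factor(g, g)


class TestAlkalineDomain:
    def _bump_profile(self, amp=0.5, center=350.0, sigma=60.0, noise=0.0, seed=0,
                      n_bins=40):
        pos = 10.0 + 20.0 * np.arange(n_bins)
        rng = np.random.default_rng(seed)
        v = 5.2 + amp * np.exp(-0.5 * ((pos - center) / sigma) ** 2)
        v = v + noise * rng.standard_normal(n_bins)
        return synth_profile(v, pos)

    def test_gaussian_bump_parameters_recovered(self):
        prof = self._bump_profile(noise=0.005, seed=1)
        dom = rp.detect_alkaline_domain(prof, (200, 500))
        assert dom is not None
        assert abs(dom.peak_position_um - 350.0) <= 20.0
        assert dom.amplitude == pytest.approx(0.5, rel=0.10)
        assert dom.fwhm_um == pytest.approx(2.355 * 60.0, rel=0.15)

    def test_flat_profile_has_no_domain(self):
        prof = self._bump_profile(amp=0.0, noise=0.01, seed=2)
        assert rp.detect_alkaline_domain(prof, (200, 500)) is None

    def test_truncated_bump_is_boundary_limited(self):
        prof = self._bump_profile(center=180.0, sigma=80.0, noise=0.003, seed=3)
        dom = rp.detect_alkaline_domain(prof, (160, 400))
        assert dom is not None and dom.boundary_limited

    def test_window_outside_profile(self):
        with pytest.raises(WindowError):
            rp.detect_alkaline_domain(self._bump_profile(), (5000, 6000))

    def test_too_few_bins_in_window(self):
        with pytest.raises(AnalysisError):
            rp.detect_alkaline_domain(self._bump_profile(), (340, 380))


class TestCompareProfiles:
    def test_windowed_difference_flagged(self):
        a = make_group(10, 11)
        b = make_group(10, 12, bump=0.3)
        res = rp.compare_profiles(a, b)
        inside = res[(res.position_um >= 220) & (res.position_um < 480)]
        assert inside.significant.all()
        assert (inside.effect > 0.9).all()

    def test_null_fraction_near_alpha(self):
        a = make_group(10, 13)
        b = make_group(10, 14)
        res = rp.compare_profiles(a, b)
        assert res.significant.mean() < 0.25

    def test_too_few_profiles(self):
        with pytest.raises(AnalysisError):
            rp.compare_profiles(make_group(2, 0), make_group(10, 1))

    def test_holm_adjustment_is_more_conservative(self):
        a = make_group(8, 15)
        b = make_group(8, 16, bump=0.05)
        raw = rp.compare_profiles(a, b)
        adj = rp.compare_profiles(a, b, adjust="holm")
        assert adj.significant.sum() <= raw.significant.sum()
        assert (adj.p_adj >= raw.p_adj - 1e-15).all()


class TestManyToOne:
    def test_deviant_group_flagged_only(self):
        groups = {
            "control": make_group(8, 20),
            "same": make_group(8, 21),
            "shifted": make_group(8, 22, bump=0.3),
        }
        res = rp.many_to_one_comparison(groups, "control")
        inside = lambda df: df[(df.position_um >= 220) & (df.position_um < 480)]
        assert inside(res["shifted"]).significant.all()
        assert inside(res["same"]).significant.mean() < 0.2

    def test_missing_control(self):
        with pytest.raises(AnalysisError, match="control"):
            rp.many_to_one_comparison({"a": make_group(5, 0), "b": make_group(5, 1)},
                                      "Col-0")


class TestPenetration:
    @staticmethod
    def toy_table():
        return pd.DataFrame({
            "genotype": ["ref", "var", "ref", "var"],
            "pore_size_um": [139.0] * 4,
            "n_penetrated": [8, 4, 5, 4],
            "n_total": [10, 10, 10, 10],
            "replicate": [1, 1, 2, 2],
        })

    def test_hand_checked_toy_table(self):
        out = rp.penetration_efficiency(self.toy_table(), ("ref", 139.0))
        var = out[out.genotype == "var"].iloc[0]
        ref = out[out.genotype == "ref"].iloc[0]
        # replicate efficiencies 4/10 / (8/10) = 0.5 and 4/10 / (5/10) = 0.8
        assert var.efficiency_mean == pytest.approx(0.65)
        assert ref.efficiency_mean == pytest.approx(1.0)

    def test_zero_penetration_variant(self):
        tab = self.toy_table()
        tab.loc[tab.genotype == "var", "n_penetrated"] = 0
        out = rp.penetration_efficiency(tab, ("ref", 139.0))
        assert out[out.genotype == "var"].efficiency_mean.iloc[0] == 0.0

    def test_count_scale_invariance(self):
        tab = self.toy_table()
        scaled = tab.assign(n_penetrated=tab.n_penetrated * 3,
                            n_total=tab.n_total * 3)
        o1 = rp.penetration_efficiency(tab, ("ref", 139.0))
        o2 = rp.penetration_efficiency(scaled, ("ref", 139.0))
        pd.testing.assert_frame_equal(o1, o2)

    def test_zero_reference_replicate_excluded(self):
        tab = self.toy_table()
        tab.loc[(tab.genotype == "ref") & (tab.replicate == 2), "n_penetrated"] = 0
        with pytest.warns(UserWarning, match="excluded"):
            out = rp.penetration_efficiency(tab, ("ref", 139.0))
        assert (out.n_replicates == 1).all()

    def test_missing_reference(self):
        with pytest.raises(AnalysisError):
            rp.penetration_efficiency(self.toy_table(), ("Col-0", 139.0))
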