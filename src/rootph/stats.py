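"""Derived metrics and rank-based profile comparison.

Profiles from different roots are compared position by position: each
longitudinal bin is one independent data point per root, and two groups
are compared at each position with the Brunner-Munzel rank test, which
estimates the relative effect P(X < Y) + 0.5 P(X = Y) and tolerates
unequal variances and ties.  Per-position significance is marked at
alpha with no across-position correction by default (a Holm adjustment
is available); many-to-one comparisons Holm-adjust across groups at each
position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.ndimage import uniform_filter1d
from statsmodels.stats.multitest import multipletests

from .errors import AlignmentError, AnalysisError, WindowError
from .profiling import PHProfile


# ---------------------------------------------------------------- rank test

def relative_effect(x: np.ndarray, y: np.ndarray) -> float:
    """Midrank estimate of P(X < Y) + 0.5 P(X = Y)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    return float((ranks[nx:].mean() - (ny + 1) / 2.0) / nx)


def rank_test_two_sample(x, y) -> tuple[float, float, float]:
    """Brunner-Munzel test: (relative effect, statistic, two-sided p).

    Degenerate zero-variance cases are resolved explicitly: all values
    tied across both samples give (0.5, 0.0, 1.0); complete separation
    gives p = 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 5 or len(y) < 5:
        raise AnalysisError(f"need >= 5 observations per sample, got {len(x)}, {len(y)}")
    p_hat = relative_effect(x, y)
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 0.5, 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = sps.brunnermunzel(x, y, alternative="two-sided")
    if not np.isfinite(p):
        # zero rank variance: either no overlap at all, or identical ranks
        p = 1.0 if abs(p_hat - 0.5) < 1e-12 else 0.0
        stat = np.inf if p == 0.0 else 0.0
    return p_hat, float(stat), float(p)


# ------------------------------------------------------- profile alignment

def _profile_series(profile: PHProfile, side: str, column: str) -> tuple[np.ndarray, np.ndarray]:
    pos = profile.positions(side)
    val = profile.values(side, column)
    ok = np.isfinite(val)
    return pos[ok], val[ok]


def resample_profiles(
    profiles: Sequence[PHProfile],
    side: str = "both",
    column: str = "mean_ratio",
    grid: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear-interpolate each profile onto a common position grid.

    The grid defaults to the first profile's bin centers restricted to
    the range covered by every profile.  Returns (grid, values) with
    values shaped (n_profiles, n_positions); positions outside a
    profile's own range are NaN.
    """
    series = [_profile_series(p, side, column) for p in profiles]
    if any(len(s[0]) == 0 for s in series):
        raise AnalysisError("a profile has no valid bins")
    lo = max(s[0].min() for s in series)
    hi = min(s[0].max() for s in series)
    if lo >= hi:
        raise AlignmentError(
            f"profiles have no overlapping position range ({lo:.0f} >= {hi:.0f} um)"
        )
    if grid is None:
        g0 = series[0][0]
        grid = g0[(g0 >= lo) & (g0 <= hi)]
    else:
        grid = np.asarray(grid, float)
        grid = grid[(grid >= lo) & (grid <= hi)]
    if len(grid) == 0:
        raise AlignmentError("common grid is empty after range restriction")
    vals = np.vstack([np.interp(grid, pos, v) for pos, v in series])
    return grid, vals


# ------------------------------------------------------------------ metrics

def alkalinization_factor(
    treated: Sequence[PHProfile],
    control: Sequence[PHProfile],
    n_boot: int = 1000,
    seed: Optional[int] = None,
    side: str = "both",
    column: str = "mean_ratio",
) -> pd.DataFrame:
    """Per-position ratio of group-mean profiles (treated / control).

    A measure of treatment-induced alkalinization relative to control
    roots; the bootstrap CI resamples roots within each group.
    Columns: position_um, af, ci_lo, ci_hi.
    """
    if len(treated) < 3 or len(control) < 3:
        raise AnalysisError("need >= 3 profiles per group")
    grid, vt = resample_profiles(treated, side, column)
    grid_c, vc = resample_profiles(control, side, column, grid=grid)
    if len(grid_c) != len(grid) or not np.allclose(grid_c, grid):
        grid, vt = resample_profiles(treated, side, column, grid=grid_c)
        grid_c, vc = resample_profiles(control, side, column, grid=grid)
    af = vt.mean(axis=0) / vc.mean(axis=0)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(grid)))
    for b in range(n_boot):
        it = rng.integers(0, len(vt), len(vt))
        ic = rng.integers(0, len(vc), len(vc))
        boots[b] = vt[it].mean(axis=0) / vc[ic].mean(axis=0)
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    return pd.DataFrame({"position_um": grid, "af": af, "ci_lo": lo, "ci_hi": hi})


@dataclass
class DomainDescriptor:
    """Alkaline-domain summary: peak location, amplitude over baseline, FWHM."""

    peak_position_um: float
    amplitude: float
    fwhm_um: float
    baseline_points: tuple
    boundary_limited: bool = False


def detect_alkaline_domain(
    profile: PHProfile,
    search_window_um: tuple[float, float] = (200.0, 500.0),
    side: str = "both",
    column: str = "mean_ratio",
    k_sigma: float = 3.0,
) -> Optional[DomainDescriptor]:
    """Locate the alkaline bump within a longitudinal window.

    Baseline = linear interpolation between the profile minima flanking
    the window; the domain is reported when the baseline-subtracted peak
    exceeds ``k_sigma`` times a robust noise SD (successive-difference
    MAD) of the profile.  Returns None when no domain is detected.
    """
    pos, val_raw = _profile_series(profile, side, column)
    lo, hi = search_window_um
    if len(pos) == 0 or lo >= pos.max() or hi <= pos.min():
        raise WindowError(f"window {search_window_um} um outside profile range")
    inside = (pos >= lo) & (pos <= hi)
    if inside.sum() < 10:
        raise AnalysisError(
            f"need >= 10 valid bins inside the window, got {int(inside.sum())}"
        )
    # a light smoothing keeps the flanking-minimum baseline from riding the
    # noise floor (the minimum of raw noisy bins is biased low)
    val = uniform_filter1d(val_raw, 3, mode="nearest") if len(val_raw) >= 3 else val_raw
    left = pos <= lo
    right = pos >= hi
    # flanking minima (fall back to window edge bins if a flank is empty)
    i_l = np.nonzero(left)[0][np.argmin(val[left])] if left.any() else np.nonzero(inside)[0][0]
    i_r = np.nonzero(right)[0][np.argmin(val[right])] if right.any() else np.nonzero(inside)[0][-1]
    p1, v1 = pos[i_l], val[i_l]
    p2, v2 = pos[i_r], val[i_r]
    baseline = v1 + (v2 - v1) * (pos - p1) / max(p2 - p1, 1e-12)
    det = val - baseline

    # robust noise SD of the raw profile from successive differences
    noise_sd = 1.4826 * float(np.median(np.abs(np.diff(val_raw)))) / np.sqrt(2.0)
    k_peak = np.nonzero(inside)[0][np.argmax(det[inside])]
    amplitude = float(det[k_peak])
    if amplitude <= k_sigma * noise_sd or amplitude <= 0:
        return None

    half = amplitude / 2.0
    # walk out from the peak to the half-maximum crossings
    boundary = False

    def _cross(direction: int) -> float:
        nonlocal boundary
        i = k_peak
        while 0 <= i + direction < len(det) and det[i + direction] > half:
            i += direction
        j = i + direction
        if j < 0 or j >= len(det):
            boundary = True
            return pos[i]
        # linear interpolation between bins i and j
        f = (det[i] - half) / max(det[i] - det[j], 1e-12)
        return float(pos[i] + f * (pos[j] - pos[i]))

    x_left = _cross(-1)
    x_right = _cross(+1)
    if x_left < lo or x_right > hi:
        # the half-maximum extent spills out of the search window
        boundary = True
    if pos[k_peak] in (pos[inside][0], pos[inside][-1]):
        boundary = True
    return DomainDescriptor(
        peak_position_um=float(pos[k_peak]),
        amplitude=amplitude,
        fwhm_um=float(x_right - x_left),
        baseline_points=((float(p1), float(v1)), (float(p2), float(v2))),
        boundary_limited=boundary,
    )


# ------------------------------------------------------------- comparisons

def compare_profiles(
    group_a: Sequence[PHProfile],
    group_b: Sequence[PHProfile],
    alpha: float = 0.05,
    adjust: Optional[str] = None,
    side: str = "both",
    column: str = "mean_ratio",
) -> pd.DataFrame:
    """Position-wise Brunner-Munzel comparison of two profile groups.

    Each bin position is one independent data point per root; per-
    position flags at ``alpha`` with no across-position correction by
    default (``adjust='holm'`` to enable).  Columns: position_um,
    effect, statistic, p, p_adj, significant.
    """
    if len(group_a) < 5 or len(group_b) < 5:
        raise AnalysisError("need >= 5 profiles per group")
    grid, va = resample_profiles(group_a, side, column)
    grid, vb = resample_profiles(group_b, side, column, grid=grid)
    rows = []
    for k, pos in enumerate(grid):
        x = va[:, k][np.isfinite(va[:, k])]
        y = vb[:, k][np.isfinite(vb[:, k])]
        if len(x) < 5 or len(y) < 5:
            rows.append((pos, np.nan, np.nan, np.nan))
            continue
        eff, stat, p = rank_test_two_sample(x, y)
        rows.append((pos, eff, stat, p))
    df = pd.DataFrame(rows, columns=["position_um", "effect", "statistic", "p"])
    ok = np.isfinite(df.p)
    if adjust == "holm":
        adj = np.full(len(df), np.nan)
        adj[ok] = multipletests(df.p[ok], method="holm")[1]
        df["p_adj"] = adj
    elif adjust is None:
        df["p_adj"] = df.p
    else:
        raise ValueError(f"unknown adjustment: {adjust!r}")
    df["significant"] = df.p_adj < alpha
    df.attrs.update({"alpha": alpha, "adjust": adjust,
                     "n_a": len(group_a), "n_b": len(group_b)})
    return df


def many_to_one_comparison(
    groups: dict,
    control_name: str,
    alpha: float = 0.05,
    side: str = "both",
    column: str = "mean_ratio",
) -> dict:
    """Each group vs control, Holm-adjusted across groups at each position."""
    if control_name not in groups:
        raise AnalysisError(f"control group {control_name!r} not found")
    others = [n for n in groups if n != control_name]
    if len(others) < 2:
        raise AnalysisError("need >= 2 non-control groups")
    results = {
        name: compare_profiles(groups[name], groups[control_name],
                               alpha=alpha, side=side, column=column)
        for name in others
    }
    # align on the intersection of grids and Holm-adjust across groups
    common = None
    for df in results.values():
        p = set(np.round(df.position_um, 9))
        common = p if common is None else (common & p)
    for pos in sorted(common):
        ps, keys = [], []
        for name, df in results.items():
            row = df.index[np.isclose(df.position_um, pos)]
            if len(row) and np.isfinite(df.loc[row[0], "p"]):
                ps.append(df.loc[row[0], "p"])
                keys.append((name, row[0]))
        if ps:
            adj = multipletests(ps, method="holm")[1]
            for (name, i), pa in zip(keys, adj):
                results[name].loc[i, "p_adj"] = pa
                results[name].loc[i, "significant"] = pa < alpha
    for df in results.values():
        df.attrs["adjust"] = "holm-across-groups"
    return results


# ------------------------------------------------------------- penetration

def penetration_efficiency(
    table: pd.DataFrame,
    reference: tuple[str, float],
) -> pd.DataFrame:
    """Mesh-penetration efficiencies normalized to a reference variant.

    Per replicate, efficiency(variant) = (n_pen/n_tot) divided by the
    reference variant's raw efficiency in that replicate; the reference
    variant itself is instead normalized to its across-replicate mean
    raw efficiency.  Replicates where the reference efficiency is zero
    are excluded with a warning.  Returns per-variant mean and SD across
    replicates.
    """
    ref_geno, ref_pore = reference
    df = table.copy()
    df["raw_eff"] = df.n_penetrated / df.n_total
    is_ref = (df.genotype == ref_geno) & (df.pore_size_um == ref_pore)
    if not is_ref.any():
        raise AnalysisError(f"reference variant {reference} absent from the table")
    ref_by_rep = df[is_ref].set_index("replicate").raw_eff
    missing = set(df.replicate) - set(ref_by_rep.index)
    if missing:
        raise AnalysisError(f"reference variant missing in replicates {sorted(missing)}")
    zero_reps = ref_by_rep.index[ref_by_rep == 0].tolist()
    if zero_reps:
        warnings.warn(
            f"reference efficiency is 0 in replicates {zero_reps}; excluded",
            stacklevel=2,
        )
        df = df[~df.replicate.isin(zero_reps)]
        ref_by_rep = ref_by_rep.drop(zero_reps)
    ref_mean = ref_by_rep.mean()
    norm = np.where(
        (df.genotype == ref_geno) & (df.pore_size_um == ref_pore),
        df.raw_eff / ref_mean,
        df.raw_eff / df.replicate.map(ref_by_rep).to_numpy(),
    )
    df = df.assign(efficiency=norm)
    out = (df.groupby(["genotype", "pore_size_um"])["efficiency"]
             .agg(["mean", "std", "count"]).reset_index()
             .rename(columns={"mean": "efficiency_mean", "std": "efficiency_sd",
                              "count": "n_replicates"}))
    return out
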