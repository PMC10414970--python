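"""Monotone ratio <-> pH calibration.

The F488/405 excitation ratio of the sulfonated-fluorescein dye rises
monotonically with pH over its response range, so the default model is a
monotone piecewise-cubic (PCHIP) interpolant through the measured
standards; a 4-parameter logistic ("sigmoid") is available because
fluorescein-family dyes follow a single-pKa titration curve.  Queries
outside the fitted range are clamped to the boundary and flagged, never
extrapolated: the dye saturates outside its response range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import curve_fit

from .errors import CalibrationFitError, InsufficientStandardsError, MonotonicityError


def logistic_ratio(ph, r_lo, r_hi, pka, slope):
    """Single-pKa titration curve: ratio as a logistic function of pH."""
    return r_lo + (r_hi - r_lo) / (1.0 + 10.0 ** (slope * (pka - ph)))


@dataclass
class CalibrationCurve:
    """Fitted monotone mapping between F488/405 ratio and pH."""

    ph_std: np.ndarray
    ratio_std: np.ndarray
    model: str = "interpolating"
    params: Optional[dict] = None
    residual_rms: float = 0.0
    _fwd: object = field(default=None, repr=False)   # pH -> ratio
    _inv: object = field(default=None, repr=False)   # ratio -> pH

    @property
    def ph_range(self) -> tuple[float, float]:
        return float(self.ph_std.min()), float(self.ph_std.max())

    @property
    def ratio_range(self) -> tuple[float, float]:
        lo, hi = self.ph_range
        return float(self._fwd(lo)), float(self._fwd(hi))

    def ph_to_ratio(self, ph):
        """Forward evaluation; out-of-range pH clamps to the boundary."""
        ph = np.asarray(ph, float)
        lo, hi = self.ph_range
        clamped = (ph < lo) | (ph > hi)
        out = self._fwd(np.clip(ph, lo, hi))
        return (out.item() if out.ndim == 0 else out,
                clamped.item() if clamped.ndim == 0 else clamped)

    def ratio_to_ph(self, ratio):
        """Inverse evaluation; out-of-range ratios clamp to the boundary."""
        ratio = np.asarray(ratio, float)
        rlo, rhi = self.ratio_range
        clamped = (ratio < rlo) | (ratio > rhi)
        out = self._inv(np.clip(ratio, rlo, rhi))
        return (out.item() if out.ndim == 0 else out,
                clamped.item() if clamped.ndim == 0 else clamped)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "model": self.model,
            "ph_std": self.ph_std.tolist(),
            "ratio_std": self.ratio_std.tolist(),
            "params": self.params,
            "residual_rms": self.residual_rms,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationCurve":
        with open(path) as fh:
            obj = json.load(fh)
        std = pd.DataFrame({"pH": obj["ph_std"], "ratio": obj["ratio_std"]})
        return fit_calibration(std, model=obj["model"])


def fit_calibration(standards, model: str = "interpolating") -> CalibrationCurve:
    """Fit a monotone ratio<->pH curve to (pH, ratio) standards.

    ``standards`` is a DataFrame with columns pH, ratio (or a sequence
    of pairs), sorted or not.  The interpolating model requires ratios
    strictly increasing with pH; the sigmoid model fits
    :func:`logistic_ratio` by least squares.
    """
    if isinstance(standards, pd.DataFrame):
        ph = standards["pH"].to_numpy(float)
        ratio = standards["ratio"].to_numpy(float)
    else:
        arr = np.asarray(standards, float)
        ph, ratio = arr[:, 0], arr[:, 1]
    order = np.argsort(ph)
    ph, ratio = ph[order], ratio[order]
    if len(np.unique(ph)) < 3:
        raise InsufficientStandardsError(
            f"need >= 3 distinct pH standards, got {len(np.unique(ph))}"
        )

    if model == "interpolating":
        if np.any(np.diff(ratio) <= 0):
            raise MonotonicityError(
                "standards are not strictly increasing in ratio vs pH; "
                "consider model='sigmoid'"
            )
        fwd = PchipInterpolator(ph, ratio)

        def inv(r, _fwd=fwd, _ph=ph, _ratio=ratio):
            # exact functional inverse: root of the monotone forward spline
            r = np.asarray(r, float)
            flat = np.atleast_1d(r).ravel()
            out = np.empty(flat.shape)
            for i, ri in enumerate(flat):
                if ri <= _ratio[0]:
                    out[i] = _ph[0]
                elif ri >= _ratio[-1]:
                    out[i] = _ph[-1]
                else:
                    out[i] = _fwd.solve(ri, extrapolate=False)[0]
            return out.reshape(r.shape)

        resid = 0.0
        params = None
    elif model == "sigmoid":
        p0 = [ratio.min(), ratio.max(), float(np.median(ph)), 1.0]
        bounds = ([0.0, 0.0, ph.min() - 5.0, 0.05],
                  [np.inf, np.inf, ph.max() + 5.0, 20.0])
        try:
            popt, _ = curve_fit(logistic_ratio, ph, ratio, p0=p0,
                                bounds=bounds, maxfev=20000)
        except RuntimeError as exc:
            raise CalibrationFitError(f"sigmoid fit did not converge: {exc}") from exc
        r_lo, r_hi, pka, slope = popt
        if r_hi <= r_lo:
            raise CalibrationFitError("sigmoid fit is not increasing in pH")
        params = dict(r_lo=r_lo, r_hi=r_hi, pka=pka, slope=slope)

        def fwd(p, _pp=popt):
            return logistic_ratio(np.asarray(p, float), *_pp)

        def inv(r, _pp=popt):
            r_lo, r_hi, pka, slope = _pp
            r = np.asarray(r, float)
            frac = np.clip((r - r_lo) / (r_hi - r_lo), 1e-12, 1 - 1e-12)
            return pka - np.log10(1.0 / frac - 1.0) / slope

        resid = float(np.sqrt(np.mean((fwd(ph) - ratio) ** 2)))
    else:
        raise ValueError(f"unknown calibration model: {model!r}")

    curve = CalibrationCurve(
        ph_std=ph, ratio_std=ratio, model=model, params=params,
        residual_rms=resid, _fwd=fwd, _inv=inv,
    )
    _check_monotone(curve)
    return curve


def _check_monotone(curve: CalibrationCurve, n: int = 512) -> None:
    lo, hi = curve.ph_range
    grid = np.linspace(lo, hi, n)
    vals = curve._fwd(grid)
    if np.any(np.diff(vals) <= 0):
        raise MonotonicityError("fitted curve is not strictly increasing")
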