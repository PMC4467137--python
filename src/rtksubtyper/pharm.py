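"""Dose-response fitting and Chou-Talalay combination-index synergy analysis.

Single-drug viability curves are fitted with the four-parameter logistic
model (variable slope)

    y(D) = bottom + (top - bottom) / (1 + (D / IC50)^slope),  slope > 0,

by multi-start least squares over a grid of initial log10 IC50 values; when
the fitted IC50 exceeds the largest tested dose the IC50 is reported censored
at that dose.  The median-effect model fa/(1-fa) = (D/Dm)^m is fitted by
linear regression of log10(fa/(1-fa)) on log10 D.  For a combination
observation (d1, d2, fa), Dx_i = Dm_i * (fa/(1-fa))^(1/m_i) is the dose of
drug i alone producing fa, and the (mutually nonexclusive, two-term)
combination index is CI = d1/Dx1 + d2/Dx2: synergism below 1, additivity at
1 (within tolerance 0.05), antagonism above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseFit",
    "MedianEffectModel",
    "fit_4pl",
    "fit_median_effect",
    "combination_index",
    "combo_table_to_fa",
]


@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters with censoring status."""

    bottom: float
    top: float
    ic50: float  # reported IC50 (capped at max dose when censored)
    log_ic50: float  # log10 of the uncensored fitted IC50
    hill_slope: float  # > 0 for decreasing viability curves
    censored: bool
    sse: float
    dose_range: tuple[float, float]


def _four_pl(d: np.ndarray, bottom: float, top: float, lic: float, slope: float):
    return bottom + (top - bottom) / (1.0 + (d / 10.0**lic) ** slope)


def fit_4pl(
    doses: Sequence[float],
    viabilities: Sequence[float],
    bottom_bounds: tuple[float, float] = (0.0, 0.5),
    top_bounds: tuple[float, float] = (0.5, 1.2),
) -> DoseResponseFit:
    """Least-squares 4PL fit of viability fractions against dose.

    Multi-start over initial log10 IC50 values spanning the tested range and
    several slopes; the best (lowest SSE) converged fit is returned, and is
    never worse than any start.
    """
    d = np.asarray(doses, float)
    y = np.asarray(viabilities, float)
    if d.shape != y.shape:
        raise ValueError("doses and viabilities must have equal length")
    if len(np.unique(d)) < 4:
        raise ValueError("need >= 4 distinct doses")
    if np.any(d <= 0):
        raise ValueError("doses must be strictly positive")
    if np.allclose(y, y[0]):
        raise ValueError("all viabilities identical; no dose response to fit")

    lo, hi = float(d.min()), float(d.max())
    bounds = (
        [bottom_bounds[0], top_bounds[0], np.log10(lo) - 2.0, 0.05],
        [bottom_bounds[1], top_bounds[1], np.log10(hi) + 2.0, 10.0],
    )
    b0 = float(np.clip(y.min(), *bottom_bounds))
    t0 = float(np.clip(y.max(), *top_bounds))
    best = None
    for lic0 in np.linspace(np.log10(lo), np.log10(hi), 7):
        for slope0 in (0.5, 1.0, 3.0):
            p0 = [b0, t0, lic0, slope0]
            try:
                popt, _ = curve_fit(
                    _four_pl, d, y, p0=p0, bounds=bounds, maxfev=20000,
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except RuntimeError:
                continue
            sse = float(((y - _four_pl(d, *popt)) ** 2).sum())
            if best is None or sse < best[1]:
                best = (popt, sse)
    if best is None:
        raise RuntimeError("4PL fit failed from every start")
    (bottom, top, lic, slope), sse = best
    ic50 = 10.0**lic
    censored = bool(ic50 > hi)
    return DoseResponseFit(
        bottom=float(bottom),
        top=float(top),
        ic50=float(hi if censored else ic50),
        log_ic50=float(lic),
        hill_slope=float(slope),
        censored=censored,
        sse=sse,
        dose_range=(lo, hi),
    )


@dataclass
class MedianEffectModel:
    """Median-effect parameters: slope m, median-effect dose Dm, fit R^2."""

    m: float
    dm: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.dm <= 0:
            raise ValueError("Dm must be positive")

    def dx(self, fa) -> np.ndarray:
        """Dose producing fraction affected fa under this model."""
        fa = np.asarray(fa, float)
        if np.any((fa <= 0) | (fa >= 1)):
            raise ValueError("fa must lie strictly in (0, 1)")
        return self.dm * (fa / (1.0 - fa)) ** (1.0 / self.m)


def fit_median_effect(
    doses: Sequence[float], fa: Sequence[float], fa_window: tuple[float, float] = (0.01, 0.99)
) -> MedianEffectModel:
    """Fit the median-effect plot log10(fa/(1-fa)) ~ log10 D.

    Points with fa outside ``fa_window`` carry no usable information on the
    log-odds scale and are clipped out with a warning.
    """
    d = np.asarray(doses, float)
    f = np.asarray(fa, float)
    if d.shape != f.shape:
        raise ValueError("doses and fa must have equal length")
    if np.any(d <= 0):
        raise ValueError("doses must be strictly positive")
    keep = (f > fa_window[0]) & (f < fa_window[1])
    if keep.sum() < len(f):
        warnings.warn(
            f"dropping {int((~keep).sum())} point(s) with fa outside "
            f"({fa_window[0]}, {fa_window[1]})",
            RuntimeWarning,
            stacklevel=2,
        )
    if keep.sum() < 2:
        raise ValueError("need >= 2 points with fa inside the usable window")
    x = np.log10(d[keep])
    y = np.log10(f[keep] / (1.0 - f[keep]))
    m, intercept = np.polyfit(x, y, 1)
    if m <= 0:
        raise ValueError("non-positive median-effect slope; not a dose response")
    fitted = m * x + intercept
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return MedianEffectModel(
        m=float(m), dm=float(10.0 ** (-intercept / m)), r_squared=r2, n_points=int(keep.sum())
    )


def combination_index(
    model_a: MedianEffectModel,
    model_b: MedianEffectModel,
    combo: Sequence[tuple[float, float, float]],
    additivity_tol: float = 0.05,
) -> pd.DataFrame:
    """Chou-Talalay combination indices for (d1, d2, fa) observations.

    Returns a frame with d1, d2, fa, Dx1, Dx2, CI and the synergy call:
    synergism (CI < 1 - tol), additivity (|CI - 1| <= tol), antagonism.
    """
    rows = []
    for d1, d2, fa in combo:
        if not 0 < fa < 1:
            raise ValueError(f"fa={fa} outside (0, 1); Dx undefined")
        dx1 = float(model_a.dx(fa))
        dx2 = float(model_b.dx(fa))
        ci = d1 / dx1 + d2 / dx2
        if ci < 1.0 - additivity_tol:
            call = "synergism"
        elif ci <= 1.0 + additivity_tol:
            call = "additivity"
        else:
            call = "antagonism"
        rows.append((d1, d2, fa, dx1, dx2, ci, call))
    return pd.DataFrame(rows, columns=["d1", "d2", "fa", "Dx1", "Dx2", "CI", "call"])


def combo_table_to_fa(table: pd.DataFrame, fa_window=(0.01, 0.99)) -> list[tuple[float, float, float]]:
    """Average replicate viabilities per dose pair and convert to fa = 1 - v."""
    grouped = table.groupby(["d1", "d2"], as_index=False)["viability"].mean()
    out = []
    for _, row in grouped.iterrows():
        fa = 1.0 - float(row["viability"])
        if fa_window[0] < fa < fa_window[1]:
            out.append((float(row["d1"]), float(row["d2"]), fa))
    return out
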