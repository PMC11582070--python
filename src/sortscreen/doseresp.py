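"""Reporter degradation dose-response quantification.

A degradation reporter expresses the degron fused to eGFP from the same
transcript as an mCherry control, so the eGFP/mCherry geometric-mean ratio
of a treated well, normalized to vehicle (DMSO) wells, measures the
fraction of reporter remaining.  Dose series are summarized two ways:

* a LOESS curve (local-linear, tricube weights, on log10 concentration)
  for display, and
* a four-parameter log-logistic (4PL) fit

  ``f(x) = d + (a - d) / (1 + (x / c)^b)``

  whose inflection ``c`` is the DC50 (half-maximal degradation
  concentration) and whose asymptote ratio gives the maximal depth of
  degradation ``Dmax = (1 - d/a) * 100`` percent.  The same operation fits
  AlphaScreen-style inhibition curves.

Also included: competition growth assay trajectories (marker-positive cell
fractions normalized to day 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import ValidationError

__all__ = [
    "geometric_mean",
    "four_pl",
    "reporter_ratio",
    "normalize_wells",
    "LoessCurve",
    "fit_loess",
    "FourPLFit",
    "fit_4pl",
    "fit_dose_response",
    "summarize_competition",
]

WELL_COLUMNS = ["condition", "concentration_M", "gfp_geomean", "mcherry_geomean",
                "replicate"]
FIT_COLUMNS = ["condition", "a", "b", "c", "d", "dc50_M", "dmax_pct",
               "dmax_empirical_pct", "converged", "residual"]


def geometric_mean(values) -> float:
    """Geometric mean of per-event fluorescence values (all must be > 0)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0 or (arr <= 0).any():
        raise ValidationError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(arr))))


def four_pl(x, a: float, b: float, c: float, d: float):
    """Four-parameter log-logistic: ``d + (a - d) / (1 + (x/c)^b)``.

    ``a`` is the response as x -> 0, ``d`` the response as x -> inf (for
    b > 0), ``c`` the inflection concentration where f = (a + d)/2.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        t = np.exp(np.clip(b * (np.log(x) - math.log(c)), -500, 500))
    return d + (a - d) / (1.0 + t)


def reporter_ratio(gfp_geomean: float, mcherry_geomean: float,
                   vehicle_ratios: Sequence[float]) -> float:
    """eGFP/mCherry ratio of one well as a fraction of the mean vehicle ratio."""
    if gfp_geomean <= 0 or mcherry_geomean <= 0:
        raise ValidationError("geometric means must be positive")
    vr = np.asarray(list(vehicle_ratios), dtype=float)
    if vr.size == 0:
        raise ValidationError("at least one vehicle well is required")
    if (vr <= 0).any():
        raise ValidationError("vehicle ratios must be positive")
    return (gfp_geomean / mcherry_geomean) / vr.mean()


def normalize_wells(wells: pd.DataFrame) -> pd.DataFrame:
    """Add ``ratio`` and ``stability`` columns to a wells table.

    Wells with ``concentration_M == 0`` are the vehicle set; ``stability``
    is each well's eGFP/mCherry ratio divided by the mean vehicle ratio
    (per condition).
    """
    missing = [c for c in ("condition", "concentration_M", "gfp_geomean",
                           "mcherry_geomean") if c not in wells.columns]
    if missing:
        raise ValidationError(f"wells table missing columns: {missing}")
    if (wells["gfp_geomean"] <= 0).any() or (wells["mcherry_geomean"] <= 0).any():
        raise ValidationError("geometric means must be positive")
    out = wells.copy()
    out["ratio"] = out["gfp_geomean"] / out["mcherry_geomean"]
    stab = np.empty(len(out))
    for cond, grp in out.groupby("condition", sort=False):
        veh = grp.loc[grp["concentration_M"] == 0, "ratio"]
        if veh.empty:
            raise ValidationError(f"condition {cond!r} has no vehicle "
                                  f"(concentration 0) well")
        stab[out["condition"] == cond] = grp["ratio"] / veh.mean()
    out["stability"] = stab
    return out


# ---------------------------------------------------------------------------
# LOESS display curve
# ---------------------------------------------------------------------------

@dataclass
class LoessCurve:
    """LOESS fit evaluated at the input doses and on a dense display grid."""

    concentrations: np.ndarray
    fitted: np.ndarray
    grid: np.ndarray
    grid_fitted: np.ndarray


def fit_loess(concentrations, responses, span: float = 0.75,
              n_grid: int = 200) -> LoessCurve:
    """Local-linear LOESS of response on log10 concentration.

    Requires at least 5 distinct positive concentrations.  The dense display
    curve interpolates the fit between the observed doses.
    """
    if not 0 < span <= 1:
        raise ValidationError("span must be in (0, 1]")
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("concentrations and responses differ in length")
    if (x <= 0).any():
        raise ValidationError("LOESS smoothing requires positive concentrations")
    if np.unique(x).size < 5:
        raise ValidationError("need >= 5 distinct concentrations for LOESS")
    order = np.argsort(x, kind="mergesort")
    lx = np.log10(x[order])
    fit = lowess(y[order], lx, frac=span, it=0, return_sorted=True)
    xs, fs = fit[:, 0], fit[:, 1]
    fitted = np.interp(lx, xs, fs)
    grid = np.linspace(lx.min(), lx.max(), n_grid)
    return LoessCurve(x[order], fitted, 10.0 ** grid, np.interp(grid, xs, fs))


# ---------------------------------------------------------------------------
# 4PL fit
# ---------------------------------------------------------------------------

@dataclass
class FourPLFit:
    """Fitted 4PL parameters with derived DC50 and Dmax.

    ``dmax_pct`` is defined from the fitted asymptotes, ``(1 - d/a) * 100``;
    ``dmax_empirical_pct`` is the model-free alternative
    ``(1 - min(response)) * 100`` on vehicle-normalized responses.  When the
    data are flat the fit is declared not converged and DC50/Dmax are NaN.
    """

    a: float
    b: float
    c: float
    d: float
    dc50: float
    dmax_pct: float
    dmax_empirical_pct: float
    converged: bool
    residual: float

    def predict(self, x):
        return four_pl(x, self.a, self.b, self.c, self.d)


def fit_4pl(concentrations, responses, flat_tol: float = 1e-6) -> FourPLFit:
    """Bounded multi-start least-squares 4PL fit on log concentration.

    Vehicle points (concentration 0) must be excluded by the caller (they
    are used for normalization, not fitting).  Four deterministic starts
    from quantile heuristics guard against the multimodality of 4PL fits on
    sparse grids.  Flat data (response range below ``flat_tol``) return
    ``converged=False`` with NaN DC50 rather than raising.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("concentrations and responses differ in length")
    if (x <= 0).any():
        raise ValidationError("4PL fitting requires positive concentrations "
                              "(drop vehicle wells first)")
    if np.unique(x).size < 4:
        raise ValidationError("need >= 4 distinct concentrations for a 4PL fit")
    dmax_emp = (1.0 - float(y.min())) * 100.0
    span_y = float(y.max() - y.min())
    if span_y < flat_tol:
        return FourPLFit(float(y.mean()), math.nan, math.nan, float(y.mean()),
                         math.nan, math.nan, dmax_emp, False, 0.0)
    lx = np.log(x)
    order = np.argsort(lx)

    def resid(theta):
        a, b, lc, d = theta
        t = np.exp(np.clip(b * (lx - lc), -500, 500))
        return d + (a - d) / (1.0 + t) - y

    lo_end = float(np.mean(y[order[:2]]))   # response at the low-dose end
    hi_end = float(np.mean(y[order[-2:]]))
    mid = 0.5 * (y.max() + y.min())
    lc_half = float(lx[np.argmin(np.abs(y - mid))])
    lc_med = float(np.median(lx))
    starts = [
        (lo_end, 1.0, lc_med, hi_end),
        (lo_end, 3.0, lc_med, hi_end),
        (lo_end, 1.0, lc_half, hi_end),
        (float(y.max()), 1.0, lc_half, float(y.min())),
    ]
    pad = 2.0 * span_y
    bounds = (
        [y.min() - pad, 1e-3, lx.min() - 5.0, y.min() - pad],
        [y.max() + pad, 50.0, lx.max() + 5.0, y.max() + pad],
    )
    best = None
    for s0 in starts:
        x0 = np.clip(s0, bounds[0], bounds[1])
        try:
            res = least_squares(resid, x0, bounds=bounds, method="trf")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return FourPLFit(math.nan, math.nan, math.nan, math.nan, math.nan,
                         math.nan, dmax_emp, False, math.nan)
    a, b, lc, d = best.x
    ssr = float(2.0 * best.cost)
    rmse = math.sqrt(ssr / y.size)
    dc50 = math.exp(lc)
    dmax = (1.0 - d / a) * 100.0 if a > 0 else math.nan
    return FourPLFit(float(a), float(b), dc50, float(d), dc50, float(dmax),
                     dmax_emp, bool(best.success), rmse)


def fit_dose_response(wells: pd.DataFrame, span: float = 0.75) -> pd.DataFrame:
    """Normalize a wells table and fit a 4PL per condition.

    Returns one row per condition with the columns of ``FIT_COLUMNS``.
    """
    norm = normalize_wells(wells)
    rows = []
    for cond, grp in norm.groupby("condition", sort=False):
        treated = grp[grp["concentration_M"] > 0]
        fit = fit_4pl(treated["concentration_M"].to_numpy(),
                      treated["stability"].to_numpy())
        rows.append({"condition": cond, "a": fit.a, "b": fit.b, "c": fit.c,
                     "d": fit.d, "dc50_M": fit.dc50, "dmax_pct": fit.dmax_pct,
                     "dmax_empirical_pct": fit.dmax_empirical_pct,
                     "converged": fit.converged, "residual": fit.residual})
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


# ---------------------------------------------------------------------------
# competition growth assays
# ---------------------------------------------------------------------------

def summarize_competition(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Normalize marker-positive fractions to each arm's day-0 value.

    Expects columns ``arm``, ``day``, ``fraction`` (in [0, 1]); returns the
    table with a ``normalized`` column, ordered by arm then day.
    """
    missing = [c for c in ("arm", "day", "fraction")
               if c not in trajectories.columns]
    if missing:
        raise ValidationError(f"competition table missing columns: {missing}")
    frac = trajectories["fraction"]
    if ((frac < 0) | (frac > 1)).any():
        raise ValidationError("fractions must lie in [0, 1]")
    out = trajectories.copy().sort_values(["arm", "day"], kind="mergesort",
                                          ignore_index=True)
    norm = np.empty(len(out))
    for arm, grp in out.groupby("arm", sort=False):
        day0 = grp.loc[grp["day"] == 0, "fraction"]
        if day0.empty:
            raise ValidationError(f"arm {arm!r} has no day-0 measurement")
        f0 = day0.mean()
        if f0 <= 0:
            raise ValidationError(f"arm {arm!r} day-0 fraction must be > 0")
        norm[out["arm"] == arm] = grp["fraction"] / f0
    out["normalized"] = norm
    return out
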