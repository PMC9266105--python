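"""Pixel-wise climate-driver attribution of TVDI.

For each pixel the annual TVDI series x is related to annual precipitation y
and annual mean temperature z through

* the partial correlation  r_xy.z = (Rxy - Rxz*Ryz) / sqrt((1-Rxz^2)(1-Ryz^2)),
* the multiple correlation R_x.yz with R^2 = 1 - (1-Rxy^2)(1-r_xz.y^2)
  (identical to the R^2 of regressing x on y and z with intercept),

tested with t = r*sqrt((n-3)/(1-r^2)) on n-3 df (one controlled variable)
and F = (R^2/2) / ((1-R^2)/(n-3)) on (2, n-3) df.  Pixels are then zoned
into four driver classes:

    F significant and only the precipitation partial test significant
        -> precipitation driven
    F significant and only the temperature partial test significant
        -> temperature driven
    F significant otherwise (both or neither partial significant)
        -> temperature and precipitation driven
    F not significant -> other drive types

Tests are two-sided; no multiple-testing correction is applied (each pixel
is treated as its own analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rasters import Raster

__all__ = [
    "partial_corr",
    "multiple_corr",
    "partial_t",
    "multiple_F",
    "driver_zoning",
    "driver_zoning_grid",
    "DRIVER_CLASS_NAMES",
    "DriverZoneResult",
]

DRIVER_CLASS_NAMES = {
    1: "precipitation driven",
    2: "temperature driven",
    3: "temperature and precipitation driven",
    4: "other drive types",
}


def _pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation along the last axis (vectorised)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    am = a - a.mean(axis=-1, keepdims=True)
    bm = b - b.mean(axis=-1, keepdims=True)
    num = (am * bm).sum(axis=-1)
    den = np.sqrt((am**2).sum(axis=-1) * (bm**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def partial_corr(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Partial correlation of x and y with z held fixed (last axis = time).

    Undefined (NaN) when either x or y is perfectly correlated with z, or
    when any series is constant.
    """
    rxy = _pearson(x, y)
    rxz = _pearson(x, z)
    ryz = _pearson(y, z)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt((1.0 - rxz**2) * (1.0 - ryz**2))
        r = (rxy - rxz * ryz) / denom
    return np.where(denom > 0, r, np.nan)


def multiple_corr(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Multiple correlation of x with (y, z), in [0, 1].

    Computed as R^2 = 1 - (1 - Rxy^2)(1 - r_xz.y^2); equals the coefficient
    of determination of the two-covariate least-squares fit.  NaN when y and
    z are collinear.
    """
    rxy = _pearson(x, y)
    r_xz_y = partial_corr(x, z, y)
    with np.errstate(invalid="ignore"):
        r2 = 1.0 - (1.0 - rxy**2) * (1.0 - r_xz_y**2)
        # |Rxy| = 1: x already perfectly explained by y alone; the partial
        # term is 0/0 but the multiple correlation is 1 by definition
        r2 = np.where(rxy**2 >= 1.0 - 1e-15, 1.0, r2)
    return np.sqrt(np.clip(r2, 0.0, 1.0))


def partial_t(r: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """t statistic and two-sided p for a partial correlation, df = n - 3."""
    r = np.asarray(r, dtype=float)
    df = n - 3
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    t = np.where(np.abs(r) >= 1.0, np.copysign(np.inf, r), t)
    t_arr = np.atleast_1d(t)
    p = 2.0 * stats.t.sf(np.abs(t_arr), df)
    p = np.where(np.isnan(t_arr), np.nan, p)
    if np.ndim(t) == 0:
        return float(t), float(p[0])
    return t, p.reshape(t.shape)


def multiple_F(R: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """F statistic and p for a multiple correlation, df = (2, n - 3)."""
    R = np.asarray(R, dtype=float)
    df2 = n - 3
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (R**2 / 2.0) / ((1.0 - R**2) / df2)
    F = np.where(R >= 1.0, np.inf, F)
    F_arr = np.atleast_1d(F)
    p = stats.f.sf(F_arr, 2, df2)
    p = np.where(np.isnan(F_arr), np.nan, p)
    if np.ndim(R) == 0:
        return float(F), float(p[0])
    return F, p.reshape(F.shape)


def driver_zoning(
    r_p: np.ndarray,
    r_t: np.ndarray,
    R: np.ndarray,
    n: int,
    alpha: float = 0.05,
) -> np.ndarray:
    """Four-class driver codes (see :data:`DRIVER_CLASS_NAMES`); NaN -> -1."""
    _tp, p_p = partial_t(r_p, n)
    _tt, p_t = partial_t(r_t, n)
    _F, p_F = multiple_F(R, n)
    p_p, p_t, p_F = np.atleast_1d(p_p), np.atleast_1d(p_t), np.atleast_1d(p_F)
    sig_p = p_p <= alpha
    sig_t = p_t <= alpha
    sig_F = p_F <= alpha
    cls = np.full(sig_F.shape, 4, dtype=np.int64)
    cls[sig_F] = 3
    cls[sig_F & sig_p & ~sig_t] = 1
    cls[sig_F & sig_t & ~sig_p] = 2
    nodata = np.isnan(p_p) | np.isnan(p_t) | np.isnan(p_F)
    cls[nodata] = -1
    if np.ndim(r_p) == 0:
        return int(cls[0])
    return cls.reshape(np.shape(r_p))


@dataclass
class DriverZoneResult:
    """Class grid plus companion statistic grids and an area summary."""

    classes: Raster
    r_precip: Raster
    r_temp: Raster
    R_multi: Raster
    n_years: int
    area_percent: pd.DataFrame  # index: class name, column: percent of valid area


def driver_zoning_grid(
    tvdi_stack: np.ndarray,
    precip_stack: np.ndarray,
    temp_stack: np.ndarray,
    template: Raster,
    alpha: float = 0.05,
) -> DriverZoneResult:
    """Pixel-wise driver zoning over year stacks shaped (years, rows, cols)."""
    if not (tvdi_stack.shape == precip_stack.shape == temp_stack.shape):
        raise ValueError("tvdi/precip/temp stacks must share one shape")
    n = tvdi_stack.shape[0]
    if n < 5:
        raise ValueError("need at least 5 years for driver zoning")
    x = np.moveaxis(tvdi_stack, 0, -1)
    y = np.moveaxis(precip_stack, 0, -1)
    z = np.moveaxis(temp_stack, 0, -1)
    r_p = partial_corr(x, y, z)
    r_t = partial_corr(x, z, y)
    R = multiple_corr(x, y, z)
    cls = driver_zoning(r_p, r_t, R, n, alpha=alpha)
    valid = cls > 0
    total = int(valid.sum())
    pct = {
        name: (100.0 * float((cls[valid] == code).sum()) / total if total else np.nan)
        for code, name in DRIVER_CLASS_NAMES.items()
    }
    area = pd.DataFrame.from_dict(pct, orient="index", columns=["percent"])
    area.index.name = "driver class"
    return DriverZoneResult(
        classes=template.like(cls, nodata=-1, units="driver class"),
        r_precip=template.like(r_p, units="r"),
        r_temp=template.like(r_t, units="r"),
        R_multi=template.like(R, units="R"),
        n_years=n,
        area_percent=area,
    )
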