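"""Per-pixel linear trend of annual TVDI, significance, and 6-level classes.

The trend statistic is the closed-form least-squares slope of TVDI on the
year index i = 1..n:

    slope = (n * sum(i * TVDI_i) - sum(i) * sum(TVDI_i))
            / (n * sum(i^2) - (sum(i))^2)

which is algebraically the OLS slope of simple linear regression.
Significance comes from the slope t-test (df = n - 2, two-sided); classes
combine the slope sign with p-value cutpoints 0.01 and 0.05 into six levels,
boundary p assigned to the more significant class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .rasters import Raster, ZoneMap

__all__ = [
    "trend_slope",
    "trend_test",
    "classify_trend",
    "trend_grid",
    "area_fractions",
    "TREND_CLASS_NAMES",
]

TREND_CLASS_NAMES = {
    1: "extremely significant decrease",
    2: "significant decrease",
    3: "non-significant decrease",
    4: "non-significant increase",
    5: "significant increase",
    6: "extremely significant increase",
}


def trend_slope(series: np.ndarray) -> np.ndarray:
    """Closed-form trend slope along the last axis (units: TVDI per year index).

    Pixels with fewer than 3 finite values return NaN; missing years are
    dropped pairwise with their index kept.
    """
    y = np.asarray(series, dtype=float)
    n_total = y.shape[-1]
    i = np.arange(1, n_total + 1, dtype=float)
    finite = np.isfinite(y)
    n = finite.sum(axis=-1)
    iy = np.where(finite, i * y, 0.0).sum(axis=-1)
    si = np.where(finite, i, 0.0).sum(axis=-1)
    sy = np.where(finite, y, 0.0).sum(axis=-1)
    sii = np.where(finite, i * i, 0.0).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = (n * iy - si * sy) / (n * sii - si**2)
    return np.where(n >= 3, slope, np.nan)


def trend_test(series: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slope, t statistic and two-sided p along the last axis.

    t = slope / SE(slope) with df = n - 2.  Perfect fits (zero residual
    variance) get p = 0 for a nonzero slope and p = 1 otherwise.
    """
    y = np.asarray(series, dtype=float)
    n_total = y.shape[-1]
    i = np.arange(1, n_total + 1, dtype=float)
    finite = np.isfinite(y)
    n = finite.sum(axis=-1).astype(float)
    slope = trend_slope(y)
    si = np.where(finite, i, 0.0).sum(axis=-1)
    sy = np.where(finite, y, 0.0).sum(axis=-1)
    sii = np.where(finite, i * i, 0.0).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ibar = si / n
        ybar = sy / n
        sxx = sii - n * ibar**2
        intercept = ybar - slope * ibar
        resid = np.where(finite, y - (intercept[..., None] + slope[..., None] * i), 0.0)
        ss_res = (resid**2).sum(axis=-1)
        df = n - 2
        se = np.sqrt(ss_res / df / sxx)
        t = slope / se
    p = np.full(t.shape, np.nan)
    ok = np.isfinite(t)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), (n - 2)[ok])
    exact = (ss_res <= 0) & (n >= 3)
    with np.errstate(invalid="ignore"):
        t = np.where(exact & (slope != 0), np.copysign(np.inf, slope), t)
    p = np.where(exact, np.where(slope != 0, 0.0, 1.0), p)
    bad = n < 3
    return (np.where(bad, np.nan, slope),
            np.where(bad, np.nan, t),
            np.where(bad, np.nan, p))


def classify_trend(slope: np.ndarray, p_value: np.ndarray) -> np.ndarray:
    """Six-level trend class codes (see :data:`TREND_CLASS_NAMES`).

    Decrease family for slope < 0, increase family for slope >= 0 (an exact
    zero slope is a measure-zero event and falls to ``non-significant
    increase`` by convention).  p <= 0.01 -> extremely significant,
    0.01 < p <= 0.05 -> significant, p > 0.05 -> non-significant.
    NaN inputs give -1 (nodata).
    """
    slope = np.asarray(slope, dtype=float)
    p = np.asarray(p_value, dtype=float)
    sig = np.full(slope.shape, 0, dtype=np.int64)  # 0 non-sig, 1 sig, 2 extreme
    sig[p <= 0.05] = 1
    sig[p <= 0.01] = 2
    cls = np.where(slope < 0, 3 - sig, 4 + sig)
    cls = np.where(np.isfinite(slope) & np.isfinite(p), cls, -1)
    return cls.astype(np.int64)


def trend_grid(annual_tvdi: list[Raster]) -> tuple[Raster, Raster, Raster]:
    """Slope, p-value and class rasters from a stack of annual TVDI grids."""
    if len(annual_tvdi) < 3:
        raise ValueError("need at least 3 annual grids for a trend")
    first = annual_tvdi[0]
    for r in annual_tvdi[1:]:
        first.require_same_grid(r, "annual grid")
    stack = np.stack([r.data for r in annual_tvdi], axis=-1)
    slope, _t, p = trend_test(stack)
    cls = classify_trend(slope, p)
    return (
        first.like(slope, units="tvdi/yr"),
        first.like(p, units="p"),
        first.like(cls, nodata=-1, units="trend class"),
    )


def area_fractions(class_grid: Raster, zones: ZoneMap) -> pd.DataFrame:
    """Per-zone area fractions of the six trend classes (rows sum to 1).

    Zones with no valid classified pixel get a NaN row.
    """
    zones.require_same_grid(class_grid, "class grid")
    rows = {}
    for z in zones.zone_ids:
        m = zones.mask_for(z) & class_grid.valid_mask
        total = int(m.sum())
        if total == 0:
            rows[z] = {c: np.nan for c in range(1, 7)}
            continue
        vals, counts = np.unique(class_grid.data[m], return_counts=True)
        frac = dict.fromkeys(range(1, 7), 0.0)
        for v, c in zip(vals, counts):
            frac[int(v)] = c / total
        rows[z] = frac
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.columns = [f"TVDI-t{c}" for c in df.columns]
    df.index.name = "zone_id"
    return df
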