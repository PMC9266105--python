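"""Validation of TVDI against point samples of near-surface soil moisture.

Surface dryness and 10 cm soil moisture are anticoupled, so a well-formed
TVDI product regresses against collocated moisture samples with a negative
slope.  ``validate`` extracts TVDI at sample cells (nearest cell centre,
multiple samples in one cell averaged) and fits ordinary least squares
``moisture ~ TVDI``; ``compare_zoned_global`` runs the same check for a
per-zone-edges product and a single-global-edge product side by side — on
domains whose zones genuinely differ, the zoned product validates at least
as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rasters import Raster

__all__ = ["ValidationResult", "validate", "collocate"]


@dataclass
class ValidationResult:
    """OLS of point soil moisture on collocated TVDI."""

    n: int
    intercept: float
    slope: float          # moisture units per TVDI unit
    r2: float
    p_value: float
    per_year: pd.DataFrame | None = None


def collocate(tvdi: Raster, points: pd.DataFrame) -> pd.DataFrame:
    """Attach the TVDI value of each sample's cell; average duplicates.

    ``points`` needs columns ``row``, ``col``, ``moisture`` (``year``
    optional and carried through).  Points outside the grid or on nodata
    cells are dropped.
    """
    rows, cols = tvdi.shape
    pts = points.copy()
    inside = pts["row"].between(0, rows - 1) & pts["col"].between(0, cols - 1)
    pts = pts[inside]
    pts["tvdi"] = tvdi.data[pts["row"].to_numpy(int), pts["col"].to_numpy(int)]
    pts = pts.dropna(subset=["tvdi"])
    keys = ["row", "col"] + (["year"] if "year" in pts.columns else [])
    return pts.groupby(keys, as_index=False).agg(
        moisture=("moisture", "mean"), tvdi=("tvdi", "mean")
    )


def _ols(pts: pd.DataFrame) -> tuple[float, float, float, float]:
    fit = stats.linregress(pts["tvdi"], pts["moisture"])
    return float(fit.intercept), float(fit.slope), float(fit.rvalue**2), float(fit.pvalue)


def validate(tvdi: Raster, points: pd.DataFrame) -> ValidationResult:
    """Regress point moisture on collocated TVDI (pooled + per-year panels)."""
    pts = collocate(tvdi, points)
    if len(pts) < 3:
        raise ValueError(f"only {len(pts)} collocatable points; need >= 3")
    intercept, slope, r2, p = _ols(pts)
    per_year = None
    if "year" in pts.columns and pts["year"].nunique() > 1:
        rows = []
        for year, grp in pts.groupby("year"):
            if len(grp) >= 3 and grp["tvdi"].nunique() > 1:
                a, b, r, pv = _ols(grp)
                rows.append({"year": int(year), "n": len(grp), "intercept": a,
                             "slope": b, "r2": r, "p_value": pv})
        if rows:
            per_year = pd.DataFrame(rows).set_index("year")
    return ValidationResult(
        n=len(pts), intercept=intercept, slope=slope, r2=r2, p_value=p,
        per_year=per_year,
    )


def compare_zoned_global(
    tvdi_zoned: Raster,
    tvdi_global: Raster,
    points: pd.DataFrame,
) -> pd.DataFrame:
    """Side-by-side validation of zoned vs globally fitted TVDI products."""
    rows = []
    for name, grid in [("zoned", tvdi_zoned), ("global", tvdi_global)]:
        res = validate(grid, points)
        rows.append({"product": name, "n": res.n, "slope": res.slope,
                     "r2": res.r2, "p_value": res.p_value})
    return pd.DataFrame(rows).set_index("product")
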