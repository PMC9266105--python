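"""TVDI computation, compositing, smoothing, drought grading, mosaicking.

The temperature-vegetation dryness index locates a pixel's LST between the
zone's fitted wet edge (TVDI = 0) and dry edge (TVDI = 1) at the pixel's
NDVI:

    TVDI = (LST - LSTmin(NDVI)) / (LSTmax(NDVI) - LSTmin(NDVI))

Higher values are drier.  Grades follow the five-interval scheme
(extremely wet [0, 0.2], wet (0.2, 0.4], normal (0.4, 0.6], dry (0.6, 0.8],
extremely dry (0.8, 1.0]) with drought types no-drought [0, 0.6],
drought (0.6, 0.8], severe drought (0.8, 1.0].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .featurespace import EdgeFit
from .rasters import Raster, ZoneMap

__all__ = [
    "composite_max",
    "smooth_ndvi",
    "compute_tvdi",
    "classify_drought",
    "mosaic_zones",
    "GRADE_NAMES",
    "TYPE_NAMES",
    "TvdiResult",
    "MosaicDiagnostics",
]

GRADE_NAMES = {1: "extremely wet", 2: "wet", 3: "normal", 4: "dry", 5: "extremely dry"}
TYPE_NAMES = {0: "no drought", 1: "drought", 2: "severe drought"}

DEGENERACY_EPS = 0.5  # degC: minimum dry-wet separation at a pixel's NDVI


@dataclass
class TvdiResult:
    """TVDI grid plus the bookkeeping the range invariant requires."""

    grid: Raster
    n_valid: int
    n_clipped: int
    n_degenerate: int
    n_out_of_range: int

    @property
    def clipped_fraction(self) -> float:
        return self.n_clipped / self.n_valid if self.n_valid else 0.0


def composite_max(series: list[Raster]) -> Raster:
    """Per-pixel maximum-value composite over co-registered rasters.

    A pixel is nodata only where it is nodata in every input — the standard
    trick for suppressing cloud/atmosphere-depressed observations.
    """
    if not series:
        raise ValueError("composite_max needs at least one raster")
    first = series[0]
    stack = []
    for r in series:
        first.require_same_grid(r, "composite input")
        stack.append(np.where(r.valid_mask, r.data.astype(float), -np.inf))
    out = np.max(stack, axis=0)
    out[np.isinf(out)] = np.nan
    return first.like(out)


def smooth_ndvi(series: np.ndarray, window: int = 5, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay filter along the last axis of a time sequence.

    NaN gaps are linearly interpolated before filtering and re-masked after,
    so smoothing never invents observations.  Sequences shorter than the
    window are returned unchanged.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    if n < window:
        return series.copy()
    flat = series.reshape(-1, n)
    out = np.empty_like(flat)
    idx = np.arange(n)
    for i, row in enumerate(flat):
        bad = np.isnan(row)
        if bad.all():
            out[i] = row
            continue
        filled = row.copy()
        if bad.any():
            filled[bad] = np.interp(idx[bad], idx[~bad], row[~bad])
        sm = savgol_filter(filled, window, polyorder)
        sm[bad] = np.nan
        out[i] = sm
    return out.reshape(series.shape)


def compute_tvdi(
    lst: Raster,
    ndvi: Raster,
    edges: EdgeFit,
    mask: np.ndarray | None = None,
    eps: float = DEGENERACY_EPS,
    clip: bool = True,
) -> TvdiResult:
    """Per-pixel TVDI from fitted edges, restricted to the edge-fit NDVI range.

    Pixels whose NDVI lies outside ``[edges.ndvi_lo, edges.ndvi_hi]``, or at
    which the edges separate by less than ``eps`` degC, become nodata (the
    latter counted as degenerate).  Noise can push LST beyond the fitted
    envelope; those values are clipped into [0, 1] and counted.
    """
    lst.require_same_grid(ndvi, "ndvi")
    valid = lst.valid_mask & ndvi.valid_mask
    if mask is not None:
        valid &= mask
    n = ndvi.data
    in_range = (n >= edges.ndvi_lo) & (n <= edges.ndvi_hi)
    n_out = int((valid & ~in_range).sum())
    use = valid & in_range
    wet = edges.wet(n)
    dry = edges.dry(n)
    sep = dry - wet
    degen = use & (sep <= eps)
    use &= ~degen
    raw = np.full(lst.shape, np.nan)
    raw[use] = (lst.data[use] - wet[use]) / sep[use]
    n_clipped = int(((raw < 0) | (raw > 1)).sum())
    out = np.clip(raw, 0.0, 1.0) if clip else raw
    return TvdiResult(
        grid=lst.like(out, units="tvdi"),
        n_valid=int(use.sum()),
        n_clipped=n_clipped,
        n_degenerate=int(degen.sum()),
        n_out_of_range=n_out,
    )


def classify_drought(tvdi: Raster) -> tuple[Raster, Raster]:
    """Five drought grades and three drought types from a TVDI grid.

    Interval closure is lower-open / upper-closed, with the first interval
    closed at 0, so boundary values (0.2, 0.4, 0.6, 0.8) belong to the
    class below; the grades partition [0, 1] exactly.
    Returns ``(grades, types)`` as categorical rasters (codes follow
    :data:`GRADE_NAMES` / :data:`TYPE_NAMES`; nodata = -1).
    """
    v = tvdi.data
    valid = tvdi.valid_mask
    grade = np.full(tvdi.shape, -1, dtype=np.int64)
    # np.digitize with right=True: value <= edge goes to the lower side
    grade[valid] = np.digitize(v[valid], [0.2, 0.4, 0.6, 0.8], right=True) + 1
    dtype_ = np.full(tvdi.shape, -1, dtype=np.int64)
    dtype_[valid] = np.digitize(v[valid], [0.6, 0.8], right=True)
    grades = tvdi.like(grade, nodata=-1, units="grade")
    types = tvdi.like(dtype_, nodata=-1, units="drought type")
    return grades, types


@dataclass
class MosaicDiagnostics:
    """Edge-effect diagnostic for a zone mosaic.

    Mean absolute TVDI difference between 4-neighbour pixel pairs straddling
    a zone boundary, versus pairs inside one zone.  Independently fitted
    edges make the boundary figure exceed the within-zone figure.
    """

    boundary_mean_abs_diff: float
    within_mean_abs_diff: float
    n_boundary_pairs: int
    n_within_pairs: int


def mosaic_zones(per_zone: dict[int, Raster], zones: ZoneMap) -> tuple[Raster, MosaicDiagnostics]:
    """Stitch per-zone TVDI grids: each pixel takes its own zone's value."""
    missing = [z for z in zones.zone_ids if z not in per_zone]
    if missing:
        raise ValueError(f"mosaic_zones: no TVDI grid for zone ids {missing}")
    out = np.full(zones.shape, np.nan)
    template = next(iter(per_zone.values()))
    for z, grid in per_zone.items():
        template.require_same_grid(grid, f"zone {z} grid")
        m = zones.mask_for(z) & grid.valid_mask
        out[m] = grid.data[m]
    diag = _neighbor_diagnostics(out, zones.data)
    return template.like(out, units="tvdi"), diag


def _neighbor_diagnostics(values: np.ndarray, zone_data: np.ndarray) -> MosaicDiagnostics:
    b_diffs, w_diffs = [], []
    for axis in (0, 1):
        v1 = np.moveaxis(values, axis, 0)
        z1 = np.moveaxis(zone_data, axis, 0)
        dv = np.abs(v1[1:] - v1[:-1])
        same = z1[1:] == z1[:-1]
        ok = ~np.isnan(dv)
        w_diffs.append(dv[ok & same])
        b_diffs.append(dv[ok & ~same])
    b = np.concatenate(b_diffs)
    w = np.concatenate(w_diffs)
    return MosaicDiagnostics(
        boundary_mean_abs_diff=float(b.mean()) if b.size else np.nan,
        within_mean_abs_diff=float(w.mean()) if w.size else np.nan,
        n_boundary_pairs=int(b.size),
        n_within_pairs=int(w.size),
    )
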