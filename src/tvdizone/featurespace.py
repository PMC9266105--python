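"""NDVI-LST feature space construction and dry/wet edge fitting.

Within one zone, the scatter of LST against NDVI is triangular: the upper
envelope (dry edge, fully dry surfaces) falls with NDVI while the lower
envelope (wet edge, saturated surfaces) rises.  Both edges are estimated by
slicing NDVI into fixed-width bins, taking the per-bin maximum and minimum
LST, and fitting ordinary least squares lines through those extrema:

    wet edge:  LSTmin = a1 + b1 * NDVI      (b1 > 0 expected)
    dry edge:  LSTmax = a2 + b2 * NDVI      (b2 < 0 expected)

Low-NDVI pixels are excluded by default (NDVI < 0.2) because the index is a
poor vegetation measure there and drags the wet edge down; one designated
zone may use the full [0, 1] range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rasters import Raster

__all__ = ["FeatureSpaceBins", "EdgeFit", "bin_extrema", "fit_edges"]

DEFAULT_NDVI_RANGE = (0.2, 1.0)
DEFAULT_BIN_WIDTH = 0.01


class EmptyFeatureSpaceError(ValueError):
    """No valid pixels fall inside the configured NDVI range."""


class InsufficientBinsError(ValueError):
    """Too few retained bins to fit the edges."""


@dataclass
class FeatureSpaceBins:
    """Per-NDVI-bin LST extrema.

    ``bins`` rows are ``(ndvi_mid, lst_max, lst_min, pixel_count)`` sorted by
    ndvi_mid; only bins with at least ``min_count`` pixels are retained.
    """

    ndvi_lo: float
    ndvi_hi: float
    bin_width: float
    bins: np.ndarray  # shape (k, 4)

    @property
    def ndvi_mid(self) -> np.ndarray:
        return self.bins[:, 0]

    @property
    def lst_max(self) -> np.ndarray:
        return self.bins[:, 1]

    @property
    def lst_min(self) -> np.ndarray:
        return self.bins[:, 2]

    @property
    def counts(self) -> np.ndarray:
        return self.bins[:, 3]


@dataclass
class EdgeFit:
    """Fitted wet/dry edge coefficients for one zone with diagnostics."""

    zone_id: int
    a1: float  # wet-edge intercept (degC)
    b1: float  # wet-edge slope (degC per NDVI unit)
    a2: float  # dry-edge intercept
    b2: float  # dry-edge slope
    r2_wet: float
    r2_dry: float
    n_bins_used: int
    ndvi_lo: float = DEFAULT_NDVI_RANGE[0]
    ndvi_hi: float = DEFAULT_NDVI_RANGE[1]
    degenerate: bool = False

    def wet(self, ndvi) -> np.ndarray:
        return self.a1 + self.b1 * np.asarray(ndvi, dtype=float)

    def dry(self, ndvi) -> np.ndarray:
        return self.a2 + self.b2 * np.asarray(ndvi, dtype=float)

    def check_degenerate(self) -> bool:
        """Dry edge must stay strictly above wet over the fitted NDVI range."""
        lo, hi = self.ndvi_lo, self.ndvi_hi
        return bool(min(self.dry(lo) - self.wet(lo), self.dry(hi) - self.wet(hi)) <= 0)


def bin_extrema(
    ndvi: Raster,
    lst: Raster,
    ndvi_range: tuple[float, float] = DEFAULT_NDVI_RANGE,
    bin_width: float = DEFAULT_BIN_WIDTH,
    min_count: int = 1,
    mask: np.ndarray | None = None,
) -> FeatureSpaceBins:
    """Per-NDVI-bin max/min LST over valid pixels.

    Bins are half-open ``[lo + k*w, lo + (k+1)*w)`` except the last, which is
    closed at ``hi`` so every in-range pixel maps to exactly one bin.  An
    optional boolean ``mask`` restricts the pixels considered (e.g. one
    zone, or a water mask).
    """
    lo, hi = ndvi_range
    if not lo < hi:
        raise ValueError(f"ndvi_range must satisfy lo < hi, got ({lo}, {hi})")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    ndvi.require_same_grid(lst, "lst")
    valid = ndvi.valid_mask & lst.valid_mask
    if mask is not None:
        valid &= mask
    n = ndvi.data[valid]
    t = lst.data[valid]
    in_range = (n >= lo) & (n <= hi)
    n, t = n[in_range], t[in_range]
    if n.size == 0:
        raise EmptyFeatureSpaceError(
            f"no valid pixels with NDVI in [{lo}, {hi}]"
        )
    n_bins = int(np.ceil((hi - lo) / bin_width - 1e-12))
    k = np.minimum((np.floor((n - lo) / bin_width)).astype(int), n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = k == b
        cnt = int(sel.sum())
        if cnt < max(min_count, 1):
            continue
        tb = t[sel]
        rows.append((lo + (b + 0.5) * bin_width, tb.max(), tb.min(), cnt))
    return FeatureSpaceBins(lo, hi, bin_width, np.array(rows, dtype=float))


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line y = a + b*x; returns (a, b, r2)."""
    b, a = np.polyfit(x, y, 1)
    fitted = a + b * x
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return float(a), float(b), min(r2, 1.0)


def fit_edges(bins: FeatureSpaceBins, zone_id: int = 0) -> EdgeFit:
    """OLS of bin LST extrema on bin-mid NDVI: maxima give the dry edge
    (a2, b2), minima the wet edge (a1, b1).  A fit whose dry edge dips below
    its wet edge anywhere on the range is flagged ``degenerate`` (kept, so
    callers can report it) rather than raised.
    """
    if len(bins.bins) < 3:
        raise InsufficientBinsError(
            f"zone {zone_id}: {len(bins.bins)} bins retained, need >= 3"
        )
    x = bins.ndvi_mid
    a1, b1, r2_wet = _ols_line(x, bins.lst_min)
    a2, b2, r2_dry = _ols_line(x, bins.lst_max)
    fit = EdgeFit(
        zone_id=zone_id, a1=a1, b1=b1, a2=a2, b2=b2,
        r2_wet=r2_wet, r2_dry=r2_dry, n_bins_used=len(bins.bins),
        ndvi_lo=bins.ndvi_lo, ndvi_hi=bins.ndvi_hi,
    )
    fit.degenerate = fit.check_degenerate()
    return fit
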