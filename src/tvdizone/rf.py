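"""Random-forest attribution of TVDI to environmental factors.

Eight factors — annual precipitation, annual mean temperature, elevation,
slope, aspect, distance to built-up land, distance to water, and land use —
are aggregated to an analysis grid (default 4x the native cell), stacked
into a sample table against annual-mean TVDI, and fed to a random-forest
regressor.  Importance is impurity-based (the node-purity-increase measure:
total variance reduction credited to splits on each factor, one-hot land-use
columns summed back into a single entry), and factor-response relationships
are summarised with classical partial-dependence curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .rasters import Raster, ZoneMap
from .synthetic import LANDUSE_CATEGORIES

__all__ = [
    "FACTOR_COLUMNS",
    "assemble_samples",
    "fit_rf",
    "dependence_curve",
    "RandomForestReport",
    "DependenceCurve",
]

FACTOR_COLUMNS = [
    "precip", "temp", "elevation", "slope", "aspect",
    "dist_built", "dist_water", "landuse",
]
CONTINUOUS = FACTOR_COLUMNS[:-1]


def _block_reduce(data: np.ndarray, cell: int, how: str) -> np.ndarray:
    """Aggregate cell x cell blocks by mean or mode (trailing remainders drop)."""
    rows, cols = data.shape
    r, c = rows // cell, cols // cell
    blocks = data[: r * cell, : c * cell].reshape(r, cell, c, cell)
    if how == "mean":
        return np.nanmean(blocks, axis=(1, 3))
    # mode with deterministic ties: smallest category code wins (documented)
    out = np.empty((r, c), dtype=data.dtype)
    flat = blocks.transpose(0, 2, 1, 3).reshape(r, c, cell * cell)
    for i in range(r):
        for j in range(c):
            vals, counts = np.unique(flat[i, j], return_counts=True)
            out[i, j] = vals[np.argmax(counts)]  # first max = smallest code
    return out


def assemble_samples(
    factors: dict[str, Raster],
    tvdi: Raster,
    zones: ZoneMap,
    cell: int = 4,
) -> pd.DataFrame:
    """Sample table at the analysis resolution: one row per complete cell.

    Continuous factors aggregate by block mean, the categorical land-use
    factor by block mode (ties break to the lowest category code), the
    response TVDI by block mean.  Rows with any missing value are dropped;
    the count of dropped rows is stored in ``df.attrs['n_dropped']``.
    Columns: the eight factors, ``tvdi``, and ``zone`` (block-mode zone id).
    """
    missing = [f for f in FACTOR_COLUMNS if f not in factors]
    if missing:
        raise ValueError(f"assemble_samples: missing factors {missing}")
    if cell < 1:
        raise ValueError("cell must be >= 1")
    cols = {}
    for name in CONTINUOUS:
        r = factors[name]
        zones.require_same_grid(r, name)
        with np.errstate(invalid="ignore"):
            cols[name] = _block_reduce(r.data.astype(float), cell, "mean").ravel()
    lu = factors["landuse"]
    zones.require_same_grid(lu, "landuse")
    cols["landuse"] = _block_reduce(lu.data, cell, "mode").ravel()
    zones.require_same_grid(tvdi, "tvdi")
    cols["tvdi"] = _block_reduce(
        np.where(tvdi.valid_mask, tvdi.data, np.nan), cell, "mean"
    ).ravel()
    cols["zone"] = _block_reduce(zones.data, cell, "mode").ravel()
    df = pd.DataFrame(cols)
    n_before = len(df)
    complete = df.notna().all(axis=1) & (df["landuse"] != int(lu.nodata)) & (df["zone"] > 0)
    df = df[complete].reset_index(drop=True)
    if df.empty:
        raise ValueError("assemble_samples: zero complete rows retained")
    df.attrs["n_dropped"] = n_before - len(df)
    return df


@dataclass
class RandomForestReport:
    """Fitted forest with importance ranking and holdout skill."""

    model: RandomForestRegressor
    importance: pd.DataFrame      # index: factor, columns: importance, rank
    holdout_r2: float
    n_train: int
    n_test: int
    feature_names: list[str]      # encoded (one-hot) design column order

    def top_factor(self) -> str:
        return str(self.importance["rank"].idxmin())


def _encode(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Design matrix: continuous factors as-is, land use one-hot per category."""
    parts = [table[CONTINUOUS].to_numpy(dtype=float)]
    names = list(CONTINUOUS)
    lu = table["landuse"].to_numpy()
    for code, cat in enumerate(LANDUSE_CATEGORIES):
        parts.append((lu == code).astype(float)[:, None])
        names.append(f"landuse={cat}")
    return np.hstack(parts), names


def fit_rf(
    table: pd.DataFrame,
    train_fraction: float = 0.7,
    seed: int = 0,
    n_trees: int = 500,
) -> RandomForestReport:
    """Seeded 70/30 fit of TVDI on the eight factors.

    The split permutes row indices with the given seed and takes exactly
    ``floor(train_fraction * n)`` training rows.  Importance is the forest's
    normalised impurity decrease, with one-hot land-use importances summed
    into one ``landuse`` entry; ranks are 1 (most important) to 8.
    """
    if len(table) < 100:
        raise ValueError(f"need >= 100 rows to fit, got {len(table)}")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    y = table["tvdi"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("degenerate response: TVDI is constant")
    X, names = _encode(table)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(table))
    n_train = floor(train_fraction * len(table))
    tr, te = order[:n_train], order[n_train:]
    model = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    model.fit(X[tr], y[tr])
    holdout_r2 = float(model.score(X[te], y[te]))
    imp = pd.Series(model.feature_importances_, index=names)
    collapsed = {f: float(imp[f]) for f in CONTINUOUS}
    collapsed["landuse"] = float(imp[[n for n in names if n.startswith("landuse=")]].sum())
    report = pd.DataFrame({"importance": pd.Series(collapsed)})
    report["rank"] = report["importance"].rank(ascending=False, method="first").astype(int)
    report.index.name = "factor"
    return RandomForestReport(
        model=model,
        importance=report.sort_values("rank"),
        holdout_r2=holdout_r2,
        n_train=len(tr),
        n_test=len(te),
        feature_names=names,
    )


@dataclass
class DependenceCurve:
    """Partial dependence of predicted TVDI on one factor."""

    factor: str
    grid: np.ndarray        # factor values (or category codes)
    mean_prediction: np.ndarray
    categories: list[str] | None = None

    def as_frame(self) -> pd.DataFrame:
        idx = self.categories if self.categories is not None else self.grid
        return pd.DataFrame({"value": idx, "mean_tvdi": self.mean_prediction})


def dependence_curve(
    report: RandomForestReport,
    table: pd.DataFrame,
    factor: str,
    n_points: int = 25,
) -> DependenceCurve:
    """Classical partial dependence: force the factor to each grid value and
    average the forest's predictions over the sample.  Continuous factors
    are evaluated on an even grid spanning the observed range; the land-use
    factor is evaluated per category.
    """
    if factor not in FACTOR_COLUMNS:
        raise ValueError(f"unknown factor {factor!r}; expected one of {FACTOR_COLUMNS}")
    X, names = _encode(table)
    if factor == "landuse":
        onehot_idx = [names.index(f"landuse={c}") for c in LANDUSE_CATEGORIES]
        present = sorted(int(v) for v in table["landuse"].unique())
        means = []
        for code in present:
            Xv = X.copy()
            Xv[:, onehot_idx] = 0.0
            Xv[:, onehot_idx[code]] = 1.0
            means.append(float(report.model.predict(Xv).mean()))
        return DependenceCurve(
            factor, np.array(present, dtype=float), np.array(means),
            categories=[LANDUSE_CATEGORIES[c] for c in present],
        )
    col = names.index(factor)
    vals = table[factor].to_numpy(dtype=float)
    grid = np.linspace(vals.min(), vals.max(), n_points)
    means = []
    for v in grid:
        Xv = X.copy()
        Xv[:, col] = v
        means.append(float(report.model.predict(Xv).mean()))
    return DependenceCurve(factor, grid, np.array(means))
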