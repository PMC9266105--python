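"""Zone indicator table and systematic (hierarchical) cluster analysis.

Each geomorphic zone is summarised by nine indicators of its drought regime:
the maximum, minimum, mean and standard deviation of its annual-mean TVDI
over the study years; the zone-mean trend slope (scaled, see below); and the
area fractions of the four upper trend classes (non-significant decrease
through extremely significant increase).  Zones are then grouped by
agglomerative clustering with correlation distance d = 1 - Pearson(row_u,
row_v) and average linkage — rows are used unstandardised because Pearson
distance is already location/scale-invariant per row.

A reference indicator matrix for the eight geomorphological divisions of the
Qinghai-Tibet Plateau (AQM, QHB, KWKM, CEKM, QP, STR, HMLY, HDM), published
for the 2000-2019 drought regime, ships with the package; cutting its
dendrogram at three groups separates the humid southern divisions
(HMLY, HDM), the central divisions (QP, STR, AQM) and the arid north-central
divisions (KWKM, CEKM, QHB).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .rasters import Raster, ZoneMap
from .trends import area_fractions

__all__ = [
    "INDICATOR_COLUMNS",
    "build_indicator_table",
    "load_reference_indicators",
    "cluster_zones",
    "Dendrogram",
    "ZonePartition",
]

INDICATOR_COLUMNS = [
    "TVDI-Max", "TVDI-Min", "TVDI-Mean", "TVDI-SD", "Slope-Mean",
    "TVDI-t3", "TVDI-t4", "TVDI-t5", "TVDI-t6",
]

# The published slope-mean values span roughly -3 to 10, i.e. the raw
# TVDI/yr slope times 1e3; the builder applies the same scale by default.
DEFAULT_SLOPE_SCALE = 1e3


def build_indicator_table(
    annual_tvdi: list[Raster],
    slopes: Raster,
    trend_classes: Raster,
    zones: ZoneMap,
    slope_scale: float = DEFAULT_SLOPE_SCALE,
    zone_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Nine-indicator row per zone from annual TVDI, slope and class grids.

    The min/max/mean/SD indicators are statistics of the *zone-mean annual
    TVDI series* (one value per year), matching how a per-division drought
    regime is summarised; area fractions come straight from the trend-class
    grid.  Empty zones yield NaN rows.
    """
    if not annual_tvdi:
        raise ValueError("need at least one annual TVDI grid")
    for r in annual_tvdi + [slopes, trend_classes]:
        zones.require_same_grid(r, "indicator input")
    frac = area_fractions(trend_classes, zones)
    rows = {}
    for z in zones.zone_ids:
        zmask = zones.mask_for(z)
        series = []
        for grid in annual_tvdi:
            m = zmask & grid.valid_mask
            series.append(float(grid.data[m].mean()) if m.any() else np.nan)
        series = np.asarray(series)
        sl_m = zmask & slopes.valid_mask
        slope_mean = float(slopes.data[sl_m].mean()) * slope_scale if sl_m.any() else np.nan
        rows[z] = {
            "TVDI-Max": np.nanmax(series),
            "TVDI-Min": np.nanmin(series),
            "TVDI-Mean": np.nanmean(series),
            "TVDI-SD": np.nanstd(series, ddof=0),
            "Slope-Mean": slope_mean,
            "TVDI-t3": frac.loc[z, "TVDI-t3"],
            "TVDI-t4": frac.loc[z, "TVDI-t4"],
            "TVDI-t5": frac.loc[z, "TVDI-t5"],
            "TVDI-t6": frac.loc[z, "TVDI-t6"],
        }
    table = pd.DataFrame.from_dict(rows, orient="index")[INDICATOR_COLUMNS]
    if zone_names:
        table.index = [zone_names.get(z, str(z)) for z in table.index]
    table.index.name = "zone"
    return table


def load_reference_indicators() -> pd.DataFrame:
    """Packaged QTP per-division indicator matrix (percent columns -> fractions)."""
    with resources.files("tvdizone.data").joinpath("qtp_zone_indicators.csv").open() as fh:
        df = pd.read_csv(fh, index_col="zone")
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].str.rstrip("%").astype(float) / 100.0
    return df


@dataclass
class Dendrogram:
    """Merge history of an agglomerative clustering."""

    linkage_matrix: np.ndarray
    labels: list[str]
    distance: str = "1 - Pearson correlation"
    linkage_method: str = "average"

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Newick text with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def rec(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


@dataclass
class ZonePartition:
    """k-group partition of zones with its dendrogram."""

    groups: dict[int, list[str]]          # group id -> zone labels
    assignment: dict[str, int]            # zone label -> group id
    dendrogram: Dendrogram

    def as_sets(self) -> set[frozenset]:
        return {frozenset(members) for members in self.groups.values()}


def correlation_distance_matrix(table: pd.DataFrame) -> np.ndarray:
    """Symmetric d = 1 - Pearson(row_u, row_v); errors on constant rows."""
    X = table.to_numpy(dtype=float)
    const = X.std(axis=1) == 0
    if const.any():
        bad = list(table.index[const])
        raise ValueError(f"constant indicator rows (correlation undefined): {bad}")
    return 1.0 - np.corrcoef(X)


def cluster_zones(
    table: pd.DataFrame,
    k: int = 3,
    method: str = "average",
) -> ZonePartition:
    """Agglomerative clustering of indicator rows, cut into ``k`` groups."""
    if len(table) < k:
        raise ValueError(f"{len(table)} zones cannot form {k} groups")
    if table.isna().any().any():
        bad = list(table.index[table.isna().any(axis=1)])
        raise ValueError(f"indicator rows with missing values: {bad}")
    D = correlation_distance_matrix(table)
    Z = hierarchy.linkage(squareform(D, checks=False), method=method)
    flat = hierarchy.fcluster(Z, k, criterion="maxclust")
    labels = [str(i) for i in table.index]
    groups: dict[int, list[str]] = {}
    for lab, g in zip(labels, flat):
        groups.setdefault(int(g), []).append(lab)
    dend = Dendrogram(Z, labels, linkage_method=method)
    return ZonePartition(
        groups=groups,
        assignment={lab: int(g) for lab, g in zip(labels, flat)},
        dendrogram=dend,
    )
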