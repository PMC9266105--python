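"""Plain-text raster containers and I/O.

All gridded quantities in the pipeline (NDVI, LST, TVDI, climate fields,
static factors, zone labels, class maps) travel as :class:`Raster`: a 2-D
numpy array plus the minimal geo-metadata of an ESRI ASCII grid (lower-left
corner, square cell size, nodata sentinel).  Continuous rasters use NaN for
nodata in memory; categorical rasters use an integer sentinel.  Files are
written in the ESRI ASCII grid format (.asc), which any GIS reads directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Raster", "ZoneMap", "read_ascii_grid", "write_ascii_grid"]

DEFAULT_NODATA = -9999.0


@dataclass
class Raster:
    """Single-band 2-D grid with affine placement and a nodata convention.

    Parameters
    ----------
    data:
        2-D array. Float arrays mark nodata as NaN; integer arrays use
        ``int(nodata)``.
    xll, yll:
        Coordinates of the lower-left corner of the lower-left cell (m).
    cellsize:
        Square cell edge length (m). Default 1000 m, the native resolution
        of the MODIS products this pipeline is designed around.
    nodata:
        Sentinel written to disk (and used in-memory for integer grids).
    units:
        Free-text unit label carried along for provenance.
    """

    data: np.ndarray
    xll: float = 0.0
    yll: float = 0.0
    cellsize: float = 1000.0
    nodata: float = DEFAULT_NODATA
    units: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"Raster data must be 2-D, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def is_integer(self) -> bool:
        return np.issubdtype(self.data.dtype, np.integer)

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata) cells."""
        if self.is_integer:
            return self.data != int(self.nodata)
        return ~np.isnan(self.data)

    def values(self) -> np.ndarray:
        """Valid cell values as a flat array."""
        return self.data[self.valid_mask]

    def like(self, data: np.ndarray, **overrides) -> "Raster":
        """New plain Raster with this grid's placement/nodata and fresh data.

        Always returns the base class (a float grid derived from a ZoneMap
        must not inherit integer-casting behaviour).
        """
        kwargs = dict(xll=self.xll, yll=self.yll, cellsize=self.cellsize,
                      nodata=self.nodata, units=self.units)
        kwargs.update(overrides)
        return Raster(np.asarray(data), **kwargs)

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.xll, other.xll)
            and np.isclose(self.yll, other.yll)
            and np.isclose(self.cellsize, other.cellsize)
        )

    def require_same_grid(self, other: "Raster", what: str = "raster") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"co-registration error: {what} grid {other.shape} @"
                f" ({other.xll},{other.yll},{other.cellsize}) does not match"
                f" {self.shape} @ ({self.xll},{self.yll},{self.cellsize})"
            )


@dataclass
class ZoneMap(Raster):
    """Integer-labelled raster partitioning the domain into geomorphic zones.

    Zone ids are positive integers; ``nodata`` cells lie outside the domain.
    """

    nodata: float = -1

    def __post_init__(self) -> None:
        super().__post_init__()
        if not self.is_integer:
            self.data = self.data.astype(np.int64)

    @property
    def zone_ids(self) -> list[int]:
        ids = np.unique(self.data[self.valid_mask])
        return [int(z) for z in ids]

    def mask_for(self, zone_id: int) -> np.ndarray:
        return self.data == zone_id


def write_ascii_grid(raster: Raster, path: str | Path) -> Path:
    """Write a raster as an ESRI ASCII grid (plain text)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = raster.data
    if not raster.is_integer:
        data = np.where(np.isnan(data), raster.nodata, data)
    nrows, ncols = raster.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {raster.xll}\n"
        f"yllcorner {raster.yll}\n"
        f"cellsize {raster.cellsize}\n"
        f"NODATA_value {int(raster.nodata) if raster.is_integer else raster.nodata}\n"
    )
    fmt = "%d" if raster.is_integer else "%.8g"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt=fmt)
    return path


def read_ascii_grid(path: str | Path, categorical: bool = False) -> Raster:
    """Read an ESRI ASCII grid; NaN-masks nodata unless ``categorical``."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    if categorical:
        data = data.astype(np.int64)
        cls = ZoneMap if categorical == "zones" else Raster
        return cls(
            data,
            xll=header["xllcorner"],
            yll=header["yllcorner"],
            cellsize=header["cellsize"],
            nodata=nodata,
        )
    data = data.astype(float)
    data[data == nodata] = np.nan
    return Raster(
        data,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=nodata,
    )
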