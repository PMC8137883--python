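"""Elevation grids for catchment hypsometry and ice-flow simulation.

Grids are planar with a metric cell size, so band areas convert directly to
km²; real DEMs must be supplied in a metric projection.  The text exchange
format is ESRI ASCII grid, with nodata marking cells outside the catchment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ElevationGrid"]

_NODATA = -9999.0


@dataclass
class ElevationGrid:
    """Cell elevations (m a.s.l.), square cell size (m), catchment mask."""

    z: np.ndarray
    cellsize: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.mask is None:
            self.mask = np.ones_like(self.z, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.z.ndim != 2:
            raise ValueError("elevation grid must be 2-D")
        if self.mask.shape != self.z.shape:
            raise ValueError("mask shape mismatch")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        if not np.isfinite(self.z[self.mask]).all():
            raise ValueError("non-finite elevations inside catchment")
        if not self.mask.any():
            raise ValueError("empty catchment mask")

    @property
    def cell_area_km2(self) -> float:
        return (self.cellsize / 1000.0) ** 2

    @property
    def catchment_area_km2(self) -> float:
        return float(self.mask.sum()) * self.cell_area_km2

    def band_areas(self, lo: float = 1000.0, hi: float = 6000.0, width: float = 100.0,
                   where: np.ndarray | None = None) -> "np.ndarray":
        """Area (km²) of catchment cells per elevation band [lo, hi)."""
        sel = self.mask if where is None else (self.mask & where)
        edges = np.arange(lo, hi + width, width)
        hist, _ = np.histogram(self.z[sel], bins=edges)
        return hist * self.cell_area_km2

    # -- ESRI ASCII ------------------------------------------------------
    def to_ascii(self, path: str | Path) -> None:
        ny, nx = self.z.shape
        data = np.where(self.mask, self.z, _NODATA)
        header = (
            f"ncols {nx}\nnrows {ny}\nxllcorner 0.0\nyllcorner 0.0\n"
            f"cellsize {self.cellsize}\nNODATA_value {_NODATA}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, data, fmt="%.3f")

    @classmethod
    def from_ascii(cls, path: str | Path) -> "ElevationGrid":
        header: dict[str, float] = {}
        with open(path) as fh:
            lines = fh.readlines()
        n_header = 0
        for line in lines:
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
            }:
                header[parts[0].lower()] = float(parts[1])
                n_header += 1
            else:
                break
        data = np.loadtxt(lines[n_header:])
        data = np.atleast_2d(data)
        nodata = header.get("nodata_value", _NODATA)
        mask = data != nodata
        return cls(z=np.where(mask, data, np.nan), cellsize=header["cellsize"], mask=mask)
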