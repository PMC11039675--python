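"""Lightweight planar geospatial containers.

The package works in a local equidistant plane: ``y`` is the alongshore
coordinate in km (increasing northward), ``x`` the cross-shore coordinate in
km (ocean lies at ``x`` less than the shore position).  Latitude is derived
as ``lat0 + y / KM_PER_DEG``.  At the sub-50-km scales involved the planar
Euclidean distance is indistinguishable from the great-circle distance, so
all distances are planar.

Rasters are stored as plain numpy grids with square cells and read/written
as ESRI ASCII grids (a plain-text interchange format readable by any GIS).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

KM_PER_DEG = 111.2


@dataclass
class Raster:
    """A single-band raster on a regular square grid.

    ``values[i, j]`` is the cell centred at ``(x0 + j*cell, y0 + i*cell)``;
    row 0 is the southernmost row.  NaN marks nodata (e.g. land in a
    bathymetry grid).
    """

    values: np.ndarray
    x0: float
    y0: float
    cell: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    @property
    def x_coords(self) -> np.ndarray:
        return self.x0 + self.cell * np.arange(self.nx)

    @property
    def y_coords(self) -> np.ndarray:
        return self.y0 + self.cell * np.arange(self.ny)

    def index_of(self, x, y):
        """Row/column of the cell containing each point (nearest centre)."""
        j = np.rint((np.asarray(x, dtype=float) - self.x0) / self.cell).astype(int)
        i = np.rint((np.asarray(y, dtype=float) - self.y0) / self.cell).astype(int)
        return i, j

    def contains(self, x, y):
        i, j = self.index_of(x, y)
        return (i >= 0) & (i < self.ny) & (j >= 0) & (j < self.nx)

    def sample(self, x, y):
        """Nearest-cell value at each point; NaN outside the grid."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        i, j = self.index_of(x, y)
        ok = (i >= 0) & (i < self.ny) & (j >= 0) & (j < self.nx)
        out = np.full(x.shape, np.nan)
        out[ok] = self.values[i[ok], j[ok]]
        return out

    def write_ascii(self, path) -> None:
        header = (
            f"ncols {self.nx}\nnrows {self.ny}\n"
            f"xllcorner {self.x0 - self.cell / 2}\n"
            f"yllcorner {self.y0 - self.cell / 2}\n"
            f"cellsize {self.cell}\nNODATA_value -9999\n"
        )
        vals = np.where(np.isnan(self.values), -9999.0, self.values)
        with open(path, "w") as fh:
            fh.write(header)
            # ESRI convention: first data row is the northernmost
            np.savetxt(fh, vals[::-1], fmt="%.6g")

    @classmethod
    def read_ascii(cls, path) -> "Raster":
        hdr = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                hdr[key.lower()] = float(val)
            vals = np.loadtxt(fh)
        vals = np.atleast_2d(vals)[::-1].copy()
        vals[vals == hdr["nodata_value"]] = np.nan
        cell = hdr["cellsize"]
        return cls(
            values=vals,
            x0=hdr["xllcorner"] + cell / 2,
            y0=hdr["yllcorner"] + cell / 2,
            cell=cell,
        )


@dataclass
class Coastline:
    """A north-south coastline polyline, parameterised by alongshore y.

    ``shore_x[i]`` is the cross-shore position of the shore at ``y[i]``;
    the ocean occupies ``x < shore_x``.  ``lat0`` anchors ``y = 0``.
    """

    y: np.ndarray
    shore_x: np.ndarray
    lat0: float = 42.0
    estuaries: list = field(default_factory=list)  # dicts: x, y, area_ha

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.shore_x = np.asarray(self.shore_x, dtype=float)
        if self.y.shape != self.shore_x.shape:
            raise ValueError("y and shore_x must have matching shapes")
        if np.any(np.diff(self.y) <= 0):
            raise ValueError("y must be strictly increasing")

    def shore_at(self, y):
        """Interpolated shore x-position at alongshore coordinate(s) y."""
        return np.interp(np.asarray(y, dtype=float), self.y, self.shore_x)

    def lat_of(self, y):
        return self.lat0 + np.asarray(y, dtype=float) / KM_PER_DEG

    def y_of_lat(self, lat):
        return (np.asarray(lat, dtype=float) - self.lat0) * KM_PER_DEG

    def arc_length(self) -> np.ndarray:
        """Cumulative along-shore arc length (km) at each vertex."""
        seg = np.hypot(np.diff(self.shore_x), np.diff(self.y))
        return np.concatenate([[0.0], np.cumsum(seg)])

    def to_geojson(self, path) -> None:
        line = {
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": [
                    [float(x), float(y)] for x, y in zip(self.shore_x, self.y)
                ],
            },
            "properties": {"lat0": self.lat0, "crs": "local-km"},
        }
        points = [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [e["x"], e["y"]]},
                "properties": {"area_ha": e["area_ha"], "kind": "estuary"},
            }
            for e in self.estuaries
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": [line] + points}, fh)

    @classmethod
    def from_geojson(cls, path) -> "Coastline":
        with open(path) as fh:
            fc = json.load(fh)
        line = next(
            f for f in fc["features"] if f["geometry"]["type"] == "LineString"
        )
        coords = np.asarray(line["geometry"]["coordinates"], dtype=float)
        estuaries = [
            {
                "x": f["geometry"]["coordinates"][0],
                "y": f["geometry"]["coordinates"][1],
                "area_ha": f["properties"]["area_ha"],
            }
            for f in fc["features"]
            if f["geometry"]["type"] == "Point"
        ]
        return cls(
            y=coords[:, 1],
            shore_x=coords[:, 0],
            lat0=line["properties"].get("lat0", 42.0),
            estuaries=estuaries,
        )
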