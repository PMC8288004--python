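"""Regular lon/lat climate rasters and text I/O.

Grids are stored south-up: ``values[iy, ix]`` covers the half-open cell
``[lon0 + ix*cell, lon0 + (ix+1)*cell) x [lat0 + iy*cell, lat0 + (iy+1)*cell)``
with the origin at the lower-left (south-west) corner.  Nodata cells are NaN
in memory.  On disk the ESRI ASCII grid format is used (rows written
north-to-south, as the format requires).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ClimateGrid"]


@dataclass
class ClimateGrid:
    """One climate variable on a regular WGS84 lon/lat grid.

    Parameters
    ----------
    name : variable name (e.g. ``"temp_seasonality"``).
    group : ``"temperature"`` or ``"precipitation"``.
    lon0, lat0 : coordinates of the lower-left (south-west) grid corner, degrees.
    cell : cell size in degrees (> 0).
    values : 2-D array, shape ``(ny, nx)``, row 0 southmost; NaN = nodata.
    """

    name: str
    group: str
    lon0: float
    lat0: float
    cell: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError(f"cell size must be positive, got {self.cell}")
        if self.group not in ("temperature", "precipitation"):
            raise ValueError(f"unknown variable group {self.group!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")

    # ------------------------------------------------------------------ geometry
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max)."""
        ny, nx = self.values.shape
        return (self.lon0, self.lat0, self.lon0 + nx * self.cell, self.lat0 + ny * self.cell)

    @property
    def lon_centers(self) -> np.ndarray:
        nx = self.values.shape[1]
        return self.lon0 + (np.arange(nx) + 0.5) * self.cell

    @property
    def lat_centers(self) -> np.ndarray:
        ny = self.values.shape[0]
        return self.lat0 + (np.arange(ny) + 0.5) * self.cell

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """Indices (iy, ix) of the half-open cell containing a point.

        Raises ``ValueError`` when the point falls outside the grid extent.
        """
        lon_min, lat_min, lon_max, lat_max = self.extent
        if not (lon_min <= lon < lon_max and lat_min <= lat < lat_max):
            raise ValueError(f"point ({lon}, {lat}) outside grid extent {self.extent}")
        ix = int(np.floor((lon - self.lon0) / self.cell))
        iy = int(np.floor((lat - self.lat0) / self.cell))
        return iy, ix

    def value_at(self, lon: float, lat: float) -> float:
        """Nearest-cell (containing-cell) value at a point; NaN for nodata."""
        iy, ix = self.cell_index(lon, lat)
        return float(self.values[iy, ix])

    # ------------------------------------------------------------------ text I/O
    def to_ascii(self, path, nodata: float = -9999.0) -> None:
        """Write as ESRI ASCII grid (rows north to south)."""
        ny, nx = self.values.shape
        vals = np.where(np.isnan(self.values), nodata, self.values)
        with open(path, "w") as fh:
            fh.write(f"ncols {nx}\n")
            fh.write(f"nrows {ny}\n")
            fh.write(f"xllcorner {float(self.lon0)!r}\n")
            fh.write(f"yllcorner {float(self.lat0)!r}\n")
            fh.write(f"cellsize {float(self.cell)!r}\n")
            fh.write(f"NODATA_value {float(nodata)!r}\n")
            for row in vals[::-1]:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def from_ascii(cls, path, name: str, group: str) -> "ClimateGrid":
        header: dict[str, float] = {}
        rows: list[list[float]] = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if parts[0].lower() in ("ncols", "nrows", "xllcorner", "yllcorner",
                                        "cellsize", "nodata_value"):
                    header[parts[0].lower()] = float(parts[1])
                else:
                    rows.append([float(v) for v in parts])
        values = np.array(rows[::-1], dtype=float)
        nodata = header.get("nodata_value", -9999.0)
        values[values == nodata] = np.nan
        return cls(name=name, group=group, lon0=header["xllcorner"],
                   lat0=header["yllcorner"], cell=header["cellsize"], values=values)
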