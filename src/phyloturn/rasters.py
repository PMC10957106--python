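"""Minimal single-band ESRI ASCII grid rasters.

Plate-carree only: a regular lon/lat lattice with square cells.  Data are
stored north-up (row 0 is the northern edge), matching the on-disk layout of
the ``.asc`` format.  This is all the raster machinery the pipeline needs:
value lookup at a coordinate, and text round-tripping.
"""

from __future__ import annotations

import numpy as np

__all__ = ["AsciiGrid"]


class AsciiGrid:
    """A single-band raster on a regular lon/lat grid."""

    def __init__(
        self,
        data: np.ndarray,
        xllcorner: float,
        yllcorner: float,
        cellsize: float,
        nodata: float = -9999.0,
    ):
        self.data = np.asarray(data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        self.xllcorner = float(xllcorner)
        self.yllcorner = float(yllcorner)
        self.cellsize = float(cellsize)
        self.nodata = float(nodata)

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    def contains(self, lon: float, lat: float) -> bool:
        return (
            self.xllcorner <= lon < self.xllcorner + self.ncols * self.cellsize
            and self.yllcorner <= lat < self.yllcorner + self.nrows * self.cellsize
        )

    def value_at(self, lon, lat):
        """Raster value at coordinates (scalar or arrays); NaN outside."""
        scalar = np.isscalar(lon) and np.isscalar(lat)
        lon_a, lat_a = np.broadcast_arrays(
            np.atleast_1d(np.asarray(lon, dtype=float)),
            np.atleast_1d(np.asarray(lat, dtype=float)),
        )
        col = np.floor((lon_a - self.xllcorner) / self.cellsize).astype(int)
        south_row = np.floor((lat_a - self.yllcorner) / self.cellsize).astype(int)
        row = self.nrows - 1 - south_row
        ok = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        out = np.full(lon_a.shape, np.nan)
        out[ok] = self.data[row[ok], col[ok]]
        out[out == self.nodata] = np.nan
        return float(out[0]) if scalar else out

    # ------------------------------------------------------------------ #
    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {self.xllcorner:.10g}\n")
            fh.write(f"yllcorner {self.yllcorner:.10g}\n")
            fh.write(f"cellsize {self.cellsize:.10g}\n")
            fh.write(f"NODATA_value {self.nodata:.10g}\n")
            for row in self.data:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def read(cls, path) -> "AsciiGrid":
        header: dict[str, float] = {}
        rows: list[list[float]] = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if parts[0].lower() in {
                    "ncols", "nrows", "xllcorner", "yllcorner",
                    "cellsize", "nodata_value",
                }:
                    header[parts[0].lower()] = float(parts[1])
                else:
                    rows.append([float(v) for v in parts])
        data = np.array(rows)
        if data.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValueError("ASCII grid data does not match header dimensions")
        return cls(
            data,
            header["xllcorner"],
            header["yllcorner"],
            header["cellsize"],
            header.get("nodata_value", -9999.0),
        )
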