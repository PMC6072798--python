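"""Minimal single-band raster container with plain-text (ESRI ASCII grid) I/O.

Backscatter and biomass grids are small enough at desk scale that a float
array plus a nodata convention covers everything the pipeline needs.  Nodata
is represented internally as NaN; the ASCII representation uses an explicit
sentinel value.  Row 0 is the top (northernmost) row, matching the on-disk
order of the ASCII grid format.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class Raster:
    """A single-band georeferenced grid.

    Parameters
    ----------
    data:
        2-D float array; NaN marks nodata.
    pixel_size:
        Ground pixel edge length in metres (default 25 m).
    year:
        Acquisition year, if meaningful for this band.
    origin:
        (x, y) of the lower-left corner in map units.
    """

    data: np.ndarray
    pixel_size: float = 25.0
    year: int | None = None
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def pixel_area_ha(self) -> float:
        """Area of one pixel in hectares (25 m pixel -> 0.0625 ha)."""
        return self.pixel_size**2 / 10_000.0

    # -- validity -------------------------------------------------------
    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.data)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def copy_with(self, data: np.ndarray, **kwargs) -> "Raster":
        """New raster sharing this raster's georeferencing."""
        return replace(self, data=np.asarray(data, dtype=float), **kwargs)

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) map coordinates of every pixel centre, shape == data.shape."""
        nrows, ncols = self.data.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.pixel_size
        ys = y0 + (nrows - np.arange(nrows) - 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    # -- I/O ------------------------------------------------------------
    def write_ascii(self, path: str | Path, nodata: float = -9999.0) -> None:
        write_ascii_grid(self, path, nodata=nodata)

    @classmethod
    def read_ascii(cls, path: str | Path, year: int | None = None) -> "Raster":
        return read_ascii_grid(path, year=year)


def write_ascii_grid(raster: Raster, path: str | Path, nodata: float = -9999.0) -> None:
    """Write an ESRI ASCII grid (.asc), a plain-text raster interchange format."""
    data = np.where(raster.valid, raster.data, nodata)
    nrows, ncols = data.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {raster.origin[0]:.6f}\n"
        f"yllcorner {raster.origin[1]:.6f}\n"
        f"cellsize {raster.pixel_size:.6f}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.8g")


def read_ascii_grid(path: str | Path, year: int | None = None) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid` (or any tool)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(value)
                pos = fh.tell()
            else:  # optional NODATA line absent
                break
        fh.seek(pos)
        data = np.loadtxt(fh, ndmin=2)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid shape {data.shape} disagrees with header in {path}")
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return Raster(
        data=data,
        pixel_size=header["cellsize"],
        year=year,
        origin=(header["xllcorner"], header["yllcorner"]),
    )
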