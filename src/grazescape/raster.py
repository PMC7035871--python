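"""Categorical raster container and plain-text (ESRI ASCII grid) I/O.

Grids live in a projected CRS with square cells in metres. Row 0 is the
northernmost row; ``origin`` is the (x, y) of the top-left corner of the
grid, so the centre of cell (i, j) is
``(x0 + (j + 0.5) c, y0 - (i + 0.5) c)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple, Union

import numpy as np

__all__ = ["LandCoverRaster", "read_ascii_grid", "write_ascii_grid"]

DEFAULT_CRS = "EPSG:32736"  # UTM WGS84 zone 36S
DEFAULT_NODATA = -9999


@dataclass
class LandCoverRaster:
    """Single-band categorical raster (integer class codes).

    ``crs_unit`` must be metres for any distance-based operation; a raster in
    a geographic (degree) CRS is rejected by the buffer extractor.
    """

    data: np.ndarray
    cell_size: float
    origin: Tuple[float, float] = (0.0, 0.0)
    crs: str = DEFAULT_CRS
    crs_unit: str = "m"
    nodata: int = DEFAULT_NODATA
    meta: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be a 2-D array")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("categorical raster requires an integer dtype")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.data.shape

    @property
    def bounds(self) -> Tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        rows, cols = self.data.shape
        x0, y0 = self.origin
        return (x0, y0 - rows * self.cell_size, x0 + cols * self.cell_size, y0)

    def cell_center(self, i, j):
        x0, y0 = self.origin
        c = self.cell_size
        return (x0 + (np.asarray(j) + 0.5) * c, y0 - (np.asarray(i) + 0.5) * c)

    def index_of(self, x: float, y: float) -> Tuple[int, int]:
        """Row/column of the cell containing (x, y); may be off-grid."""
        x0, y0 = self.origin
        c = self.cell_size
        return (int(np.floor((y0 - y) / c)), int(np.floor((x - x0) / c)))

    def in_grid(self, i: int, j: int) -> bool:
        rows, cols = self.data.shape
        return 0 <= i < rows and 0 <= j < cols

    def value_at(self, x: float, y: float) -> int:
        i, j = self.index_of(x, y)
        if not self.in_grid(i, j):
            raise ValueError(f"point ({x}, {y}) is outside the raster extent")
        return int(self.data[i, j])

    def class_proportions(self) -> Dict[int, float]:
        """Global class proportions (%) over non-nodata cells."""
        valid = self.data[self.data != self.nodata]
        if valid.size == 0:
            raise ValueError("raster has no valid cells")
        codes, counts = np.unique(valid, return_counts=True)
        return {int(k): 100.0 * n / valid.size for k, n in zip(codes, counts)}


def write_ascii_grid(raster: LandCoverRaster, path: Union[str, Path]) -> None:
    """Write as an ESRI ASCII grid (.asc), a GDAL-readable text format."""
    path = Path(path)
    rows, cols = raster.data.shape
    x0, y0 = raster.origin
    yll = y0 - rows * raster.cell_size
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner {x0!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {raster.cell_size!r}\n"
        f"NODATA_value {raster.nodata}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.data, fmt="%d")


def read_ascii_grid(
    path: Union[str, Path], crs: str = DEFAULT_CRS, crs_unit: str = "m"
) -> LandCoverRaster:
    path = Path(path)
    header: Dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh, dtype=np.int32, ndmin=2)
    rows, cols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (rows, cols):
        raise ValueError(
            f"grid body {data.shape} does not match header ({rows}, {cols})"
        )
    cell = header["cellsize"]
    if "xllcorner" in header:
        x0 = header["xllcorner"]
        y0 = header["yllcorner"] + rows * cell
    else:  # cell-centre registration
        x0 = header["xllcenter"] - cell / 2.0
        y0 = header["yllcenter"] - cell / 2.0 + rows * cell
    nodata = int(header.get("nodata_value", DEFAULT_NODATA))
    return LandCoverRaster(
        data=data, cell_size=cell, origin=(x0, y0), crs=crs,
        crs_unit=crs_unit, nodata=nodata,
    )
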