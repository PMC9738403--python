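"""Regular-grid rasters (population counts, density surfaces) and ESRI ASCII grid IO."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Raster", "write_ascii_grid", "read_ascii_grid"]


@dataclass(frozen=True)
class Raster:
    """A single-band raster on square cells in a planar meter frame.

    ``values`` has shape (ny, nx) with row 0 the *southernmost* row;
    ``origin`` is the lower-left corner of the grid.
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("raster values must be 2-D")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate vectors of cell centers (x: nx, y: ny)."""
        ny, nx = self.values.shape
        cx = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        cy = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        return cx, cy

    def total(self) -> float:
        return float(self.values.sum())


def write_ascii_grid(raster: Raster, path, nodata: float = -9999.0) -> None:
    """Write an ESRI ASCII grid (.asc); rows are stored north-to-south."""
    ny, nx = raster.values.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\n")
        fh.write(f"nrows {ny}\n")
        fh.write(f"xllcorner {raster.origin[0]:.6f}\n")
        fh.write(f"yllcorner {raster.origin[1]:.6f}\n")
        fh.write(f"cellsize {raster.cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in raster.values[::-1]:  # top row first
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_ascii_grid(path) -> Raster:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)[::-1]  # back to south-first rows
    return Raster(
        origin=(header["xllcorner"], header["yllcorner"]),
        cell_size=header["cellsize"],
        values=values,
    )
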