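"""Lightweight gridded-raster container shared by every sensor and metric module.

All synthetic layers live in one planar scene coordinate system (meters),
so a raster is fully described by its value array, its resolution and the
top-left corner of its extent. Row 0 is the northernmost (largest-y) row,
matching the top-left origin convention of GeoTIFF imagery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile


@dataclass
class Raster:
    """A single-band raster in scene coordinates.

    Parameters
    ----------
    values : ndarray of shape (nrows, ncols)
        Cell values; NaN marks missing cells.
    resolution : float
        Cell side length in meters (cells are square).
    origin : (float, float)
        (x, y) of the *top-left corner* of the top-left cell; y decreases
        with increasing row index.
    """

    values: np.ndarray
    resolution: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) of the raster in meters."""
        nrows, ncols = self.values.shape
        return ncols * self.resolution, nrows * self.resolution

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every cell center, each shaped like values."""
        nrows, ncols = self.values.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.resolution
        ys = y0 - (np.arange(nrows) + 0.5) * self.resolution
        return np.meshgrid(xs, ys)

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cells containing points (x, y); no bounds check."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.resolution).astype(int)
        row = np.floor((y0 - y) / self.resolution).astype(int)
        return row, col

    def sample(self, x, y):
        """Value of the cell containing each point; NaN outside the extent."""
        row, col = self.index_of(x, y)
        nrows, ncols = self.values.shape
        inside = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
        out = np.full(np.shape(row), np.nan, dtype=float)
        out[inside] = self.values[row[inside], col[inside]]
        if np.isscalar(x) or np.ndim(x) == 0:
            return float(out)
        return out

    def same_grid(self, other: "Raster", atol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.resolution - other.resolution) <= atol
            and abs(self.origin[0] - other.origin[0]) <= atol
            and abs(self.origin[1] - other.origin[1]) <= atol
        )

    def with_values(self, values: np.ndarray) -> "Raster":
        return replace(self, values=np.asarray(values, dtype=float))


def require_same_grid(*rasters: Raster) -> None:
    first = rasters[0]
    for r in rasters[1:]:
        if not first.same_grid(r):
            raise ValueError(
                f"rasters are not co-registered: shape/res/origin "
                f"{first.shape}/{first.resolution}/{first.origin} vs "
                f"{r.shape}/{r.resolution}/{r.origin}"
            )


def write_raster(path, raster: Raster, bands: dict[str, np.ndarray] | None = None) -> None:
    """Write a raster (or a named multi-band stack on its grid) as TIFF.

    Resolution and origin are stored in the TIFF resolution tag and the
    image description so a round trip preserves the grid.
    """
    if bands:
        data = np.stack([np.asarray(v, dtype=np.float32) for v in bands.values()])
        names = ",".join(bands.keys())
    else:
        data = raster.values.astype(np.float32)
        names = ""
    desc = f"resolution={raster.resolution};origin={raster.origin[0]},{raster.origin[1]};bands={names}"
    tifffile.imwrite(path, data, description=desc)


def read_raster(path) -> Raster | dict[str, Raster]:
    """Read a TIFF written by :func:`write_raster`."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray().astype(float)
        desc = tif.pages[0].tags.get("ImageDescription")
        desc = desc.value if desc is not None else ""
    meta = dict(item.split("=", 1) for item in desc.split(";") if "=" in item)
    resolution = float(meta.get("resolution", 1.0))
    ox, oy = (float(v) for v in meta.get("origin", "0,0").split(","))
    names = [n for n in meta.get("bands", "").split(",") if n]
    if data.ndim == 3 and names:
        return {
            name: Raster(band, resolution=resolution, origin=(ox, oy))
            for name, band in zip(names, data)
        }
    return Raster(np.atleast_2d(data), resolution=resolution, origin=(ox, oy))
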