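"""Discrete-return lidar products: DSM, DEM, CHM and individual-tree metrics.

First returns gridded at 0.5 m (max per cell) give the digital surface
model; last returns (min per cell) the digital elevation model; their
difference, clipped at zero, the canopy height model. Dominant and
co-dominant trees are found on the CHM with an adaptive local-maxima
filter whose circular search window scales with canopy height through a
calibrated height -> crown-radius line. Detected trees feed plot-level
stem density and crown-area-weighted height
(sum(Ca_i * H_i) / sum(Ca_i) — the crown-area analogue of Lorey's
basal-area-weighted height).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import Raster, require_same_grid


@dataclass
class SurfaceRaster(Raster):
    """A gridded surface: canopy top (DSM), ground (DEM) or height (CHM)."""

    kind: str = ""


@dataclass
class WindowModel:
    """Linear crown-radius-from-height model driving the search window.

    ``radius(h) = intercept + slope * h``, clipped to ``bounds`` — the range
    of crown radii seen in calibration.
    """

    intercept: float
    slope: float
    bounds: tuple[float, float]

    def predict(self, height) -> np.ndarray:
        r = self.intercept + self.slope * np.asarray(height, dtype=float)
        return np.clip(r, self.bounds[0], self.bounds[1])


def first_returns(cloud: pd.DataFrame) -> pd.DataFrame:
    return cloud.loc[cloud["return_index"] == 1]


def last_returns(cloud: pd.DataFrame) -> pd.DataFrame:
    return cloud.loc[cloud["return_index"] == cloud["n_returns"]]


def interpolate_surface(
    cloud: pd.DataFrame,
    which: str,
    resolution: float = 0.5,
    extent: tuple[float, float] | None = None,
) -> SurfaceRaster:
    """Grid first or last returns into a surface raster.

    Cell value is the max of in-cell elevations for first returns (canopy
    top) and the min for last returns (ground); cells without returns are
    filled from their nearest filled cell.
    """
    if which not in ("first", "last"):
        raise ValueError("which must be 'first' or 'last'")
    pts = first_returns(cloud) if which == "first" else last_returns(cloud)
    if len(pts) == 0:
        raise ValueError(f"no {which} returns in the point cloud")
    x = pts["x"].to_numpy()
    y = pts["y"].to_numpy()
    z = pts["elevation"].to_numpy()
    if extent is None:
        extent = (
            float(np.ceil(x.max() / resolution)) * resolution,
            float(np.ceil(y.max() / resolution)) * resolution,
        )
    ncols = max(1, int(round(extent[0] / resolution)))
    nrows = max(1, int(round(extent[1] / resolution)))
    grid = SurfaceRaster(
        np.full((nrows, ncols), np.nan), resolution, origin=(0.0, extent[1]),
        kind="DSM" if which == "first" else "DEM",
    )
    row, col = grid.index_of(x, y)
    ok = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
    row, col, z = row[ok], col[ok], z[ok]

    fill = -np.inf if which == "first" else np.inf
    acc = np.full((nrows, ncols), fill)
    if which == "first":
        np.maximum.at(acc, (row, col), z)
    else:
        np.minimum.at(acc, (row, col), z)
    empty = ~np.isfinite(acc)
    if empty.all():
        raise ValueError("no returns fall inside the requested extent")
    if empty.any():  # nearest-neighbor fill from populated cells
        _, (ri, ci) = ndimage.distance_transform_edt(empty, return_indices=True)
        acc = acc[ri, ci]
    grid.values[:] = acc
    return grid


def compute_chm(dsm: Raster, dem: Raster) -> SurfaceRaster:
    """Canopy height model: DSM - DEM, negatives (noise) clipped to zero."""
    require_same_grid(dsm, dem)
    chm = np.maximum(dsm.values - dem.values, 0.0)
    return SurfaceRaster(chm, dsm.resolution, origin=dsm.origin, kind="CHM")


def calibrate_window_model(heights, crown_radii) -> WindowModel:
    """Least-squares line of crown radius on height from calibration pairs."""
    h = np.asarray(heights, dtype=float)
    r = np.asarray(crown_radii, dtype=float)
    if len(h) < 2 or np.ptp(h) == 0:
        raise ValueError("need >= 2 calibration pairs with distinct heights")
    slope, intercept = np.polyfit(h, r, 1)
    return WindowModel(
        intercept=float(intercept),
        slope=float(slope),
        bounds=(float(r.min()), float(r.max())),
    )


def detect_trees(
    chm: Raster, window_model: WindowModel, min_height: float = 2.0
) -> pd.DataFrame:
    """Adaptive local-maxima individual-tree detection on the CHM.

    A cell is a tree top iff its height is >= ``min_height`` and strictly
    greater than every other cell within the circular window of radius
    ``window_model.predict(height)`` meters (floored at one cell so each
    window has neighbors); equal-valued ties are broken in favor of the
    first cell in row-major scan order, so a flat plateau is counted once.

    Returns a DataFrame with columns ``x, y, height, crown_radius,
    crown_area, h_times_diam`` (crown radius from the window model, crown
    area = pi r^2, and the height x crown-diameter product).
    """
    if min_height < 0:
        raise ValueError("min_height must be >= 0")
    values = chm.values
    nrows, ncols = values.shape
    res = chm.resolution
    radius_m = np.maximum(window_model.predict(values), res)
    # squared window radius in cell units; the offset set only changes at
    # integer values of di^2 + dj^2, so group cells by floor(rpx^2)
    rpx2 = np.floor((radius_m / res) ** 2).astype(int)

    eligible = values >= min_height
    candidate = np.zeros_like(values, dtype=bool)
    # prefilter with a few window-size buckets (each bucket's smallest
    # window is a necessary condition); the exact per-cell window is
    # verified in the candidate pass below
    uniq = np.unique(rpx2[eligible])
    for bucket in np.array_split(uniq, min(len(uniq), 6)):
        if len(bucket) == 0:
            continue
        fp = _circular_footprint(int(bucket[0]))
        local_max = ndimage.maximum_filter(
            values, footprint=fp, mode="constant", cval=-np.inf
        )
        in_bucket = (rpx2 >= bucket[0]) & (rpx2 <= bucket[-1])
        candidate |= eligible & in_bucket & (values >= local_max)

    rows, cols = np.nonzero(candidate)
    keep = np.ones(len(rows), dtype=bool)
    for i, (r0, c0) in enumerate(zip(rows, cols)):  # exact window + tie pass
        s = rpx2[r0, c0]
        rad = int(np.floor(np.sqrt(s)))
        r_lo, r_hi = max(0, r0 - rad), min(nrows, r0 + rad + 1)
        c_lo, c_hi = max(0, c0 - rad), min(ncols, c0 + rad + 1)
        patch = values[r_lo:r_hi, c_lo:c_hi]
        di = np.arange(r_lo, r_hi)[:, None] - r0
        dj = np.arange(c_lo, c_hi)[None, :] - c0
        inside = di**2 + dj**2 <= s
        v0 = values[r0, c0]
        if np.any(inside & (patch > v0)):
            keep[i] = False
            continue
        ties = inside & (patch == v0)
        tr, tc = np.nonzero(ties)
        scan = (tr + r_lo) * ncols + (tc + c_lo)
        if scan.min() < r0 * ncols + c0:
            keep[i] = False

    rows, cols = rows[keep], cols[keep]
    heights = values[rows, cols]
    crown_radius = window_model.predict(heights)
    x0, y0 = chm.origin
    return pd.DataFrame(
        {
            "x": x0 + (cols + 0.5) * res,
            "y": y0 - (rows + 0.5) * res,
            "height": heights,
            "crown_radius": crown_radius,
            "crown_area": np.pi * crown_radius**2,
            "h_times_diam": heights * 2.0 * crown_radius,
        }
    )


def _circular_footprint(rpx2: int) -> np.ndarray:
    """Boolean disk of all offsets with di^2 + dj^2 <= rpx2 (center included)."""
    rad = int(np.floor(np.sqrt(rpx2)))
    di = np.arange(-rad, rad + 1)[:, None]
    dj = np.arange(-rad, rad + 1)[None, :]
    return di**2 + dj**2 <= rpx2


def stem_density(trees: pd.DataFrame, area_m2: float) -> float:
    """Stems per hectare from a detected-tree table and the area searched."""
    if area_m2 <= 0:
        raise ValueError("area must be positive")
    return len(trees) / (area_m2 / 10_000.0)


def crown_area_weighted_height(trees: pd.DataFrame) -> float:
    """Crown-area-weighted mean height, sum(Ca*H)/sum(Ca); NaN if no trees."""
    if len(trees) == 0:
        return float("nan")
    ca = trees["crown_area"].to_numpy(dtype=float)
    h = trees["height"].to_numpy(dtype=float)
    if np.any(ca <= 0):
        raise ValueError("crown areas must be positive")
    return float((ca * h).sum() / ca.sum())
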