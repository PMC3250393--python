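"""Waveform-lidar habitat metrics.

From each large-footprint waveform: noise-threshold canopy-top detection,
ground correction against the high-resolution discrete-return DEM (the
waveform instrument's own ground finding is less reliable than the point
cloud's, while its canopy-top detection is kept), relative-height energy
quantiles RH25/50/75 and canopy top RH100, total canopy cover from the
normalized cumulative energy return, and an 8-bin canopy-cover profile in
5 m height intervals approximating the vertical foliage profile.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .raster import Raster
from .sensors import Waveform


class NoSignalError(ValueError):
    """Raised when no waveform bin rises above the noise threshold."""


@dataclass
class RHMetrics:
    """Relative-height energy quantiles, meters above ground."""

    rh25: float
    rh50: float
    rh75: float
    rh100: float


@dataclass
class CoverProfile:
    """Total canopy cover plus cover in 5 m bins from 0 to 40 m."""

    total_cover: float
    bin_cover: np.ndarray  # 8 fractions, bins [0,5), [5,10), ..., [35,40+]


def footprint_ground(dem: Raster, center: tuple[float, float], diameter: float) -> float:
    """Mean DEM ground elevation within the footprint circle."""
    cx, cy = center
    r = diameter / 2.0
    nrows, ncols = dem.values.shape
    res = dem.resolution
    # clip the circle's bounding box to the grid, then mask locally
    r0, c0 = dem.index_of(cx - r, cy + r)
    r1, c1 = dem.index_of(cx + r, cy - r)
    r0, r1 = max(0, min(r0, r1)), min(nrows - 1, max(r0, r1))
    c0, c1 = max(0, min(c0, c1)), min(ncols - 1, max(c0, c1))
    if r0 > r1 or c0 > c1:
        raise ValueError(f"footprint at {center} outside the DEM")
    x0, y0 = dem.origin
    xs = x0 + (np.arange(c0, c1 + 1) + 0.5) * res
    ys = y0 - (np.arange(r0, r1 + 1) + 0.5) * res
    dx2 = (xs[None, :] - cx) ** 2
    dy2 = (ys[:, None] - cy) ** 2
    mask = dx2 + dy2 <= r**2
    if not mask.any():
        val = dem.sample(cx, cy)
        if np.isnan(val):
            raise ValueError(f"footprint at {center} outside the DEM")
        return float(val)
    return float(dem.values[r0 : r1 + 1, c0 : c1 + 1][mask].mean())


def detect_canopy_top(waveform: Waveform, k_sigma: float = 4.0) -> float:
    """Highest axis position whose amplitude exceeds the noise threshold
    ``noise_mean + k_sigma * noise_sd``."""
    if len(waveform.axis) == 0:
        raise ValueError("empty waveform")
    threshold = waveform.noise_mean + k_sigma * waveform.noise_sd
    above = waveform.amplitude > threshold
    if not above.any():
        raise NoSignalError("no waveform bin above the noise threshold")
    return float(waveform.axis[above].max())


def ground_correct(waveform: Waveform, ground_elevation: float) -> Waveform:
    """Re-express the elevation axis as height above the DRL ground."""
    if not np.isfinite(ground_elevation):
        raise ValueError("ground elevation must be finite")
    return replace(
        waveform,
        axis=waveform.axis - ground_elevation,
        reference="height",
        ground_elevation=float(ground_elevation),
    )


def _signal(waveform: Waveform) -> np.ndarray:
    """Noise-floor-subtracted amplitudes, negatives clipped to zero."""
    return np.maximum(waveform.amplitude - waveform.noise_mean, 0.0)


def rh_metrics(
    waveform: Waveform,
    k_sigma: float = 4.0,
    include_ground: bool = True,
    split_height: float = 2.0,
) -> RHMetrics:
    """RH quantiles of a height-referenced (ground-corrected) waveform.

    The noise floor is subtracted and negatives clipped; energy is
    accumulated from the lowest bin upward over bins at or below the
    detected canopy top; RHq is the height at which the cumulative energy
    first reaches q% of the total, linearly interpolated within the
    crossing bin and clipped at the canopy top. RH100 is the canopy-top
    height itself. With ``include_ground=False`` energy below
    ``split_height`` is excluded from the totals (alternate convention).
    """
    if waveform.reference != "height":
        raise ValueError("rh_metrics expects a ground-corrected waveform")
    top = detect_canopy_top(waveform, k_sigma)
    sig = _signal(waveform)
    axis = waveform.axis
    use = axis <= top
    if not include_ground:
        use &= axis >= split_height
    energy = np.where(use, sig, 0.0)
    total = energy.sum()
    if total <= 0:
        raise NoSignalError("zero signal energy after noise subtraction")

    order = np.argsort(axis)
    e = energy[order]
    h = axis[order]
    cum = np.cumsum(e)
    w = waveform.bin_width
    out = {}
    for q in (25, 50, 75):
        target = total * q / 100.0
        i = int(np.searchsorted(cum, target))
        before = cum[i - 1] if i > 0 else 0.0
        frac = (target - before) / e[i] if e[i] > 0 else 1.0
        out[q] = min(h[i] - w / 2.0 + frac * w, top)
    return RHMetrics(rh25=out[25], rh50=out[50], rh75=out[75], rh100=top)


def canopy_cover(
    waveform: Waveform, rho_ratio: float = 1.0, split_height: float = 2.0,
    k_sigma: float = 4.0,
) -> float:
    """Total canopy cover from the normalized cumulative energy return.

    ``cover = E_canopy / (E_canopy + rho_ratio * E_ground)`` with canopy
    energy above ``split_height`` (up to the detected top) and ground
    energy at or below it. ``rho_ratio`` adjusts for the canopy/ground
    reflectance difference.
    """
    if waveform.reference != "height":
        raise ValueError("canopy_cover expects a ground-corrected waveform")
    top = detect_canopy_top(waveform, k_sigma)
    sig = _signal(waveform)
    axis = waveform.axis
    e_canopy = sig[(axis > split_height) & (axis <= top)].sum()
    e_ground = sig[axis <= split_height].sum()
    denom = e_canopy + rho_ratio * e_ground
    if denom <= 0:
        raise NoSignalError("zero signal energy")
    return float(e_canopy / denom)


def cover_profile(
    waveform: Waveform, rho_ratio: float = 1.0, split_height: float = 2.0,
    k_sigma: float = 4.0, n_bins: int = 8, bin_height: float = 5.0,
) -> CoverProfile:
    """Canopy-cover profile in 5 m height bins from 0 to 40 m.

    Bin b spans heights [5b, 5b+5); signal above the last bin edge is added
    to the top bin; signal below 0 m is the ground term. Each bin's cover
    is its energy over ``E_above_ground + rho_ratio * E_ground``, so the
    profile approximates the vertical foliage distribution.
    """
    if waveform.reference != "height":
        raise ValueError("cover_profile expects a ground-corrected waveform")
    top = detect_canopy_top(waveform, k_sigma)
    sig = _signal(waveform)
    axis = waveform.axis
    in_sig = axis <= top
    e_ground = sig[in_sig & (axis <= 0.0)].sum()
    bins = np.zeros(n_bins)
    for b in range(n_bins):
        lo = b * bin_height
        hi = (b + 1) * bin_height if b < n_bins - 1 else np.inf
        bins[b] = sig[in_sig & (axis > lo) & (axis <= hi) & (axis > 0.0)].sum()
    # bin 0 starts strictly above 0 so ground + bins partition the signal
    denom = bins.sum() + rho_ratio * e_ground
    if denom <= 0:
        raise NoSignalError("zero signal energy")
    total = canopy_cover(waveform, rho_ratio, split_height, k_sigma)
    return CoverProfile(total_cover=total, bin_cover=bins / denom)


def metrics_table(
    waveforms: list[Waveform],
    dem: Raster,
    k_sigma: float = 4.0,
    rho_ratio: float = 1.0,
    split_height: float = 2.0,
) -> pd.DataFrame:
    """Per-footprint waveform metrics joined with the DRL ground elevation.

    Footprints with no detectable signal (or outside the DEM) yield NaN
    metric rows so the downstream missing-data exclusion can act on them.
    """
    rows = []
    for wf in waveforms:
        row = {
            "footprint_id": wf.footprint_id,
            "x": wf.center[0],
            "y": wf.center[1],
        }
        try:
            ground = footprint_ground(dem, wf.center, wf.diameter)
            corrected = ground_correct(wf, ground)
            rh = rh_metrics(corrected, k_sigma)
            prof = cover_profile(corrected, rho_ratio, split_height, k_sigma)
            row.update(
                ground_elev=ground,
                rh25=rh.rh25, rh50=rh.rh50, rh75=rh.rh75, rh100=rh.rh100,
                cover_total=prof.total_cover,
                **{f"cover_b{b}": prof.bin_cover[b] for b in range(len(prof.bin_cover))},
            )
        except (NoSignalError, ValueError):
            row.update(
                ground_elev=np.nan,
                rh25=np.nan, rh50=np.nan, rh75=np.nan, rh100=np.nan,
                cover_total=np.nan,
                **{f"cover_b{b}": np.nan for b in range(8)},
            )
        rows.append(row)
    return pd.DataFrame(rows)
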