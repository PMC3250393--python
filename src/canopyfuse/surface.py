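"""Radar and multispectral habitat metrics.

Radar backscatter is converted from dB to linear power, despeckled with a
3x3 gamma-MAP filter (multiplicative gamma speckle model), and expanded
into nine bands: the three polarizations plus band ratios HH/VV, HV/VV,
HV/HH and normalized difference indices (HH-VV)/(HH+VV), (VV-HV)/(VV+HV),
(HH-HV)/(HH+HV). Multispectral red/NIR pairs yield NDVI per season and the
leaf-on minus leaf-off NDVI change, a measure of deciduousness.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .raster import Raster, require_same_grid
from .sensors import RadarScene, ReflectanceScene

RADAR_BAND_NAMES = (
    "hh", "vv", "hv",
    "hh_vv", "hv_vv", "hv_hh",
    "nd_hh_vv", "nd_vv_hv", "nd_hh_hv",
)


def db_to_power(raster: Raster) -> Raster:
    """Backscatter dB -> linear power: 10^(dB/10)."""
    return raster.with_values(10.0 ** (raster.values / 10.0))


def power_to_db(raster: Raster) -> Raster:
    with np.errstate(divide="ignore"):
        return raster.with_values(10.0 * np.log10(raster.values))


def gamma_filter(power: Raster, window: int = 3, looks: float = 4.0) -> Raster:
    """Gamma-MAP speckle filter on a linear-power raster.

    Classifies each pixel by the local coefficient of variation over the
    window: homogeneous areas take the local mean, point targets are kept,
    and intermediate pixels take the gamma-MAP estimate (positive root of
    the MAP equation for a gamma-distributed scene under gamma speckle with
    the given number of looks). Edges use the truncated neighborhood;
    degenerate MAP solutions fall back to the local mean.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    v = power.values
    ones = np.ones_like(v)
    s = ndimage.uniform_filter(v, window, mode="constant") * window**2
    s2 = ndimage.uniform_filter(v**2, window, mode="constant") * window**2
    n = ndimage.uniform_filter(ones, window, mode="constant") * window**2
    mean = s / n
    var = np.maximum(s2 / n - mean**2, 0.0)

    cu = 1.0 / np.sqrt(looks)
    cmax = np.sqrt(2.0) * cu
    with np.errstate(invalid="ignore", divide="ignore"):
        ci = np.sqrt(var) / mean
    ci = np.where(np.isfinite(ci), ci, 0.0)

    out = mean.copy()
    mid = (ci > cu) & (ci < cmax) & (mean > 0)
    if mid.any():
        ci2 = ci[mid] ** 2
        alpha = (1.0 + cu**2) / (ci2 - cu**2)
        b = alpha - looks - 1.0
        mu = mean[mid]
        i = v[mid]
        disc = mu**2 * b**2 + 4.0 * alpha * looks * mu * i
        ok = disc >= 0
        est = mu.copy()
        est[ok] = (b[ok] * mu[ok] + np.sqrt(disc[ok])) / (2.0 * alpha[ok])
        out[mid] = np.where(ok & (est > 0), est, mu)
    out[ci >= cmax] = v[ci >= cmax]  # isolated point target: keep
    return power.with_values(out)


def radar_indices(hh: Raster, vv: Raster, hv: Raster) -> dict[str, Raster]:
    """The nine radar feature bands from filtered power rasters.

    Pixels where any input band is missing, or a ratio denominator is
    zero, are NaN in every derived band.
    """
    require_same_grid(hh, vv, hv)
    a, b, c = hh.values, vv.values, hv.values
    missing = ~(np.isfinite(a) & np.isfinite(b) & np.isfinite(c))

    def safe_div(num, den):
        with np.errstate(invalid="ignore", divide="ignore"):
            out = num / den
        out[den == 0] = np.nan
        return out

    bands = {
        "hh": a.copy(),
        "vv": b.copy(),
        "hv": c.copy(),
        "hh_vv": safe_div(a, b),
        "hv_vv": safe_div(c, b),
        "hv_hh": safe_div(c, a),
        "nd_hh_vv": safe_div(a - b, a + b),
        "nd_vv_hv": safe_div(b - c, b + c),
        "nd_hh_hv": safe_div(a - c, a + c),
    }
    for arr in bands.values():
        arr[missing] = np.nan
    return {name: hh.with_values(arr) for name, arr in bands.items()}


def radar_feature_stack(
    radar: RadarScene, window: int = 3, looks: float = 4.0
) -> dict[str, Raster]:
    """dB -> power -> gamma filter -> nine-band radar feature stack."""
    filtered = {
        pol: gamma_filter(db_to_power(band), window, looks)
        for pol, band in radar.bands().items()
    }
    return radar_indices(filtered["hh"], filtered["vv"], filtered["hv"])


def ndvi(red: Raster, nir: Raster) -> Raster:
    """(NIR - red) / (NIR + red); zero-denominator pixels are NaN."""
    require_same_grid(red, nir)
    num = nir.values - red.values
    den = nir.values + red.values
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return red.with_values(out)


def ndvi_change(leafon: Raster, leafoff: Raster) -> Raster:
    """Seasonal NDVI difference (leaf-on minus leaf-off): deciduousness."""
    require_same_grid(leafon, leafoff)
    return leafon.with_values(leafon.values - leafoff.values)


def ndvi_stack(
    leafon: ReflectanceScene, leafoff: ReflectanceScene
) -> dict[str, Raster]:
    """NDVI per season plus the seasonal change raster."""
    on = ndvi(leafon.red, leafon.nir)
    off = ndvi(leafoff.red, leafoff.nir)
    return {"ndvi": on, "ndvi_leafoff": off, "ndvi_change": ndvi_change(on, off)}
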