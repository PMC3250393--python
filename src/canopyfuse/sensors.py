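"""Simulated sensor observations of a synthetic forest scene.

Four observation types mirror a typical airborne campaign over a forested
watershed:

* **Discrete-return lidar (DRL)** — a point cloud with >= 1 pulse/m^2 and up
  to four returns per pulse; first returns sample the crown envelope, last
  returns reach the ground with a probability that drops under closed canopy.
* **Large-footprint waveform lidar** — per ~25 m footprint, the vertical
  distribution of returned energy: truncated-Gaussian crown lobes weighted by
  in-footprint crown area, a ground peak, and an additive noise floor.
* **L-band polarimetric radar (HH/VV/HV)** — 5 m backscatter rasters whose
  mean power saturates with a per-pixel biomass proxy, with multiplicative
  gamma-distributed speckle.
* **Two-band multispectral reflectance** — 30 m red/NIR pairs for leaf-on and
  leaf-off seasons; the seasonal NDVI drop is confined to deciduous canopy.

Crown envelopes are vertical paraboloids from the tree top down to 60 %
(conifer) or 40 % (deciduous) of tree height, giving type-distinct vertical
profiles. None of this is radiative-transfer physics; the mechanisms are
chosen so every downstream metric has a known, recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import spatial, special

from .raster import Raster
from .scene import ForestScene

CROWN_BASE_FRACTION = {"conifer": 0.6, "deciduous": 0.4}

POINT_COLUMNS = ["x", "y", "elevation", "return_index", "n_returns"]


@dataclass
class Waveform:
    """Vertical energy profile of one large-footprint lidar shot.

    ``axis`` holds bin-center positions on a uniform grid; ``reference``
    says whether the axis is absolute elevation (m a.s.l.) or height above
    ground (after ground correction). The additive noise floor parameters
    travel with the waveform so detection thresholds are self-contained.
    """

    center: tuple[float, float]
    diameter: float
    axis: np.ndarray
    amplitude: np.ndarray
    noise_mean: float
    noise_sd: float
    reference: str = "elevation"  # "elevation" | "height"
    ground_elevation: float | None = None
    footprint_id: int | None = None

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.axis.shape != self.amplitude.shape:
            raise ValueError("axis and amplitude must have the same shape")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitudes must be non-negative")

    @property
    def bin_width(self) -> float:
        return float(abs(self.axis[1] - self.axis[0])) if len(self.axis) > 1 else 0.0


@dataclass
class RadarScene:
    """Co-registered HH/VV/HV backscatter rasters in dB."""

    hh: Raster
    vv: Raster
    hv: Raster

    def bands(self) -> dict[str, Raster]:
        return {"hh": self.hh, "vv": self.vv, "hv": self.hv}


@dataclass
class ReflectanceScene:
    """Co-registered red/NIR surface reflectance for one season."""

    red: Raster
    nir: Raster
    season: str  # "leaf_on" | "leaf_off"


@dataclass
class RadarParams:
    """Backscatter model: power = a*(1 - exp(-B/b_sat)) + floor, speckled.

    ``b_sat`` sets the biomass-proxy scale at which backscatter saturates;
    ``looks`` is the equivalent number of looks of the multiplicative gamma
    speckle (variance 1/looks on the linear power scale).
    """

    resolution: float = 5.0
    a: dict = field(default_factory=lambda: {"hh": 0.25, "vv": 0.20, "hv": 0.08})
    floor: dict = field(default_factory=lambda: {"hh": 0.010, "vv": 0.010, "hv": 0.002})
    b_sat: float = 10.0
    looks: float = 4.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.a.values()) or self.b_sat <= 0 or self.looks < 1:
            raise ValueError("require a > 0, b_sat > 0, looks >= 1")


@dataclass
class MultispectralParams:
    resolution: float = 30.0
    leafon_ndvi: float = 0.85
    leafoff_conifer_ndvi: float = 0.75
    leafoff_deciduous_ndvi: float = 0.25
    soil_ndvi: float = 0.12
    brightness: float = 0.45  # red + NIR total reflectance
    noise_sd: float = 0.01


def crown_base_height(height: np.ndarray, tree_type) -> np.ndarray:
    """Height of the crown base above ground for each tree."""
    frac = np.where(np.asarray(tree_type) == "conifer",
                    CROWN_BASE_FRACTION["conifer"], CROWN_BASE_FRACTION["deciduous"])
    return np.asarray(height, dtype=float) * frac


def crown_envelope_height(dist, height, crown_radius, base) -> np.ndarray:
    """Crown-surface height above ground at horizontal distance ``dist``.

    Paraboloid: apex at the tree top, descending to the crown base at the
    crown edge; NaN outside the crown.
    """
    dist = np.asarray(dist, dtype=float)
    with np.errstate(invalid="ignore"):
        z = height - (height - base) * (dist / crown_radius) ** 2
    return np.where(dist <= crown_radius, z, np.nan)


def simulate_drl(
    scene: ForestScene,
    density_per_m2: float = 1.0,
    vertical_error_sd: float = 0.1,
    seed: int = 0,
    ground_return_prob: float = 0.6,
    intermediate_return_prob: float = 0.25,
) -> pd.DataFrame:
    """Simulate a discrete-return lidar point cloud.

    Pulses arrive as a homogeneous Poisson process at ``density_per_m2``.
    For each pulse the first return is the highest crown-envelope surface at
    the pulse position (ground if open); under canopy the last return
    reaches the ground with probability ``ground_return_prob**n_crowns``
    (deeper canopy -> fewer ground hits), otherwise it stops at the lowest
    intersected crown base. An intermediate mid-crown return is added with
    probability ``intermediate_return_prob``. All elevations carry Gaussian
    noise with SD ``vertical_error_sd``.

    Returns a DataFrame with columns ``x, y, elevation, return_index,
    n_returns, pulse_id`` (first returns: return_index == 1; last returns:
    return_index == n_returns).
    """
    if density_per_m2 < 1:
        raise ValueError("pulse density must be >= 1 per m^2")
    rng = np.random.default_rng(seed)
    ex, ey = scene.terrain.extent
    n_pulses = rng.poisson(density_per_m2 * ex * ey)
    px = rng.uniform(0.0, ex, n_pulses)
    py = rng.uniform(0.0, ey, n_pulses)
    ground = _terrain_at(scene.terrain, px, py)

    surf, n_cov, lowest_base = _canopy_surface_at(scene, px, py)

    has_canopy = n_cov > 0
    # first return: crown surface under canopy, ground otherwise
    first_elev = np.where(has_canopy, ground + np.nan_to_num(surf), ground)

    hits_ground = rng.uniform(size=n_pulses) < ground_return_prob ** n_cov
    last_elev = np.where(
        has_canopy & ~hits_ground, ground + np.nan_to_num(lowest_base), ground
    )
    has_mid = has_canopy & (rng.uniform(size=n_pulses) < intermediate_return_prob)
    mid_elev = 0.5 * (first_elev + last_elev)

    frames = []
    pulse_id = np.arange(n_pulses)
    n_returns = np.where(has_canopy, 2 + has_mid.astype(int), 1)
    # return 1 (always)
    frames.append((px, py, first_elev, np.ones(n_pulses, int), pulse_id))
    # intermediate return (index 2 where present)
    frames.append((px[has_mid], py[has_mid], mid_elev[has_mid],
                   np.full(has_mid.sum(), 2), pulse_id[has_mid]))
    # last return for canopy pulses
    frames.append((px[has_canopy], py[has_canopy], last_elev[has_canopy],
                   n_returns[has_canopy], pulse_id[has_canopy]))

    x = np.concatenate([f[0] for f in frames])
    y = np.concatenate([f[1] for f in frames])
    elev = np.concatenate([f[2] for f in frames])
    ridx = np.concatenate([f[3] for f in frames])
    pid = np.concatenate([f[4] for f in frames])
    elev = elev + rng.normal(0.0, vertical_error_sd, len(elev))

    cloud = pd.DataFrame(
        {
            "x": x,
            "y": y,
            "elevation": elev,
            "return_index": ridx.astype(int),
            "pulse_id": pid,
        }
    )
    cloud["n_returns"] = cloud["pulse_id"].map(
        pd.Series(n_returns, index=np.arange(n_pulses))
    )
    return cloud.sort_values(["pulse_id", "return_index"], ignore_index=True)


def _terrain_at(terrain: Raster, x, y) -> np.ndarray:
    row, col = terrain.index_of(x, y)
    nrows, ncols = terrain.values.shape
    return terrain.values[np.clip(row, 0, nrows - 1), np.clip(col, 0, ncols - 1)]


def _canopy_surface_at(scene: ForestScene, x, y, k: int = 8):
    """Per point: highest crown-envelope height above ground, number of
    covering crowns, and the lowest covering crown-base height."""
    n = len(x)
    surf = np.full(n, np.nan)
    lowest_base = np.full(n, np.nan)
    n_cov = np.zeros(n, dtype=int)
    trees = scene.trees
    if len(trees) == 0:
        return surf, n_cov, lowest_base
    txy = trees[["x", "y"]].to_numpy()
    th = trees["height"].to_numpy()
    tr = trees["crown_radius"].to_numpy()
    tb = crown_base_height(th, trees["type"].to_numpy())
    r_max = tr.max()
    kd = spatial.cKDTree(txy)
    dist, idx = kd.query(np.column_stack([x, y]), k=k, distance_upper_bound=r_max)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    valid = np.isfinite(dist)
    for j in range(dist.shape[1]):
        v = valid[:, j]
        if not v.any():
            continue
        ti = idx[v, j]
        z = crown_envelope_height(dist[v, j], th[ti], tr[ti], tb[ti])
        inside = ~np.isnan(z)
        rows = np.flatnonzero(v)[inside]
        z = z[inside]
        n_cov[rows] += 1
        surf[rows] = np.fmax(surf[rows], z)
        lowest_base[rows] = np.fmin(lowest_base[rows], tb[ti[inside]])
    return surf, n_cov, lowest_base


def _circle_overlap_area(d, r1, r2) -> np.ndarray:
    """Intersection area of circles with radii r1, r2 at center distance d."""
    d = np.asarray(d, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    r2 = np.broadcast_to(np.asarray(r2, dtype=float), d.shape)
    out = np.zeros(d.shape)
    full = d <= np.abs(r1 - r2)
    out[full] = np.pi * np.minimum(r1, r2)[full] ** 2 if r1.shape else np.pi * min(r1, r2) ** 2
    lens = (~full) & (d < r1 + r2)
    if np.any(lens):
        dd, a, b = d[lens], np.broadcast_to(r1, d.shape)[lens], r2[lens]
        alpha = np.arccos(np.clip((dd**2 + a**2 - b**2) / (2 * dd * a), -1, 1))
        beta = np.arccos(np.clip((dd**2 + b**2 - a**2) / (2 * dd * b), -1, 1))
        tri = 0.5 * np.sqrt(
            np.maximum(0.0, (-dd + a + b) * (dd + a - b) * (dd - a + b) * (dd + a + b))
        )
        out[lens] = a**2 * alpha + b**2 * beta - tri
    return out


def simulate_waveform(
    scene: ForestScene,
    center: tuple[float, float],
    diameter: float = 25.0,
    bin_width: float = 0.3,
    noise_mean: float = 0.3,
    noise_sd: float = 0.1,
    seed: int = 0,
    canopy_reflectance: float = 1.0,
    ground_reflectance: float = 1.0,
    ground_sd: float = 0.5,
    footprint_id: int | None = None,
    candidate_trees: pd.DataFrame | None = None,
) -> Waveform:
    """Simulate one large-footprint waveform.

    Each in-footprint tree contributes a Gaussian energy lobe truncated to
    its crown depth, with total energy proportional to the crown area inside
    the footprint; exposed ground contributes a Gaussian peak at the mean
    in-footprint terrain elevation. Additive Gaussian noise
    (``noise_mean`` +/- ``noise_sd``) is clipped at zero.
    """
    cx, cy = center
    ex, ey = scene.terrain.extent
    if not (0 <= cx <= ex and 0 <= cy <= ey):
        raise ValueError(f"footprint center {center} outside scene extent {ex} x {ey}")
    rng = np.random.default_rng(seed)
    fr = diameter / 2.0

    g_mean, g_sd = _footprint_ground(scene.terrain, center, fr)
    axis = np.arange(g_mean - 5.0, g_mean + 45.0 + bin_width / 2, bin_width)
    amp = np.zeros_like(axis)

    footprint_area = np.pi * fr**2
    trees = scene.trees if candidate_trees is None else candidate_trees
    covered = 0.0
    if len(trees):
        d = np.hypot(trees["x"].to_numpy() - cx, trees["y"].to_numpy() - cy)
        near = d < fr + trees["crown_radius"].to_numpy()
        sub = trees.loc[near]
        if len(sub):
            overlap = _circle_overlap_area(
                d[near], sub["crown_radius"].to_numpy(), fr
            )
            h = sub["height"].to_numpy()
            base = crown_base_height(h, sub["type"].to_numpy())
            ground_tree = _terrain_at(scene.terrain, sub["x"].to_numpy(), sub["y"].to_numpy())
            lo = ground_tree + base
            hi = ground_tree + h
            mu = 0.5 * (lo + hi)
            sigma = np.maximum((hi - lo) / 4.0, 0.3)
            energy = canopy_reflectance * overlap
            amp += _truncated_lobes(axis, mu, sigma, lo, hi, energy) * bin_width
            covered = overlap.sum()

    exposed = max(0.0, footprint_area - covered)
    g_sigma = float(np.hypot(ground_sd, g_sd))
    ground_energy = ground_reflectance * exposed
    amp += (
        _truncated_lobes(
            axis,
            np.array([g_mean]),
            np.array([g_sigma]),
            np.array([g_mean - 3 * g_sigma]),
            np.array([g_mean + 3 * g_sigma]),
            np.array([ground_energy]),
        )
        * bin_width
    )

    if noise_sd > 0 or noise_mean > 0:
        amp = amp + rng.normal(noise_mean, noise_sd, amp.shape)
    amp = np.maximum(amp, 0.0)
    return Waveform(
        center=center,
        diameter=diameter,
        axis=axis,
        amplitude=amp,
        noise_mean=noise_mean,
        noise_sd=noise_sd,
        footprint_id=footprint_id,
    )


def _truncated_lobes(axis, mu, sigma, lo, hi, energy) -> np.ndarray:
    """Sum of Gaussian density lobes truncated to [lo, hi], each integrating
    to ``energy`` (per-unit-elevation density on the axis)."""
    mu = mu[:, None]
    sigma = sigma[:, None]
    lo_c = lo[:, None]
    hi_c = hi[:, None]
    e = energy[:, None]
    norm = special.ndtr((hi_c - mu) / sigma) - special.ndtr((lo_c - mu) / sigma)
    z = (axis[None, :] - mu) / sigma
    pdf = np.exp(-0.5 * z**2) / (sigma * np.sqrt(2.0 * np.pi))
    pdf[(axis[None, :] < lo_c) | (axis[None, :] > hi_c)] = 0.0
    ok = (norm > 0) & (e > 0) & (hi_c > lo_c)
    contrib = np.where(ok, e * pdf / np.where(norm > 0, norm, 1.0), 0.0)
    return contrib.sum(axis=0)


def _footprint_ground(terrain: Raster, center, radius) -> tuple[float, float]:
    xs, ys = terrain.cell_centers()
    mask = (xs - center[0]) ** 2 + (ys - center[1]) ** 2 <= radius**2
    if not mask.any():
        val = _terrain_at(terrain, np.array([center[0]]), np.array([center[1]]))
        return float(val[0]), 0.0
    vals = terrain.values[mask]
    return float(vals.mean()), float(vals.std())


def waveform_grid(
    scene: ForestScene,
    spacing: float = 25.0,
    seed: int = 0,
    **kwargs,
) -> list[Waveform]:
    """Waveform footprints on a regular grid covering the scene."""
    ex, ey = scene.terrain.extent
    half = spacing / 2.0
    xs = np.arange(half, ex, spacing)
    ys = np.arange(half, ey, spacing)
    diameter = kwargs.get("diameter", 25.0)
    trees = scene.trees
    kd = spatial.cKDTree(trees[["x", "y"]].to_numpy()) if len(trees) else None
    r_max = trees["crown_radius"].max() if len(trees) else 0.0
    waveforms = []
    fid = 0
    rng = np.random.default_rng(seed)
    for x in xs:
        for y in ys:
            if kd is not None:
                idx = kd.query_ball_point((x, y), diameter / 2.0 + r_max)
                candidates = trees.iloc[idx]
            else:
                candidates = trees
            waveforms.append(
                simulate_waveform(
                    scene,
                    (x, y),
                    seed=int(rng.integers(0, 2**31 - 1)),
                    footprint_id=fid,
                    candidate_trees=candidates,
                    **kwargs,
                )
            )
            fid += 1
    return waveforms


def biomass_proxy(scene: ForestScene, resolution: float = 5.0) -> Raster:
    """Per-pixel above-ground biomass proxy: sum of 0.5 * crown_area * height
    over stems in the pixel, divided by pixel area."""
    ex, ey = scene.terrain.extent
    ncols = max(1, int(round(ex / resolution)))
    nrows = max(1, int(round(ey / resolution)))
    grid = Raster(np.zeros((nrows, ncols)), resolution, origin=(0.0, ey))
    trees = scene.trees
    if len(trees):
        row, col = grid.index_of(trees["x"].to_numpy(), trees["y"].to_numpy())
        row = np.clip(row, 0, nrows - 1)
        col = np.clip(col, 0, ncols - 1)
        vol = 0.5 * trees["crown_area"].to_numpy() * trees["height"].to_numpy()
        np.add.at(grid.values, (row, col), vol / resolution**2)
    return grid


def simulate_radar(
    scene: ForestScene, params: RadarParams | None = None, seed: int = 0
) -> RadarScene:
    """Simulate HH/VV/HV backscatter rasters (dB) with speckle.

    Mean linear power per polarization saturates with the pixel biomass
    proxy B: ``a * (1 - exp(-B / b_sat)) + floor``; multiplicative speckle is
    gamma distributed with shape = number of looks.
    """
    params = params or RadarParams()
    rng = np.random.default_rng(seed)
    bgrid = biomass_proxy(scene, params.resolution)
    b = bgrid.values
    bands = {}
    for pol in ("hh", "vv", "hv"):
        mean_power = params.a[pol] * (1.0 - np.exp(-b / params.b_sat)) + params.floor[pol]
        speckle = rng.gamma(params.looks, 1.0 / params.looks, b.shape)
        power = mean_power * speckle
        bands[pol] = bgrid.with_values(10.0 * np.log10(np.maximum(power, 1e-12)))
    return RadarScene(**bands)


def deciduous_cover_fractions(scene: ForestScene, resolution: float) -> tuple[Raster, Raster]:
    """(vegetated cover fraction, deciduous share of crown area) per pixel."""
    ex, ey = scene.terrain.extent
    ncols = max(1, int(round(ex / resolution)))
    nrows = max(1, int(round(ey / resolution)))
    total = np.zeros((nrows, ncols))
    decid = np.zeros((nrows, ncols))
    grid = Raster(total, resolution, origin=(0.0, ey))
    trees = scene.trees
    if len(trees):
        row, col = grid.index_of(trees["x"].to_numpy(), trees["y"].to_numpy())
        row = np.clip(row, 0, nrows - 1)
        col = np.clip(col, 0, ncols - 1)
        ca = trees["crown_area"].to_numpy()
        np.add.at(total, (row, col), ca)
        is_dec = (trees["type"] == "deciduous").to_numpy()
        np.add.at(decid, (row, col), ca * is_dec)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total > 0, decid / total, 0.0)
    cover = np.minimum(total / resolution**2, 1.0)
    return grid.with_values(cover), grid.with_values(share)


def simulate_multispectral(
    scene: ForestScene,
    season: str,
    params: MultispectralParams | None = None,
    seed: int = 0,
) -> ReflectanceScene:
    """Simulate a red/NIR reflectance pair for one season.

    The pixel NDVI target mixes canopy NDVI (leaf-on: one high value for
    both types; leaf-off: deciduous NDVI collapses, conifer stays high) with
    soil NDVI by vegetated cover fraction; red/NIR are then solved from the
    target NDVI and a fixed brightness, noised and clipped to [0, 1].
    """
    if season not in ("leaf_on", "leaf_off"):
        raise ValueError("season must be 'leaf_on' or 'leaf_off'")
    params = params or MultispectralParams()
    rng = np.random.default_rng(seed)
    cover, dec_share = deciduous_cover_fractions(scene, params.resolution)
    if season == "leaf_on":
        veg_ndvi = np.full_like(cover.values, params.leafon_ndvi)
    else:
        veg_ndvi = (
            dec_share.values * params.leafoff_deciduous_ndvi
            + (1.0 - dec_share.values) * params.leafoff_conifer_ndvi
        )
    ndvi = cover.values * veg_ndvi + (1.0 - cover.values) * params.soil_ndvi
    red = params.brightness * (1.0 - ndvi) / 2.0
    nir = params.brightness * (1.0 + ndvi) / 2.0
    red = np.clip(red + rng.normal(0.0, params.noise_sd, red.shape), 0.0, 1.0)
    nir = np.clip(nir + rng.normal(0.0, params.noise_sd, nir.shape), 0.0, 1.0)
    return ReflectanceScene(
        red=cover.with_values(red), nir=cover.with_values(nir), season=season
    )


# ---------------------------------------------------------------------------
# plain-text interchange


def pointcloud_to_csv(cloud: pd.DataFrame, path) -> None:
    cloud.to_csv(path, index=False)


def waveforms_to_csv(waveforms: list[Waveform], samples_path, index_path) -> None:
    """Long-format waveform CSV + footprint index CSV."""
    frames = []
    index_rows = []
    for wf in waveforms:
        fid = wf.footprint_id
        frames.append(
            pd.DataFrame(
                {"footprint_id": fid, "elevation": wf.axis, "amplitude": wf.amplitude}
            )
        )
        index_rows.append(
            {
                "footprint_id": fid,
                "x": wf.center[0],
                "y": wf.center[1],
                "diameter": wf.diameter,
                "noise_mean": wf.noise_mean,
                "noise_sd": wf.noise_sd,
            }
        )
    pd.concat(frames, ignore_index=True).to_csv(samples_path, index=False)
    pd.DataFrame(index_rows).to_csv(index_path, index=False)


def waveforms_from_csv(samples_path, index_path) -> list[Waveform]:
    samples = pd.read_csv(samples_path)
    index = pd.read_csv(index_path).set_index("footprint_id")
    out = []
    for fid, grp in samples.groupby("footprint_id"):
        meta = index.loc[fid]
        out.append(
            Waveform(
                center=(float(meta["x"]), float(meta["y"])),
                diameter=float(meta["diameter"]),
                axis=grp["elevation"].to_numpy(),
                amplitude=grp["amplitude"].to_numpy(),
                noise_mean=float(meta["noise_mean"]),
                noise_sd=float(meta["noise_sd"]),
                footprint_id=int(fid),
            )
        )
    return out
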