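"""Synthetic forest landscapes with known structure.

This module is the ground-truth generator for the whole pipeline: a
bowl-shaped elevation surface, a conifer/deciduous stand whose composition
shifts with elevation, a north--south grid of census plots, and multi-year
songbird prevalence driven by known habitat covariates. Because every
downstream sensor product is simulated from this scene, metric-extraction
and model-recovery tests can compare against exact truth.

Conventions
-----------
* The scene occupies ``[0, extent_x] x [0, extent_y]`` meters.
* Tree stands are pandas DataFrames with columns
  ``x, y, height, crown_radius, crown_area, type`` (type in
  ``{"conifer", "deciduous"}``).
* Prevalence is the count of years (0..observation_years) a species was
  detected at a plot; detection each year is Bernoulli with probability
  inverse-logit(beta0 + beta . z) on z-scored habitat covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage, spatial, special

COVARIATE_NAMES = (
    "elevation",
    "deciduous_fraction",
    "stem_density",
    "mean_height",
    "cover_5_15",
    "cover_15_25",
)

TREE_COLUMNS = ["x", "y", "height", "crown_radius", "crown_area", "type"]


@dataclass
class SceneConfig:
    """Parameters of the synthetic landscape.

    Defaults emulate a northern-hardwood watershed: elevations spanning
    220--1,015 m, mixed stands around 500 stems/ha that become shorter,
    denser and more coniferous toward the rim of the bowl.
    """

    extent: tuple[float, float] = (1000.0, 1000.0)  # meters (x, y)
    resolution: float = 5.0  # terrain raster cell size, m
    elevation_range: tuple[float, float] = (220.0, 1015.0)  # m a.s.l.
    terrain_noise_sigma: float = 8.0  # smoothing length of terrain noise, cells
    terrain_noise_weight: float = 0.25  # noise share of relief before rescaling
    stem_density: float = 500.0  # landscape-average stems per hectare
    conifer_density_boost: float = 0.4  # extra relative density in conifer stands
    conifer_mid_elevation: float = 620.0  # m, 50% conifer probability
    conifer_elevation_scale: float = 90.0  # m, logistic width of the gradient
    conifer_height_mean: float = 12.0  # m
    conifer_height_sd: float = 2.5
    deciduous_height_mean: float = 20.0  # m
    deciduous_height_sd: float = 4.0
    min_tree_height: float = 3.0  # m, truncation of the height draw
    max_tree_height: float = 35.0
    allometry_intercept: float = 0.5  # crown_radius = a + b * height + noise
    allometry_slope: float = 0.12
    allometry_noise_sd: float = 0.25  # m
    min_crown_radius: float = 0.3  # m

    @classmethod
    def from_yaml(cls, path) -> "SceneConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("extent", "elevation_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class PlotLayout:
    """Census plot geometry: circular count plots on a transect grid."""

    centers: np.ndarray  # (n_plots, 2) meters
    radius: float = 50.0  # m; circle area pi r^2 = 0.785 ha at default
    pixel_side: float = 88.8  # m; aggregation square, 0.789 ha at default
    observation_years: int = 9
    plot_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        if self.plot_ids is None:
            self.plot_ids = np.arange(len(self.centers))
        self.plot_ids = np.asarray(self.plot_ids)

    @property
    def n_plots(self) -> int:
        return len(self.centers)

    @property
    def circle_area_ha(self) -> float:
        return np.pi * self.radius**2 / 10_000.0

    @property
    def square_area_ha(self) -> float:
        return self.pixel_side**2 / 10_000.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"plot_id": self.plot_ids, "x": self.centers[:, 0], "y": self.centers[:, 1]}
        )


@dataclass
class SpeciesResponse:
    """Logit-scale species--habitat response for the prevalence generator.

    ``detection p = expit(intercept + sum(coefficients[c] * z_c))`` where
    z_c are plot covariates standardized over the generated plot set, so
    coefficients are scale-free effects per covariate standard deviation.
    """

    name: str
    intercept: float
    coefficients: dict[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.coefficients) - set(COVARIATE_NAMES)
        if unknown:
            raise ValueError(
                f"unknown habitat covariates {sorted(unknown)}; "
                f"known: {list(COVARIATE_NAMES)}"
            )
        if self.coefficients and not any(v != 0 for v in self.coefficients.values()):
            raise ValueError("at least one coefficient must be nonzero")


#: Eight songbird archetypes mirroring the census species codes: conifer /
#: high-elevation specialists (BLPW, MAWA, MYWA, DEJU, YBFL) and
#: low-elevation deciduous-forest species (BTBW, OVEN, REVI).
DEFAULT_SPECIES: tuple[SpeciesResponse, ...] = (
    SpeciesResponse("BLPW", 0.2, {"deciduous_fraction": -1.2, "elevation": 0.8}),
    SpeciesResponse(
        "BTBW", 0.3, {"deciduous_fraction": 1.2, "elevation": -1.0, "cover_5_15": 0.6}
    ),
    SpeciesResponse("MAWA", 0.0, {"deciduous_fraction": -1.5, "cover_5_15": 0.5}),
    SpeciesResponse("MYWA", 0.2, {"deciduous_fraction": -0.8, "elevation": 0.5}),
    SpeciesResponse(
        "OVEN", 0.3, {"deciduous_fraction": 1.0, "elevation": -0.8, "mean_height": 0.5}
    ),
    SpeciesResponse("REVI", 0.4, {"deciduous_fraction": 1.2, "elevation": -0.6}),
    SpeciesResponse("DEJU", 0.1, {"elevation": 1.2, "deciduous_fraction": -0.6}),
    SpeciesResponse(
        "YBFL", -0.2, {"elevation": 1.0, "deciduous_fraction": -1.0, "cover_15_25": 0.5}
    ),
)


@dataclass
class ForestScene:
    """Bundle of the synthetic ground truth: terrain raster + tree stand."""

    terrain: "Raster"
    trees: pd.DataFrame
    config: SceneConfig


from .raster import Raster  # noqa: E402  (placed after dataclasses for readability)


def generate_terrain(config: SceneConfig, seed: int) -> Raster:
    """Generate the bowl-shaped elevation surface.

    A radial quadratic basin (low at the scene center, rising to the rim)
    plus low-frequency smooth noise, rescaled so min/max equal the
    configured elevation range exactly. Deterministic for a fixed seed.
    """
    ex, ey = config.extent
    if ex <= 0 or ey <= 0 or config.resolution <= 0:
        raise ValueError("extent and resolution must be positive")
    lo, hi = config.elevation_range
    if lo > hi:
        raise ValueError("elevation range must be (low, high)")
    rng = np.random.default_rng(seed)

    ncols = max(1, int(round(ex / config.resolution)))
    nrows = max(1, int(round(ey / config.resolution)))
    raster = Raster(np.zeros((nrows, ncols)), config.resolution, origin=(0.0, ey))
    xs, ys = raster.cell_centers()

    # radial quadratic bowl, normalized to [0, 1] over the extent
    cx, cy = ex / 2.0, ey / 2.0
    r2 = ((xs - cx) / (ex / 2.0)) ** 2 + ((ys - cy) / (ey / 2.0)) ** 2
    bowl = r2 / r2.max() if r2.max() > 0 else r2

    noise = ndimage.gaussian_filter(
        rng.standard_normal((nrows, ncols)), config.terrain_noise_sigma, mode="nearest"
    )
    span = noise.max() - noise.min()
    if span > 0:
        noise = (noise - noise.min()) / span
    surface = (1.0 - config.terrain_noise_weight) * bowl + config.terrain_noise_weight * noise

    if hi == lo:
        values = np.full_like(surface, lo)
    else:
        smin, smax = surface.min(), surface.max()
        if smax == smin:  # degenerate 1-cell raster
            values = np.full_like(surface, lo)
        else:
            values = lo + (surface - smin) * (hi - lo) / (smax - smin)
    return raster.with_values(values)


def conifer_probability(elevation, config: SceneConfig) -> np.ndarray:
    """Probability that a stem at this elevation is a conifer (logistic)."""
    return special.expit(
        (np.asarray(elevation, dtype=float) - config.conifer_mid_elevation)
        / config.conifer_elevation_scale
    )


def generate_stand(terrain: Raster, config: SceneConfig, seed: int) -> pd.DataFrame:
    """Place trees by an inhomogeneous Poisson process over the terrain.

    Conifer probability rises with elevation; conifer stands carry a
    relative density boost (normalized so the landscape mean equals
    ``config.stem_density``). Heights are type-specific truncated normals
    and crown radii follow the linear allometry
    ``r = a + b*h + noise`` truncated at ``min_crown_radius``.
    """
    if config.stem_density <= 0:
        raise ValueError("stem_density must be positive")
    rng = np.random.default_rng(seed)
    ex, ey = terrain.extent
    area_ha = ex * ey / 10_000.0

    # local density multiplier, normalized to mean 1 over the terrain
    p_con_map = conifer_probability(terrain.values, config)
    mult_map = 1.0 + config.conifer_density_boost * p_con_map
    mult_map = mult_map / mult_map.mean()
    mult_max = mult_map.max()

    # thinning of a homogeneous Poisson process at the maximum density
    n_max = rng.poisson(config.stem_density * area_ha * mult_max)
    x = rng.uniform(0.0, ex, n_max)
    y = rng.uniform(0.0, ey, n_max)
    keep = rng.uniform(0.0, mult_max, n_max) <= _sample_clipped(terrain, mult_map, x, y)
    x, y = x[keep], y[keep]
    n = len(x)

    elev = _sample_clipped(terrain, terrain.values, x, y)
    is_conifer = rng.uniform(size=n) < conifer_probability(elev, config)

    height = np.where(
        is_conifer,
        rng.normal(config.conifer_height_mean, config.conifer_height_sd, n),
        rng.normal(config.deciduous_height_mean, config.deciduous_height_sd, n),
    )
    height = np.clip(height, config.min_tree_height, config.max_tree_height)

    crown_radius = (
        config.allometry_intercept
        + config.allometry_slope * height
        + rng.normal(0.0, config.allometry_noise_sd, n)
    )
    crown_radius = np.maximum(crown_radius, config.min_crown_radius)

    return pd.DataFrame(
        {
            "x": x,
            "y": y,
            "height": height,
            "crown_radius": crown_radius,
            "crown_area": np.pi * crown_radius**2,
            "type": np.where(is_conifer, "conifer", "deciduous"),
        }
    )


def _sample_clipped(terrain: Raster, values: np.ndarray, x, y) -> np.ndarray:
    """Sample a terrain-grid array at points, clamping indices to the grid."""
    row, col = terrain.index_of(x, y)
    nrows, ncols = values.shape
    return values[np.clip(row, 0, nrows - 1), np.clip(col, 0, ncols - 1)]


def layout_plots(
    terrain: Raster,
    spacing: float,
    radius: float = 50.0,
    pixel_side: float = 88.8,
    observation_years: int = 9,
) -> PlotLayout:
    """Lay census plots on a north--south transect grid.

    Transects are columns of constant x; within each transect plots run
    north to south at the given spacing. Every plot circle must fit inside
    the scene extent.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    ex, ey = terrain.extent
    xs = np.arange(radius, ex - radius + 1e-9, spacing)
    ys = np.arange(radius, ey - radius + 1e-9, spacing)
    if len(xs) == 0 or len(ys) == 0:
        raise ValueError(
            f"no {radius} m-radius plots fit a {ex} x {ey} m extent at {spacing} m spacing"
        )
    # transect-major order, north (large y) to south within each transect
    centers = np.array([(x, y) for x in xs for y in ys[::-1]])
    return PlotLayout(
        centers=centers,
        radius=radius,
        pixel_side=pixel_side,
        observation_years=observation_years,
    )


def habitat_covariates(
    terrain: Raster, trees: pd.DataFrame, center: tuple[float, float], radius: float
) -> dict[str, float]:
    """True habitat covariates for one circular plot, straight from the stand.

    Covers are crown area of trees whose height falls in the 5--15 m or
    15--25 m stratum divided by plot area, capped at 1. A treeless plot
    yields zero density and covers (not an error).
    """
    cx, cy = center
    d2 = (trees["x"].to_numpy() - cx) ** 2 + (trees["y"].to_numpy() - cy) ** 2
    inside = trees.loc[d2 <= radius**2]
    return _covariates_from_subset(terrain, inside, center, radius)


def _covariates_from_subset(terrain, inside, center, radius) -> dict[str, float]:
    area_m2 = np.pi * radius**2
    h = inside["height"].to_numpy()
    ca = inside["crown_area"].to_numpy()
    n = len(inside)
    cov = {
        "elevation": float(terrain.sample(*center)),
        "deciduous_fraction": float((inside["type"] == "deciduous").mean()) if n else 0.0,
        "stem_density": n / (area_m2 / 10_000.0),
        "mean_height": float(h.mean()) if n else 0.0,
        "cover_5_15": min(1.0, float(ca[(h >= 5) & (h < 15)].sum()) / area_m2),
        "cover_15_25": min(1.0, float(ca[(h >= 15) & (h < 25)].sum()) / area_m2),
    }
    return cov


def habitat_covariate_table(scene: ForestScene, layout: PlotLayout) -> pd.DataFrame:
    """Covariates for every plot in the layout (indexed by plot_id)."""
    tree_xy = scene.trees[["x", "y"]].to_numpy()
    kd = spatial.cKDTree(tree_xy) if len(tree_xy) else None
    rows = []
    for pid, center in zip(layout.plot_ids, layout.centers):
        if kd is not None:
            idx = kd.query_ball_point(center, layout.radius)
            inside = scene.trees.iloc[idx]
        else:
            inside = scene.trees
        rows.append(
            {"plot_id": pid, **_covariates_from_subset(scene.terrain, inside, center, layout.radius)}
        )
    return pd.DataFrame(rows).set_index("plot_id")


def standardize_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """z-score each covariate over the plot set (population SD; constant -> 0)."""
    z = covariates.copy()
    for col in z.columns:
        v = z[col].to_numpy(dtype=float)
        sd = v.std()
        z[col] = (v - v.mean()) / sd if sd > 0 else 0.0
    return z


def generate_prevalence(
    scene: ForestScene,
    layout: PlotLayout,
    species: list[SpeciesResponse],
    seed: int,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Multi-year detection counts per plot and species.

    Yearly detection is Bernoulli(p) with
    p = expit(beta0 + beta . z) on standardized covariates; prevalence is
    Binomial(observation_years, p). Returns a long DataFrame with columns
    ``plot_id, species, prevalence``.
    """
    rng = np.random.default_rng(seed)
    if covariates is None:
        covariates = habitat_covariate_table(scene, layout)
    z = standardize_covariates(covariates)
    records = []
    for sp in species:
        eta = np.full(len(z), sp.intercept, dtype=float)
        for name, beta in sp.coefficients.items():
            eta += beta * z[name].to_numpy()
        p = special.expit(eta)
        prevalence = rng.binomial(layout.observation_years, p)
        records.append(
            pd.DataFrame(
                {"plot_id": z.index, "species": sp.name, "prevalence": prevalence}
            )
        )
    return pd.concat(records, ignore_index=True)


def detection_probabilities(
    covariates: pd.DataFrame, species: list[SpeciesResponse]
) -> pd.DataFrame:
    """True per-plot detection probabilities (one column per species)."""
    z = standardize_covariates(covariates)
    out = {}
    for sp in species:
        eta = np.full(len(z), sp.intercept, dtype=float)
        for name, beta in sp.coefficients.items():
            eta += beta * z[name].to_numpy()
        out[sp.name] = special.expit(eta)
    return pd.DataFrame(out, index=z.index)


def build_scene(config: SceneConfig, seed: int) -> ForestScene:
    """Terrain + stand with stage seeds derived from one base seed."""
    terrain = generate_terrain(config, seed)
    trees = generate_stand(terrain, config, seed + 1)
    return ForestScene(terrain=terrain, trees=trees, config=config)
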