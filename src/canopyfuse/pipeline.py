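"""End-to-end orchestration: scene -> sensors -> metrics -> feature table -> models.

This module wires the stage modules together the way the examples and the
recovery tests use them. Stage seeds are derived from one base seed by
fixed offsets so a single integer reproduces the whole simulated campaign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import drl, features, fusion, scene as scene_mod, sensors, surface, waveform

SEED_OFFSETS = {
    "terrain": 0,
    "stand": 1,
    "prevalence": 2,
    "drl": 3,
    "waveform": 4,
    "radar": 5,
    "leaf_on": 6,
    "leaf_off": 7,
}


@dataclass
class PipelineConfig:
    """Everything needed to simulate one campaign and build its features."""

    scene: scene_mod.SceneConfig = field(default_factory=scene_mod.SceneConfig)
    plot_spacing: float = 100.0
    plot_radius: float = 50.0
    pixel_side: float = 88.8
    observation_years: int = 9
    species: tuple = scene_mod.DEFAULT_SPECIES
    drl_density: float = 1.0
    drl_vertical_error_sd: float = 0.1
    surface_resolution: float = 0.5
    min_tree_height: float = 2.0
    waveform_spacing: float = 25.0
    waveform_noise_mean: float = 0.3
    waveform_noise_sd: float = 0.1
    radar: sensors.RadarParams = field(default_factory=sensors.RadarParams)
    multispectral: sensors.MultispectralParams = field(
        default_factory=sensors.MultispectralParams
    )
    n_calibration_trees: int = 200  # stand-in for field height/crown pairs
    exclusions: dict = field(default_factory=dict)


@dataclass
class PipelineProducts:
    """All intermediate and final products of one simulated campaign."""

    config: PipelineConfig
    seed: int
    scene: scene_mod.ForestScene
    layout: scene_mod.PlotLayout
    true_covariates: pd.DataFrame
    prevalence: pd.DataFrame
    dsm: drl.SurfaceRaster
    dem: drl.SurfaceRaster
    chm: drl.SurfaceRaster
    window_model: drl.WindowModel
    detected_trees: pd.DataFrame
    waveform_metrics: pd.DataFrame
    radar_stack: dict
    ndvi_bands: dict
    feature_table: pd.DataFrame  # predictors + responses, after exclusion
    exclusion_log: pd.DataFrame


def run_pipeline(config: PipelineConfig | None = None, seed: int = 0) -> PipelineProducts:
    """Simulate a campaign and assemble the plot feature/response table."""
    config = config or PipelineConfig()
    forest = scene_mod.build_scene(config.scene, seed + SEED_OFFSETS["terrain"])
    layout = scene_mod.layout_plots(
        forest.terrain,
        config.plot_spacing,
        radius=config.plot_radius,
        pixel_side=config.pixel_side,
        observation_years=config.observation_years,
    )
    true_cov = scene_mod.habitat_covariate_table(forest, layout)
    prevalence = scene_mod.generate_prevalence(
        forest, layout, list(config.species),
        seed + SEED_OFFSETS["prevalence"], covariates=true_cov,
    )

    cloud = sensors.simulate_drl(
        forest,
        density_per_m2=config.drl_density,
        vertical_error_sd=config.drl_vertical_error_sd,
        seed=seed + SEED_OFFSETS["drl"],
    )
    extent = forest.terrain.extent
    dsm = drl.interpolate_surface(cloud, "first", config.surface_resolution, extent)
    dem = drl.interpolate_surface(cloud, "last", config.surface_resolution, extent)
    chm = drl.compute_chm(dsm, dem)

    wm = calibration_window_model(forest, config.n_calibration_trees, seed)
    detected = drl.detect_trees(chm, wm, min_height=config.min_tree_height)

    waveforms = sensors.waveform_grid(
        forest,
        spacing=config.waveform_spacing,
        seed=seed + SEED_OFFSETS["waveform"],
        noise_mean=config.waveform_noise_mean,
        noise_sd=config.waveform_noise_sd,
    )
    wf_metrics = waveform.metrics_table(waveforms, dem)

    radar_scene = sensors.simulate_radar(
        forest, config.radar, seed + SEED_OFFSETS["radar"]
    )
    radar_stack = surface.radar_feature_stack(radar_scene, looks=config.radar.looks)

    leafon = sensors.simulate_multispectral(
        forest, "leaf_on", config.multispectral, seed + SEED_OFFSETS["leaf_on"]
    )
    leafoff = sensors.simulate_multispectral(
        forest, "leaf_off", config.multispectral, seed + SEED_OFFSETS["leaf_off"]
    )
    ndvi_bands = surface.ndvi_stack(leafon, leafoff)

    table = assemble_plot_features(
        layout, radar_stack, ndvi_bands, wf_metrics, detected
    )
    table, log = features.exclude_plots(table, config.exclusions)
    table = features.prevalence_join(table, prevalence, config.observation_years)

    return PipelineProducts(
        config=config,
        seed=seed,
        scene=forest,
        layout=layout,
        true_covariates=true_cov,
        prevalence=prevalence,
        dsm=dsm,
        dem=dem,
        chm=chm,
        window_model=wm,
        detected_trees=detected,
        waveform_metrics=wf_metrics,
        radar_stack=radar_stack,
        ndvi_bands=ndvi_bands,
        feature_table=table,
        exclusion_log=log,
    )


def calibration_window_model(
    forest: scene_mod.ForestScene, n_pairs: int, seed: int
) -> drl.WindowModel:
    """Height -> crown-radius line from a random sample of true trees.

    Stands in for the field calibration plots of a real campaign: the
    detection window model is fit to measured (height, crown radius)
    pairs, here drawn from the generator's stem map.
    """
    rng = np.random.default_rng(seed + 100)
    trees = forest.trees
    n = min(n_pairs, len(trees))
    if n < 2:
        raise ValueError("scene has too few trees for window calibration")
    pick = rng.choice(len(trees), size=n, replace=False)
    sample = trees.iloc[pick]
    return drl.calibrate_window_model(
        sample["height"].to_numpy(), sample["crown_radius"].to_numpy()
    )


def assemble_plot_features(
    layout: scene_mod.PlotLayout,
    radar_stack: dict,
    ndvi_bands: dict,
    wf_metrics: pd.DataFrame,
    detected_trees: pd.DataFrame,
) -> pd.DataFrame:
    """Aggregate every metric family to the plot grid and assemble."""
    family_tables = {
        "radar": features.radar_plot_features(radar_stack, layout),
        "landsat": features.landsat_plot_features(ndvi_bands, layout),
        "lvis": features.lvis_plot_features(wf_metrics, layout),
        "drl": features.drl_plot_features(detected_trees, layout),
    }
    return features.assemble_features(family_tables, layout)


def landscape_feature_table(
    products: PipelineProducts, resolution: float = 88.8
) -> pd.DataFrame:
    """The 104-column feature matrix on a wall-to-wall landscape grid.

    Re-aggregates the already-computed sensor products onto pixel centers
    of the given resolution, for prevalence/quantile mapping. Pixels with
    missing predictors are dropped.
    """
    ex, ey = products.scene.terrain.extent
    half = resolution / 2.0
    xs = np.arange(half, ex + 1e-9, resolution)
    ys = np.arange(half, ey + 1e-9, resolution)
    centers = np.array([(x, y) for y in ys[::-1] for x in xs])
    grid_layout = scene_mod.PlotLayout(
        centers=centers, radius=products.layout.radius, pixel_side=resolution
    )
    table = assemble_plot_features(
        grid_layout,
        products.radar_stack,
        products.ndvi_bands,
        products.waveform_metrics,
        products.detected_trees,
    )
    return table.dropna()


def fit_all_models(
    table: pd.DataFrame,
    species_codes: list[str] | None = None,
    n_trees: int = 800,
    seed: int = 0,
    min_samples_leaf: int = 5,
) -> dict[str, dict[str, fusion.FusionFit]]:
    """Per species, fit the five models (four single-sensor + fusion)."""
    if species_codes is None:
        species_codes = [c.removeprefix("prev_") for c in features.response_columns(table)]
    fits: dict[str, dict[str, fusion.FusionFit]] = {}
    for sp in species_codes:
        y = table[f"prev_{sp}"]
        fits[sp] = {}
        for subset in fusion.MODEL_SUBSETS:
            X = fusion.subset_features(table, subset)
            spec = fusion.ModelSpec(
                subset=subset, n_trees=n_trees, seed=seed,
                min_samples_leaf=min_samples_leaf,
            )
            fits[sp][subset] = fusion.fit_rf(X, y, spec)
    return fits


def accuracy_table(fits: dict[str, dict[str, fusion.FusionFit]]) -> pd.DataFrame:
    """pseudo-r^2 per species (rows) and model subset (columns)."""
    return pd.DataFrame(
        {sp: {subset: f.pseudo_r2 for subset, f in by_subset.items()}
         for sp, by_subset in fits.items()}
    ).T[list(fusion.MODEL_SUBSETS)]
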