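import numpy as np
import pandas as pd
import pytest

from canopyfuse.raster import Raster
from canopyfuse.scene import ForestScene, SceneConfig, build_scene


def flat_terrain(extent=(100.0, 100.0), elevation=300.0, resolution=5.0) -> Raster:
    ncols = int(round(extent[0] / resolution))
    nrows = int(round(extent[1] / resolution))
    return Raster(
        np.full((nrows, ncols), elevation), resolution, origin=(0.0, extent[1])
    )


def make_trees(rows) -> pd.DataFrame:
    """Tree table from (x, y, height, crown_radius, type) tuples."""
    df = pd.DataFrame(rows, columns=["x", "y", "height", "crown_radius", "type"])
    df["crown_area"] = np.pi * df["crown_radius"] ** 2
    return df[["x", "y", "height", "crown_radius", "crown_area", "type"]]


def flat_scene(trees=None, extent=(100.0, 100.0), elevation=300.0) -> ForestScene:
    cfg = SceneConfig(extent=extent, elevation_range=(elevation, elevation))
    terrain = flat_terrain(extent, elevation)
    if trees is None:
        trees = make_trees([])
    return ForestScene(terrain=terrain, trees=trees, config=cfg)


@pytest.fixture(scope="session")
def small_scene() -> ForestScene:
    """A modest mixed stand on bowl terrain, shared across read-only tests."""
    cfg = SceneConfig(extent=(300.0, 200.0), stem_density=400.0)
    return build_scene(cfg, seed=7)
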