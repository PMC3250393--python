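"""Plot-scale aggregation and the 104-column predictor matrix.

Every sensor metric is summarized over the 88.8 m square pixel centered on
each census plot (0.79 ha, matching the 50 m-radius count circle). Raster
metrics aggregate the cells whose centers fall in the square; per-item
records (detected trees, waveform footprints) aggregate the items whose
centers fall inside. The assembled predictor matrix has a fixed,
documented schema of 104 columns:

======== ============================================================ =====
family   columns                                                      count
======== ============================================================ =====
radar    9 power bands x (min, max, mean, std)                           36
landsat  NDVI, NDVI change x (mean, std)                                  4
lvis     ground elevation x (mean, std); RH25/50/75/100, total cover,
         cover bins 0-35 m (7 bins) x (min, max, mean, std)              50
drl      tree height, crown diameter, height x diameter x 4 stats;
         stem density; crown-area-weighted height                        14
======== ============================================================ =====

The waveform cover profile itself has 8 bins (to 40 m); the schema takes
the 7 bins from 0 to 35 m, which is the reading consistent with the
104-column total. The top bin stays available outside the schema.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .raster import Raster
from .scene import PlotLayout

STATS4 = ("min", "max", "mean", "std")
STATS2 = ("mean", "std")

RADAR_BANDS = (
    "hh", "vv", "hv", "hh_vv", "hv_vv", "hv_hh", "nd_hh_vv", "nd_vv_hv", "nd_hh_hv",
)
LVIS_DISTRIBUTED = ("rh25", "rh50", "rh75", "rh100", "cover_total") + tuple(
    f"cover_b{b}" for b in range(7)
)
DRL_DISTRIBUTED = ("height", "crown_diam", "h_diam")


def feature_schema() -> dict[str, list[str]]:
    """Canonical predictor names per family, in fixed column order."""
    schema = {
        "radar": [f"radar_{b}_{s}" for b in RADAR_BANDS for s in STATS4],
        "landsat": [f"landsat_{m}_{s}" for m in ("ndvi", "ndvi_change") for s in STATS2],
        "lvis": [f"lvis_elev_{s}" for s in STATS2]
        + [f"lvis_{m}_{s}" for m in LVIS_DISTRIBUTED for s in STATS4],
        "drl": [f"drl_{m}_{s}" for m in DRL_DISTRIBUTED for s in STATS4]
        + ["drl_stem_density", "drl_crown_area_weighted_height"],
    }
    return schema


def feature_columns() -> list[str]:
    """The 104 predictor names in canonical order (radar, landsat, lvis, drl)."""
    schema = feature_schema()
    return [c for family in ("radar", "landsat", "lvis", "drl") for c in schema[family]]


def family_of(column: str) -> str:
    return column.split("_", 1)[0]


def plot_stats(values, stats=STATS4) -> dict[str, float]:
    """Summary statistics of the values inside one plot footprint.

    Sample standard deviation (n-1 denominator); a single value yields
    std 0; an empty footprint yields NaN for every statistic.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return {s: np.nan for s in stats}
    out = {
        "min": float(v.min()),
        "max": float(v.max()),
        "mean": float(v.mean()),
        "std": float(v.std(ddof=1)) if v.size > 1 else 0.0,
    }
    return {s: out[s] for s in stats}


def _square_mask(xs, ys, center, side):
    half = side / 2.0
    return (np.abs(xs - center[0]) <= half) & (np.abs(ys - center[1]) <= half)


def aggregate_raster(
    raster: Raster, layout: PlotLayout, stats=STATS4
) -> pd.DataFrame:
    """Per-plot stats of raster cells whose centers fall in the plot square."""
    xs, ys = raster.cell_centers()
    rows = {}
    for pid, center in zip(layout.plot_ids, layout.centers):
        mask = _square_mask(xs, ys, center, layout.pixel_side)
        rows[pid] = plot_stats(raster.values[mask], stats)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "plot_id"
    return out


def aggregate_items(
    items: pd.DataFrame, value_columns, layout: PlotLayout, stats=STATS4
) -> dict[str, pd.DataFrame]:
    """Per-plot stats of per-item records (trees, footprints) by center-in-square."""
    xs = items["x"].to_numpy()
    ys = items["y"].to_numpy()
    out = {c: {} for c in value_columns}
    for pid, center in zip(layout.plot_ids, layout.centers):
        mask = _square_mask(xs, ys, center, layout.pixel_side)
        sub = items.loc[mask]
        for c in value_columns:
            out[c][pid] = plot_stats(sub[c], stats)
    frames = {}
    for c in value_columns:
        df = pd.DataFrame.from_dict(out[c], orient="index")
        df.index.name = "plot_id"
        frames[c] = df
    return frames


def radar_plot_features(stack: dict[str, Raster], layout: PlotLayout) -> pd.DataFrame:
    parts = []
    for band in RADAR_BANDS:
        stats = aggregate_raster(stack[band], layout)
        stats.columns = [f"radar_{band}_{s}" for s in stats.columns]
        parts.append(stats)
    return pd.concat(parts, axis=1)


def landsat_plot_features(ndvi_bands: dict[str, Raster], layout: PlotLayout) -> pd.DataFrame:
    parts = []
    for name in ("ndvi", "ndvi_change"):
        stats = aggregate_raster(ndvi_bands[name], layout, stats=STATS2)
        stats.columns = [f"landsat_{name}_{s}" for s in stats.columns]
        parts.append(stats)
    return pd.concat(parts, axis=1)


def lvis_plot_features(metrics: pd.DataFrame, layout: PlotLayout) -> pd.DataFrame:
    """Aggregate per-footprint waveform metrics over footprints in each plot."""
    frames = aggregate_items(metrics, ("ground_elev",), layout, stats=STATS2)
    elev = frames["ground_elev"]
    elev.columns = [f"lvis_elev_{s}" for s in elev.columns]
    parts = [elev]
    dist = aggregate_items(metrics, LVIS_DISTRIBUTED, layout)
    for m in LVIS_DISTRIBUTED:
        df = dist[m]
        df.columns = [f"lvis_{m}_{s}" for s in df.columns]
        parts.append(df)
    return pd.concat(parts, axis=1)


def drl_plot_features(trees: pd.DataFrame, layout: PlotLayout) -> pd.DataFrame:
    """Aggregate detected trees: height/diameter stats plus the two plot
    scalars (stem density, crown-area-weighted height)."""
    from .drl import crown_area_weighted_height, stem_density

    items = trees.copy()
    items["crown_diam"] = 2.0 * items["crown_radius"]
    items["h_diam"] = items.get("h_times_diam", items["height"] * items["crown_diam"])
    dist = aggregate_items(items, DRL_DISTRIBUTED, layout)
    parts = []
    for m in DRL_DISTRIBUTED:
        df = dist[m]
        df.columns = [f"drl_{m}_{s}" for s in df.columns]
        parts.append(df)
    area = layout.pixel_side**2
    xs = items["x"].to_numpy()
    ys = items["y"].to_numpy()
    density, cawh = {}, {}
    for pid, center in zip(layout.plot_ids, layout.centers):
        sub = items.loc[_square_mask(xs, ys, center, layout.pixel_side)]
        density[pid] = stem_density(sub, area)
        cawh[pid] = crown_area_weighted_height(sub)
    scalars = pd.DataFrame(
        {"drl_stem_density": density, "drl_crown_area_weighted_height": cawh}
    )
    scalars.index.name = "plot_id"
    parts.append(scalars)
    return pd.concat(parts, axis=1)


def assemble_features(
    family_tables: dict[str, pd.DataFrame], layout: PlotLayout
) -> pd.DataFrame:
    """Join the per-family plot tables into the 104-column predictor matrix.

    Raises if a family is absent or its columns deviate from the schema;
    output columns are in canonical order with plot coordinates attached.
    """
    schema = feature_schema()
    missing_families = [f for f in schema if f not in family_tables]
    if missing_families:
        absent = [c for f in missing_families for c in schema[f]]
        raise ValueError(
            f"missing metric families {missing_families}; absent columns: {absent}"
        )
    parts = []
    for family, expected in schema.items():
        table = family_tables[family]
        missing_cols = [c for c in expected if c not in table.columns]
        if missing_cols:
            raise ValueError(f"family '{family}' lacks columns {missing_cols}")
        parts.append(table[expected])
    out = pd.concat(parts, axis=1)
    out = out.reindex(layout.plot_ids)
    out = out[feature_columns()]
    out.index.name = "plot_id"
    out.insert(0, "y", layout.centers[:, 1])
    out.insert(0, "x", layout.centers[:, 0])
    return out


def predictor_frame(table: pd.DataFrame) -> pd.DataFrame:
    """The predictor columns of an assembled table (drops coords/responses)."""
    return table[feature_columns()]


def exclude_plots(
    table: pd.DataFrame,
    exclusions: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop explicitly excluded plots and plots with any missing predictor.

    ``exclusions`` maps plot_id -> reason (e.g. "high DRL crown delineation
    error"). Returns the reduced table and a log of removals with reasons.
    """
    exclusions = exclusions or {}
    log_rows = []
    drop = set()
    for pid, reason in exclusions.items():
        if pid in table.index:
            drop.add(pid)
            log_rows.append({"plot_id": pid, "reason": reason})
    preds = predictor_frame(table)
    for pid in table.index:
        if pid in drop:
            continue
        missing = preds.columns[preds.loc[pid].isna()]
        if len(missing):
            drop.add(pid)
            fams = sorted({family_of(c) for c in missing})
            log_rows.append(
                {"plot_id": pid, "reason": f"missing {fams} data ({len(missing)} columns)"}
            )
    kept = table.drop(index=sorted(drop))
    if len(kept) == 0:
        raise ValueError("exclusion removed every plot")
    return kept, pd.DataFrame(log_rows, columns=["plot_id", "reason"])


def prevalence_join(
    table: pd.DataFrame, prevalence: pd.DataFrame, observation_years: int = 9
) -> pd.DataFrame:
    """Attach one response column per species (``prev_<code>``).

    Every retained plot needs one record per species; responses are
    validated against [0, observation_years].
    """
    out = table.copy()
    for species, grp in prevalence.groupby("species", sort=True):
        series = grp.set_index("plot_id")["prevalence"]
        if series.index.duplicated().any():
            raise ValueError(f"duplicate prevalence records for species {species}")
        missing = [pid for pid in out.index if pid not in series.index]
        if missing:
            raise ValueError(f"no prevalence for species {species} at plots {missing}")
        vals = series.reindex(out.index)
        if (vals < 0).any() or (vals > observation_years).any():
            raise ValueError(
                f"prevalence outside [0, {observation_years}] for species {species}"
            )
        out[f"prev_{species}"] = vals
    return out


def response_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("prev_")]


def write_feature_table(table: pd.DataFrame, csv_path, schema_path=None) -> None:
    """CSV export plus a machine-readable JSON schema sidecar."""
    table.to_csv(csv_path)
    if schema_path is not None:
        meta = {
            "predictors": feature_columns(),
            "families": feature_schema(),
            "responses": response_columns(table),
        }
        with open(schema_path, "w") as fh:
            json.dump(meta, fh, indent=2)
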