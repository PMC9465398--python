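"""Classify a soil survey against the thresholds; build the suitability map.

Every map unit is aggregated to one (mean sand, depth) pair by weighting its
component soil types' values with their areal fractions (renormalized over
components with data — mirroring the location-aggregation convention), then
compared against the threshold rule. The comparison is inclusive: a map
unit is suitable when mean sand ≥ the sand threshold AND depth ≥ the depth
threshold ("at least as sandy and deep"). Map units with no sand data
anywhere are nodata, never unsuitable.

The map is materialized both as classified map-unit polygons and as a
raster (codes: 1 suitable, 0 unsuitable, 2 excluded, 255 nodata). Cells
under the exclusion mask — wetlands and open water — are excluded
regardless of soil state; the mask raster is resampled to the soil grid by
nearest neighbour when the grids differ.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import shapely

from .io_formats import SoilSurveyDataset
from .profile_aggregation import DEFAULT_CAP_DEPTH, soil_type_values
from .raster import GridSpec, Raster, rasterize, resample_nearest

__all__ = [
    "SUITABLE",
    "UNSUITABLE",
    "EXCLUDED",
    "NODATA",
    "ThresholdRule",
    "SuitabilityMap",
    "classify_soil_type",
    "mapunit_values",
    "build_suitability_map",
    "suitable_area",
    "state_areas",
]

SUITABLE = 1
UNSUITABLE = 0
EXCLUDED = 2
NODATA = 255

_STATE_NAMES = {SUITABLE: "suitable", UNSUITABLE: "unsuitable",
                EXCLUDED: "excluded", NODATA: "nodata"}


@dataclasses.dataclass(frozen=True)
class ThresholdRule:
    """Minimum percent sand and minimum depth; both comparisons inclusive (≥)."""

    sand_threshold: float
    depth_threshold: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sand_threshold) and np.isfinite(self.depth_threshold)):
            raise ValueError("thresholds must be finite")


@dataclasses.dataclass
class SuitabilityMap:
    """Classified landscape: a coded raster plus the classified map-unit polygons.

    ``polygons`` columns: mapunit_id, geometry, mean_sand, depth, state
    ('suitable' / 'unsuitable' / 'nodata'; exclusion is a raster-space
    overlay and appears only in ``raster``).
    """

    raster: Raster
    polygons: pd.DataFrame | None = None

    @property
    def grid(self) -> GridSpec:
        return self.raster.grid


def classify_soil_type(mean_sand, depth, rule: ThresholdRule) -> str:
    """Classify one aggregated (sand, depth) pair; null input → 'nodata'."""
    if mean_sand is None or depth is None or pd.isna(mean_sand) or pd.isna(depth):
        return "nodata"
    if mean_sand >= rule.sand_threshold and depth >= rule.depth_threshold:
        return "suitable"
    return "unsuitable"


def mapunit_values(
    survey: SoilSurveyDataset, cap_depth: float = DEFAULT_CAP_DEPTH
) -> pd.DataFrame:
    """Aggregate each map unit to component-fraction-weighted (mean_sand, depth)."""
    stv = soil_type_values(survey, cap_depth=cap_depth)
    comp = survey.components.join(stv, on="soil_type_id")
    rows = []
    for muid, grp in comp.groupby("mapunit_id", sort=False):
        w = grp["fraction"].to_numpy(dtype=float)
        sand = grp["mean_sand"].to_numpy(dtype=float)
        depth = grp["depth"].to_numpy(dtype=float)
        ok = ~np.isnan(sand)
        mean_sand = float((w[ok] * sand[ok]).sum() / w[ok].sum()) if ok.any() else np.nan
        okd = ~np.isnan(depth)
        mean_depth = float((w[okd] * depth[okd]).sum() / w[okd].sum()) if okd.any() else np.nan
        rows.append({"mapunit_id": muid, "mean_sand": mean_sand, "depth": mean_depth})
    return pd.DataFrame(rows)


def _default_grid(survey: SoilSurveyDataset, cell: float) -> GridSpec:
    bounds = shapely.bounds(survey.mapunits.geometries)
    minx, miny = bounds[:, 0].min(), bounds[:, 1].min()
    maxx, maxy = bounds[:, 2].max(), bounds[:, 3].max()
    ncols = max(1, int(np.ceil((maxx - minx) / cell)))
    nrows = max(1, int(np.ceil((maxy - miny) / cell)))
    return GridSpec(x0=float(minx), y_top=float(miny) + nrows * cell,
                    cell=cell, nrows=nrows, ncols=ncols)


def build_suitability_map(
    survey: SoilSurveyDataset,
    rule: ThresholdRule,
    exclusion_mask: Raster | None = None,
    grid: GridSpec | None = None,
    cell_size: float = 10.0,
    cap_depth: float = DEFAULT_CAP_DEPTH,
) -> SuitabilityMap:
    """Classify a survey and rasterize the result.

    ``exclusion_mask`` is a raster whose nonzero cells mark wetlands / open
    water; it must share the survey's CRS and is nearest-neighbour resampled
    onto the soil grid when the grids differ.
    """
    values = mapunit_values(survey, cap_depth=cap_depth)
    values["state"] = [
        classify_soil_type(r.mean_sand, r.depth, rule) for r in values.itertuples()
    ]
    polys = survey.mapunits.table.merge(values, on="mapunit_id")

    if grid is None:
        grid = _default_grid(survey, cell_size)
    crs = survey.mapunits.crs
    if exclusion_mask is not None:
        if (exclusion_mask.crs is not None and crs is not None
                and exclusion_mask.crs != crs):
            raise ValueError(
                f"CRS mismatch: survey {crs!r} vs exclusion mask {exclusion_mask.crs!r}"
            )

    code_of = {"suitable": SUITABLE, "unsuitable": UNSUITABLE, "nodata": NODATA}
    arr = rasterize(
        polys["geometry"],
        [code_of[s] for s in polys["state"]],
        grid,
        fill=NODATA,
        dtype=np.uint8,
    )
    if exclusion_mask is not None:
        if exclusion_mask.grid.aligned_with(grid):
            mask_vals = exclusion_mask.values
        else:
            mask_vals = resample_nearest(exclusion_mask, grid, fill=0).values
        excl = (mask_vals != 0) & (arr != NODATA)
        arr = arr.copy()
        arr[excl] = EXCLUDED

    raster = Raster(values=arr, grid=grid, crs=crs, nodata=NODATA)
    return SuitabilityMap(raster=raster, polygons=polys)


def state_areas(smap: SuitabilityMap) -> dict[str, float]:
    """Area (km²) of each state, from raster cell counts."""
    cell_km2 = smap.grid.cell_area / 1e6
    out = {}
    for code, name in _STATE_NAMES.items():
        out[name] = float((smap.raster.values == code).sum()) * cell_km2
    return out


def suitable_area(smap: SuitabilityMap, source: str = "raster") -> float:
    """Total suitable area in km².

    ``source='raster'`` counts suitable cells (the map of record, with
    exclusions applied); ``source='vector'`` sums classified map-unit polygon
    areas before exclusion.
    """
    if source == "raster":
        return state_areas(smap)["suitable"]
    if source == "vector":
        if smap.polygons is None:
            raise ValueError("no polygon classification attached")
        sel = smap.polygons[smap.polygons["state"] == "suitable"]
        return float(shapely.area(sel["geometry"].to_numpy()).sum()) / 1e6
    raise ValueError("source must be 'raster' or 'vector'")
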