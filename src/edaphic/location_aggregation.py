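"""Overlay ecosystem locations on the soil survey; area-weighted location means.

Each known ecosystem location is a polygon that typically spans several map
units and hence several soil types. A location's percent sand (and soil
depth) is the mean over its constituent soil types weighted by the area each
soil type occupies inside the location. Within a map unit the survey carries
no sub-polygon geometry, so a soil type's area inside a location is the
location/map-unit intersection area multiplied by the soil type's areal
fraction in that map unit.

Intersection slivers below ``MIN_FRAGMENT_AREA`` (1 m²) are discarded as
floating-point overlay noise. Soil types without sand data are retained in
the composition (they still carry area and depth) but are flagged and
excluded from the sand mean with weight renormalization.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import shapely
from shapely.strtree import STRtree

from .io_formats import EmptyCompositionError, SoilSurveyDataset, VectorLayer
from .profile_aggregation import DEFAULT_CAP_DEPTH, soil_type_values

__all__ = [
    "LocationComposition",
    "compose_location",
    "compose_locations",
    "location_mean_sand",
    "location_mean_depth",
    "location_summary_table",
]

MIN_FRAGMENT_AREA = 1.0  # m²


@dataclasses.dataclass
class LocationComposition:
    """Soil types inside one location with their areas and aggregated values.

    ``members`` columns: soil_type_id, area (m²), mean_sand (NaN when the
    soil type has no sand data), depth (cm).
    """

    location_id: object
    members: pd.DataFrame
    total_area: float

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise EmptyCompositionError(
                f"location {self.location_id}: no soil types intersected"
            )
        areas = self.members["area"].to_numpy()
        if (areas <= 0).any():
            raise ValueError(f"location {self.location_id}: non-positive member area")
        if not np.isclose(areas.sum(), self.total_area, rtol=1e-6):
            raise ValueError(
                f"location {self.location_id}: member areas do not sum to total_area"
            )

    @property
    def has_sand_data(self) -> bool:
        return bool(self.members["mean_sand"].notna().any())


def compose_location(
    location_id,
    polygon: shapely.Geometry,
    survey: SoilSurveyDataset,
    soil_values: pd.DataFrame | None = None,
    cap_depth: float = DEFAULT_CAP_DEPTH,
    min_fragment_area: float = MIN_FRAGMENT_AREA,
) -> LocationComposition:
    """Intersect one location polygon with the survey.

    ``soil_values`` is the per-soil-type aggregation table from
    :func:`edaphic.profile_aggregation.soil_type_values`; it is computed on
    the fly when omitted (pass it in when composing many locations).
    """
    if soil_values is None:
        soil_values = soil_type_values(survey, cap_depth=cap_depth)
    mu_geoms = survey.mapunits.geometries
    mu_ids = survey.mapunits.table["mapunit_id"].to_numpy()
    tree = STRtree(mu_geoms)
    comp_by_mu = survey.components.groupby("mapunit_id")

    frags: dict[object, float] = {}  # soil_type_id -> summed area
    for idx in tree.query(polygon, predicate="intersects"):
        inter = shapely.intersection(polygon, mu_geoms[idx])
        area = shapely.area(inter)
        if area < min_fragment_area:
            continue
        muid = mu_ids[idx]
        try:
            comps = comp_by_mu.get_group(muid)
        except KeyError:
            continue
        for c in comps.itertuples():
            a = area * float(c.fraction)
            if a <= 0:
                continue
            frags[c.soil_type_id] = frags.get(c.soil_type_id, 0.0) + a

    if not frags:
        raise EmptyCompositionError(
            f"location {location_id}: polygon intersects no soil polygon"
        )
    members = pd.DataFrame(
        {
            "soil_type_id": list(frags.keys()),
            "area": list(frags.values()),
        }
    )
    members = members.join(soil_values, on="soil_type_id")
    return LocationComposition(
        location_id=location_id,
        members=members,
        total_area=float(members["area"].sum()),
    )


def compose_locations(
    locations: VectorLayer,
    survey: SoilSurveyDataset,
    cap_depth: float = DEFAULT_CAP_DEPTH,
    id_column: str = "location_id",
) -> list[LocationComposition]:
    """Compose every location in a layer (points are rejected; polygons only)."""
    soil_values = soil_type_values(survey, cap_depth=cap_depth)
    comps = []
    for _, row in locations.table.iterrows():
        geom = row["geometry"]
        if shapely.get_dimensions(geom) != 2:
            raise ValueError(
                f"location {row.get(id_column)}: expected a polygon, got {geom.geom_type}"
            )
        comps.append(
            compose_location(
                row.get(id_column), geom, survey, soil_values=soil_values, cap_depth=cap_depth
            )
        )
    return comps


def _weighted_member_mean(comp: LocationComposition, column: str) -> float | None:
    sub = comp.members[comp.members[column].notna()]
    if len(sub) == 0:
        return None
    w = sub["area"].to_numpy(dtype=float)
    x = sub[column].to_numpy(dtype=float)
    return float((w * x).sum() / w.sum())


def location_mean_sand(comp: LocationComposition) -> float | None:
    """Area-weighted mean percent sand over soil types with sand data.

    ``None`` (flagged) when every member soil type lacks sand data.
    """
    return _weighted_member_mean(comp, "mean_sand")


def location_mean_depth(comp: LocationComposition) -> float:
    """Area-weighted mean soil depth (cm); depth is never null after capping."""
    val = _weighted_member_mean(comp, "depth")
    assert val is not None
    return val


def location_summary_table(comps: list[LocationComposition]) -> pd.DataFrame:
    """Per-location means and areas — the table behind the sand/depth scatter."""
    rows = []
    for comp in comps:
        ms = location_mean_sand(comp)
        rows.append(
            {
                "location_id": comp.location_id,
                "mean_sand": np.nan if ms is None else ms,
                "mean_depth": location_mean_depth(comp),
                "total_area": comp.total_area,
            }
        )
    return pd.DataFrame(rows)
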