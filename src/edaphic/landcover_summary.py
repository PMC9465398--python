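"""Land-cover reclassification and intersection with the suitability map.

The land-cover raster uses NLCD-style integer codes. A
:class:`LandCoverScheme` collapses them into the four reported categories —
forest (needleleaf, broadleaf deciduous, mixed), open (shrubland, grassland,
barren), agriculture (pasture/hay, cultivated crops) and urban (the four
developed classes) — plus 'excluded' (open water, wetlands) and 'other'.
Summaries report, per region, the suitable area in each category and each
category's proportion of the suitable total, alongside whole-landscape
category areas for comparison.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import shapely

from .raster import GridSpec, Raster, resample_nearest
from .suitability_mapping import SUITABLE, SuitabilityMap

__all__ = [
    "CATEGORIES",
    "REPORTED_CATEGORIES",
    "LandCoverScheme",
    "CoverSummary",
    "DEFAULT_NLCD_SCHEME",
    "reclassify_landcover",
    "summarize_cover",
    "cover_summary_frame",
]

REPORTED_CATEGORIES = ("forest", "open", "agriculture", "urban")
CATEGORIES = REPORTED_CATEGORIES + ("other", "excluded")

# stable small codes for reclassified rasters
CATEGORY_CODES = {name: i + 1 for i, name in enumerate(CATEGORIES)}
CATEGORY_NODATA = 0


@dataclasses.dataclass(frozen=True)
class LandCoverScheme:
    """Total mapping from raster land-cover codes to categories."""

    mapping: dict

    def __post_init__(self) -> None:
        bad = {c for c, cat in self.mapping.items() if cat not in CATEGORIES}
        if bad:
            raise ValueError(f"codes mapped to unknown categories: {sorted(bad)}")

    def codes_for(self, category: str) -> list[int]:
        return sorted(c for c, cat in self.mapping.items() if cat == category)

    @classmethod
    def from_dict(cls, d: dict) -> "LandCoverScheme":
        return cls(mapping={int(k): str(v) for k, v in d.items()})


# NLCD 2019 class codes
DEFAULT_NLCD_SCHEME = LandCoverScheme(
    mapping={
        11: "excluded",   # open water
        90: "excluded",   # woody wetlands
        95: "excluded",   # emergent herbaceous wetlands
        41: "forest",     # deciduous
        42: "forest",     # evergreen
        43: "forest",     # mixed
        52: "open",       # shrub/scrub
        71: "open",       # grassland/herbaceous
        31: "open",       # barren
        81: "agriculture",  # pasture/hay
        82: "agriculture",  # cultivated crops
        21: "urban",      # developed, open space
        22: "urban",      # developed, low intensity
        23: "urban",      # developed, medium intensity
        24: "urban",      # developed, high intensity
        12: "other",      # perennial ice/snow
    }
)


@dataclasses.dataclass
class CoverSummary:
    """Suitable-area breakdown by land-cover category for one region."""

    region: str
    suitable_km2: float
    category_km2: dict
    category_prop: dict
    landscape_km2: dict


def reclassify_landcover(raster: Raster, scheme: LandCoverScheme) -> Raster:
    """Substitute categories for land-cover codes; grid unchanged.

    Raises when the raster contains a code absent from the scheme, listing
    every unmapped code.
    """
    vals = raster.values
    present = np.unique(vals)
    if raster.nodata is not None:
        present = present[present != raster.nodata]
    unmapped = [int(c) for c in present if int(c) not in scheme.mapping]
    if unmapped:
        raise ValueError(f"land-cover codes with no category mapping: {unmapped}")
    lut = np.full(int(present.max(initial=0)) + 1, CATEGORY_NODATA, dtype=np.uint8)
    for code in present:
        lut[int(code)] = CATEGORY_CODES[scheme.mapping[int(code)]]
    out = np.full(vals.shape, CATEGORY_NODATA, dtype=np.uint8)
    ok = vals <= (len(lut) - 1)
    if raster.nodata is not None:
        ok &= vals != raster.nodata
    out[ok] = lut[vals[ok].astype(int)]
    return Raster(values=out, grid=raster.grid, crs=raster.crs, nodata=CATEGORY_NODATA)


def _category_grid(cover: Raster, scheme: LandCoverScheme | None, grid: GridSpec) -> np.ndarray:
    reclass = reclassify_landcover(cover, scheme) if scheme is not None else cover
    if not reclass.grid.aligned_with(grid):
        reclass = resample_nearest(reclass, grid, fill=CATEGORY_NODATA)
    return reclass.values


def summarize_cover(
    suitability: SuitabilityMap,
    cover: Raster,
    scheme: LandCoverScheme | None = DEFAULT_NLCD_SCHEME,
    regions=None,
    region_labels=None,
) -> list[CoverSummary]:
    """Intersect the suitability map with land cover, per region.

    ``cover`` is a coded land-cover raster (reclassified through ``scheme``;
    pass ``scheme=None`` if it already holds category codes), resampled to
    the suitability grid by nearest neighbour when the grids differ.
    ``regions`` is an optional sequence of polygons; by default one summary
    covers the whole extent. When regions tile the extent each cell counts
    in exactly one region (first region containing its centre), so
    per-region summaries add up to the global one.
    """
    grid = suitability.grid
    cat = _category_grid(cover, scheme, grid)
    suit = suitability.raster.values == SUITABLE
    cell_km2 = grid.cell_area / 1e6

    if regions is None:
        masks = [np.ones(grid.shape, dtype=bool)]
        labels = ["all"]
    else:
        regions = list(regions)
        labels = list(region_labels) if region_labels is not None else [
            f"region_{i}" for i in range(len(regions))
        ]
        X, Y = grid.cell_centers()
        claimed = np.zeros(grid.shape, dtype=bool)
        masks = []
        for geom in regions:
            m = shapely.intersects_xy(geom, X, Y) & ~claimed
            claimed |= m
            masks.append(m)

    summaries = []
    for label, mask in zip(labels, masks):
        if not mask.any():
            warnings.warn(f"region {label!r} is disjoint from the map extent",
                          stacklevel=2)
        cat_km2 = {}
        landscape_km2 = {}
        for name in REPORTED_CATEGORIES + ("other",):
            code = CATEGORY_CODES[name]
            cat_km2[name] = float((suit & (cat == code) & mask).sum()) * cell_km2
            landscape_km2[name] = float(((cat == code) & mask).sum()) * cell_km2
        landscape_km2["excluded"] = (
            float(((cat == CATEGORY_CODES["excluded"]) & mask).sum()) * cell_km2
        )
        suitable_km2 = float((suit & mask).sum()) * cell_km2
        props = {
            name: (a / suitable_km2 if suitable_km2 > 0 else 0.0)
            for name, a in cat_km2.items()
        }
        summaries.append(
            CoverSummary(
                region=label,
                suitable_km2=suitable_km2,
                category_km2=cat_km2,
                category_prop=props,
                landscape_km2=landscape_km2,
            )
        )
    return summaries


def cover_summary_frame(summaries: list[CoverSummary]) -> pd.DataFrame:
    """Flatten summaries to one row per region for report writing."""
    rows = []
    for s in summaries:
        row = {"region": s.region, "suitable_km2": s.suitable_km2}
        for name, a in s.category_km2.items():
            row[f"{name}_km2"] = a
            row[f"{name}_prop"] = s.category_prop[name]
        for name, a in s.landscape_km2.items():
            row[f"landscape_{name}_km2"] = a
        rows.append(row)
    return pd.DataFrame(rows)
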