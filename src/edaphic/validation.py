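"""Model validation by overlap with independent occurrence data.

Three checks mirror how an edaphic suitability map is judged against field
knowledge: (1) the held-out ecosystem locations not used for calibration —
how much of each polygon falls on suitable soil; (2) non-focal ecosystem
types — whether the map avoids ecosystems it is not meant to capture,
as an aggregated area proportion per type; (3) rare-species occurrence
points with known affinity for the focal ecosystems — the fraction of each
species' records landing on suitable cells.

Polygon overlap is measured against the raster map of record: the suitable
fraction of a polygon is the summed area of (polygon ∩ suitable cells)
divided by the polygon area, so excluded (wetland/water) cells count as
non-suitable. Points resolve to the unique cell containing them under the
grid's half-open cell ownership; points off the map count as
non-overlapping and are logged.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
import shapely

from .io_formats import OccurrenceSet
from .suitability_mapping import SUITABLE, SuitabilityMap

__all__ = [
    "overlap_proportion_polygons",
    "overlap_proportion_points",
    "validation_report",
]

logger = logging.getLogger(__name__)


def _polygon_suitable_fraction(polygon, smap: SuitabilityMap) -> float:
    area = shapely.area(polygon)
    if area <= 0:
        raise ValueError("zero-area polygon in overlap computation")
    grid = smap.grid
    vals = smap.raster.values
    minx, miny, maxx, maxy = shapely.bounds(polygon)
    c0 = max(0, int(math.floor((minx - grid.x0) / grid.cell)))
    c1 = min(grid.ncols, int(math.ceil((maxx - grid.x0) / grid.cell)))
    r0 = max(0, int(math.floor((grid.y_top - maxy) / grid.cell)))
    r1 = min(grid.nrows, int(math.ceil((grid.y_top - miny) / grid.cell)))
    if c0 >= c1 or r0 >= r1:
        return 0.0
    rows, cols = np.nonzero(vals[r0:r1, c0:c1] == SUITABLE)
    if rows.size == 0:
        return 0.0
    rows = rows + r0
    cols = cols + c0
    x0s = grid.x0 + cols * grid.cell
    y1s = grid.y_top - rows * grid.cell
    boxes = shapely.box(x0s, y1s - grid.cell, x0s + grid.cell, y1s)
    inter = shapely.area(shapely.intersection(boxes, polygon)).sum()
    return float(min(1.0, inter / area))


def overlap_proportion_polygons(entities: OccurrenceSet, smap: SuitabilityMap) -> pd.DataFrame:
    """Per-entity suitable-area fraction for polygon occurrences.

    Returns a DataFrame with label, affinity, area (m²), overlap in [0, 1].
    """
    if entities.kind != "polygon":
        raise ValueError("expected polygon occurrences")
    rows = []
    for rec in entities.records.itertuples():
        rows.append(
            {
                "label": rec.label,
                "affinity": rec.affinity,
                "area": float(shapely.area(rec.geometry)),
                "overlap": _polygon_suitable_fraction(rec.geometry, smap),
            }
        )
    return pd.DataFrame(rows)


def overlap_proportion_points(entities: OccurrenceSet, smap: SuitabilityMap) -> pd.DataFrame:
    """Per-group suitable fraction for point occurrences.

    Groups by label; returns label, affinity, n (points), overlap in [0, 1].
    """
    if entities.kind != "point":
        raise ValueError("expected point occurrences")
    geoms = entities.records["geometry"].to_numpy()
    x = shapely.get_x(geoms)
    y = shapely.get_y(geoms)
    row, col = smap.grid.index_of(x, y)
    outside = row < 0
    if outside.any():
        logger.info("%d point(s) fall outside the map extent; counted as "
                    "non-overlapping", int(outside.sum()))
    suitable = np.zeros(len(geoms), dtype=bool)
    inside = ~outside
    suitable[inside] = smap.raster.values[row[inside], col[inside]] == SUITABLE

    df = entities.records.assign(suitable=suitable)
    rows = []
    for label, grp in df.groupby("label", sort=False):
        rows.append(
            {
                "label": label,
                "affinity": grp["affinity"].iloc[0],
                "n": len(grp),
                "overlap": float(grp["suitable"].mean()),
            }
        )
    return pd.DataFrame(rows)


def validation_report(
    heldout: OccurrenceSet | None,
    nonfocal: OccurrenceSet | None,
    species: OccurrenceSet | None,
    smap: SuitabilityMap,
    coverage_cutoff: float = 0.5,
) -> pd.DataFrame:
    """Assemble the three-way validation report.

    One row per held-out location (entity_class 'heldout-focal'), one
    aggregated row per non-focal ecosystem type ('nonfocal-ecosystem'), one
    row per species ('species'), plus summary rows: the mean species
    overlap, the mean over the high-affinity species, the mean held-out
    overlap, and the fraction of held-out locations whose overlap exceeds
    ``coverage_cutoff`` (the binarized "fell within the map" reading).
    Columns: label, entity_class, affinity, n, overlap.
    """
    frames = []

    if heldout is not None and len(heldout.records):
        ho = overlap_proportion_polygons(heldout, smap)
        frames.append(
            pd.DataFrame(
                {
                    "label": ho["label"],
                    "entity_class": "heldout-focal",
                    "affinity": "n/a",
                    "n": ho["area"],
                    "overlap": ho["overlap"],
                }
            )
        )
        frames.append(pd.DataFrame([
            {"label": "heldout_mean", "entity_class": "summary", "affinity": "n/a",
             "n": len(ho), "overlap": float(ho["overlap"].mean())},
            {"label": f"heldout_covered_ge_{coverage_cutoff:g}", "entity_class": "summary",
             "affinity": "n/a", "n": len(ho),
             "overlap": float((ho["overlap"] >= coverage_cutoff).mean())},
        ]))
    else:
        logger.warning("validation: no held-out locations supplied; class omitted")

    if nonfocal is not None and len(nonfocal.records):
        nf = overlap_proportion_polygons(nonfocal, smap)
        rows = []
        for label, grp in nf.groupby("label", sort=False):
            w = grp["area"].to_numpy()
            rows.append(
                {
                    "label": label,
                    "entity_class": "nonfocal-ecosystem",
                    "affinity": grp["affinity"].iloc[0],
                    "n": float(w.sum()),
                    "overlap": float((grp["overlap"].to_numpy() * w).sum() / w.sum()),
                }
            )
        frames.append(pd.DataFrame(rows))
    else:
        logger.warning("validation: no non-focal ecosystems supplied; class omitted")

    if species is not None and len(species.records):
        sp = overlap_proportion_points(species, smap)
        frames.append(
            pd.DataFrame(
                {
                    "label": sp["label"],
                    "entity_class": "species",
                    "affinity": sp["affinity"],
                    "n": sp["n"],
                    "overlap": sp["overlap"],
                }
            )
        )
        summary = [
            {"label": "species_mean", "entity_class": "summary", "affinity": "n/a",
             "n": len(sp), "overlap": float(sp["overlap"].mean())},
        ]
        high = sp[sp["affinity"] == "high"]
        if len(high):
            summary.append(
                {"label": "species_mean_high", "entity_class": "summary",
                 "affinity": "high", "n": len(high),
                 "overlap": float(high["overlap"].mean())}
            )
        frames.append(pd.DataFrame(summary))
    else:
        logger.warning("validation: no species occurrences supplied; class omitted")

    if not frames:
        return pd.DataFrame(columns=["label", "entity_class", "affinity", "n", "overlap"])
    return pd.concat(frames, ignore_index=True)
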