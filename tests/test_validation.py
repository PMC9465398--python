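import numpy as np
import pandas as pd
import pytest
import shapely

from edaphic.io_formats import OccurrenceSet
from edaphic.raster import GridSpec, Raster
from edaphic.suitability_mapping import SuitabilityMap, ThresholdRule, build_suitability_map
from edaphic.validation import (
    overlap_proportion_points,
    overlap_proportion_polygons,
    validation_report,
)


def smap_from(values, n=10, cell=10.0, x0=0.0, y_top=None):
    y_top = n * cell if y_top is None else y_top
    grid = GridSpec(x0=x0, y_top=y_top, cell=cell, nrows=n, ncols=n)
    return SuitabilityMap(
        raster=Raster(values=np.asarray(values, np.uint8).reshape(n, n),
                      grid=grid, nodata=255)
    )


def polygons(geoms, labels=None, affinity="other"):
    labels = labels or [f"p{i}" for i in range(len(geoms))]
    return OccurrenceSet(
        records=pd.DataFrame(
            {"label": labels, "affinity": affinity, "geometry": geoms}
        ),
        kind="polygon",
    )


def points(xy, label="sp", affinity="high"):
    return OccurrenceSet(
        records=pd.DataFrame(
            {"label": label, "affinity": affinity,
             "geometry": [shapely.Point(x, y) for x, y in xy]}
        ),
        kind="point",
    )


# left half suitable (cols 0-4), right half unsuitable
HALF = np.zeros((10, 10), np.uint8)
HALF[:, :5] = 1


class TestPolygonOverlap:
    def test_inside_suitable_is_one(self):
        df = overlap_proportion_polygons(
            polygons([shapely.box(5, 5, 45, 45)]), smap_from(HALF)
        )
        assert df["overlap"].iloc[0] == pytest.approx(1.0)

    def test_outside_is_zero(self):
        df = overlap_proportion_polygons(
            polygons([shapely.box(60, 60, 95, 95)]), smap_from(HALF)
        )
        assert df["overlap"].iloc[0] == 0.0

    def test_half_covering_square_is_half(self):
        # square symmetric about the suitable/unsuitable boundary at x=50
        df = overlap_proportion_polygons(
            polygons([shapely.box(30, 20, 70, 60)]), smap_from(HALF)
        )
        assert df["overlap"].iloc[0] == pytest.approx(0.5)

    def test_excluded_cells_count_as_non_suitable(self):
        vals = HALF.copy()
        vals[:, :5] = 2  # excluded, not suitable
        df = overlap_proportion_polygons(
            polygons([shapely.box(0, 0, 100, 100)]), smap_from(vals)
        )
        assert df["overlap"].iloc[0] == 0.0

    def test_degenerate_polygon_rejected_at_ingest(self):
        degenerate = shapely.Polygon([(0, 0), (10, 0), (0, 0)])
        with pytest.raises(ValueError, match="invalid"):
            OccurrenceSet(
                records=pd.DataFrame(
                    {"label": ["z"], "affinity": ["other"], "geometry": [degenerate]}
                ),
                kind="polygon",
            )

    def test_zero_area_polygon_rejected_in_overlap(self):
        from edaphic.validation import _polygon_suitable_fraction

        with pytest.raises(ValueError, match="zero-area"):
            _polygon_suitable_fraction(shapely.Polygon(), smap_from(HALF))


class TestPointOverlap:
    def test_counting(self):
        pts = points([(10, 10), (20, 90), (30, 50), (80, 50)])  # 3 left, 1 right
        df = overlap_proportion_points(pts, smap_from(HALF))
        assert df["overlap"].iloc[0] == pytest.approx(0.75)
        assert df["n"].iloc[0] == 4

    @pytest.mark.parametrize("xy, expected", [([(10, 10), (40, 40)], 1.0),
                                              ([(60, 10), (90, 90)], 0.0)])
    def test_extremes(self, xy, expected):
        df = overlap_proportion_points(points(xy), smap_from(HALF))
        assert df["overlap"].iloc[0] == expected

    def test_point_outside_extent_counts_as_miss(self):
        df = overlap_proportion_points(
            points([(10, 10), (-500, -500)]), smap_from(HALF)
        )
        assert df["overlap"].iloc[0] == pytest.approx(0.5)

    def test_boundary_point_resolves_to_single_cell(self):
        # x=50 is the left edge of an unsuitable column under half-open cells
        df = overlap_proportion_points(points([(50.0, 55.0)]), smap_from(HALF))
        assert df["overlap"].iloc[0] == 0.0


class TestReport:
    def test_everything_suitable_gives_all_ones(self):
        smap = smap_from(np.ones(100))
        rep = validation_report(
            heldout=polygons([shapely.box(1, 1, 20, 20)], ["h1"]),
            nonfocal=polygons([shapely.box(30, 30, 60, 60)], ["nf1"]),
            species=points([(10, 10), (80, 80)]),
            smap=smap,
        )
        assert (rep["overlap"] == 1.0).all()
        assert set(rep["entity_class"]) == {
            "heldout-focal", "nonfocal-ecosystem", "species", "summary"
        }

    def test_empty_species_class_omitted_without_crash(self):
        rep = validation_report(
            heldout=polygons([shapely.box(1, 1, 20, 20)], ["h1"]),
            nonfocal=None,
            species=None,
            smap=smap_from(HALF),
        )
        assert "species" not in set(rep["entity_class"])
        assert "heldout_mean" in set(rep["label"])

    def test_summary_rows(self):
        sp = OccurrenceSet(
            records=pd.DataFrame(
                {
                    "label": ["a", "a", "b", "b"],
                    "affinity": ["high", "high", "other", "other"],
                    "geometry": [shapely.Point(10, 10), shapely.Point(20, 20),
                                 shapely.Point(80, 80), shapely.Point(90, 90)],
                }
            ),
            kind="point",
        )
        rep = validation_report(None, None, sp, smap_from(HALF))
        by_label = rep.set_index("label")
        assert by_label.loc["species_mean", "overlap"] == pytest.approx(0.5)
        assert by_label.loc["species_mean_high", "overlap"] == pytest.approx(1.0)

    def test_nonfocal_aggregates_by_area(self):
        # two fragments of one type: 1.0 overlap on a small one, 0.0 on one 3x larger
        geoms = [shapely.box(0, 0, 10, 10), shapely.box(60, 0, 90, 10)]
        nf = polygons(geoms, labels=["fen", "fen"])
        rep = validation_report(None, nf, None, smap_from(HALF))
        row = rep[rep["label"] == "fen"].iloc[0]
        assert row["overlap"] == pytest.approx((1.0 * 100 + 0.0 * 300) / 400)

    def test_translation_invariance(self):
        shift = 12345.0
        poly = shapely.box(30, 20, 70, 60)
        base = overlap_proportion_polygons(polygons([poly]), smap_from(HALF))
        moved = overlap_proportion_polygons(
            polygons([shapely.affinity.translate(poly, shift, -shift)]),
            smap_from(HALF, x0=shift, y_top=100.0 - shift),
        )
        assert moved["overlap"].iloc[0] == pytest.approx(base["overlap"].iloc[0])


def test_raising_thresholds_never_raises_overlap(small_bundle):
    """Monotonicity inherited from the suitability map."""
    prev = None
    for thr in (60.0, 76.0, 90.0):
        smap = build_suitability_map(
            small_bundle.survey, ThresholdRule(thr, 160.0),
            grid=small_bundle.landcover.grid,
        )
        rep = overlap_proportion_points(small_bundle.species, smap)
        cur = rep.set_index("label")["overlap"]
        if prev is not None:
            assert (cur <= prev + 1e-12).all()
        prev = cur
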