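import numpy as np
import pandas as pd
import pytest
import shapely

from edaphic.profile_aggregation import soil_type_values
from edaphic.suitability_mapping import ThresholdRule, build_suitability_map, mapunit_values
from edaphic.synthetic_data import (
    EXCLUDED_CODES,
    SyntheticConfig,
    generate_landcover,
    generate_locations,
    generate_occurrences,
    generate_scenario,
    generate_soil_survey,
)
from edaphic.validation import overlap_proportion_points


def tiny_config(**kw):
    base = dict(
        extent=(3000.0, 3000.0), mapunit_size=500.0, cell_size=50.0,
        n_locations=20, n_species=4, points_per_species=10, n_nonfocal=4, seed=5,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestDeterminism:
    def test_same_seed_identical_bundle(self):
        a = generate_scenario(tiny_config())
        b = generate_scenario(tiny_config())
        pd.testing.assert_frame_equal(a.survey.horizons, b.survey.horizons)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        np.testing.assert_array_equal(a.landcover.values, b.landcover.values)
        ga = a.locations.geometries
        gb = b.locations.geometries
        assert all(shapely.equals_exact(x, y, 0) for x, y in zip(ga, gb))
        assert a.manifest == b.manifest

    def test_different_seed_differs(self):
        a = generate_scenario(tiny_config(seed=5))
        b = generate_scenario(tiny_config(seed=6))
        assert not np.array_equal(a.landcover.values, b.landcover.values)


class TestSoilSurvey:
    def test_ground_truth_matches_pipeline_aggregation_exactly(self):
        """Generator bookkeeping equals the depth-weighted / fraction-weighted
        aggregation the pipeline computes from the written tables."""
        survey, truth = generate_soil_survey(tiny_config())
        vals = mapunit_values(survey).set_index("mapunit_id")
        merged = truth.set_index("mapunit_id").join(vals)
        np.testing.assert_allclose(merged["true_sand"], merged["mean_sand"], rtol=1e-9)
        np.testing.assert_allclose(merged["true_depth"], merged["depth"], rtol=1e-9)

    def test_horizon_mean_preserving_jitter(self):
        """Horizon sands vary but the profile depth-weighted mean equals the
        component draw, so per-soil-type truth is exact."""
        survey, _ = generate_soil_survey(tiny_config(horizon_sand_jitter=5.0))
        stv = soil_type_values(survey)
        assert stv["mean_sand"].between(0, 100).all()
        sand_spread = survey.horizons.groupby("soil_type_id")["percent_sand"].std()
        assert (sand_spread.dropna() > 0).any()

    def test_survey_invariants_hold(self):
        survey, _ = generate_soil_survey(tiny_config())
        survey.validate()
        sums = survey.components.groupby("mapunit_id")["fraction"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_patch_fraction_zero_gives_background_only(self):
        survey, truth = generate_soil_survey(tiny_config(patch_fraction=0.0))
        assert truth["is_patch"].sum() == 0
        # background sand ~ N(45, 15): unit means far below the patch regime
        assert truth["true_sand"].mean() < 60.0

    def test_infeasible_patch_fraction_rejected(self):
        with pytest.raises(ValueError, match="patch"):
            tiny_config(patch_fraction=0.001).validate()


class TestLocations:
    def test_full_bias_puts_all_centroids_on_patches(self):
        cfg = tiny_config(location_patch_bias=1.0)
        survey, truth = generate_soil_survey(cfg)
        locs = generate_locations(cfg, survey, truth)
        patch_geoms = [
            g for g, r in zip(survey.mapunits.geometries,
                              truth.itertuples())
            if r.is_patch
        ]
        union = shapely.union_all(patch_geoms)
        cents = shapely.centroid(locs.geometries)
        assert shapely.intersects(union, cents).all()

    def test_half_bias_on_patch_fraction_near_half(self):
        """Simulation oracle over 20 seeds: centroid-on-patch rate ~ bias."""
        rates = []
        for seed in range(20):
            cfg = tiny_config(location_patch_bias=0.5, seed=seed)
            survey, truth = generate_soil_survey(cfg)
            locs = generate_locations(cfg, survey, truth)
            rates.append(locs.table["on_patch"].mean())
        n = 20 * 20
        se = np.sqrt(0.25 / n)
        assert abs(np.mean(rates) - 0.5) < 4 * se

    def test_locations_fit_inside_extent(self):
        cfg = tiny_config()
        survey, truth = generate_soil_survey(cfg)
        locs = generate_locations(cfg, survey, truth)
        bounds = shapely.bounds(locs.geometries)
        assert (bounds[:, 0] >= 0).all() and (bounds[:, 2] <= 3000).all()
        assert (bounds[:, 1] >= 0).all() and (bounds[:, 3] <= 3000).all()


class TestLandcover:
    def test_exact_category_allocation(self):
        cfg = tiny_config()
        survey, truth = generate_soil_survey(cfg)
        cover = generate_landcover(cfg, truth)
        from edaphic.synthetic_data import CATEGORY_CODES

        cpu = cfg.cells_per_unit
        patch_units = truth.set_index("mapunit_id")["is_patch"]
        n_patch_cells = int(patch_units.sum()) * cpu * cpu
        forest_codes = CATEGORY_CODES["forest"]
        patch_mask = np.kron(
            truth.sort_values(["unit_row", "unit_col"])["is_patch"]
            .to_numpy().reshape(cfg.unit_shape),
            np.ones((cpu, cpu), dtype=bool),
        )
        n_forest_patch = int(np.isin(cover.values, forest_codes)[patch_mask].sum())
        expected = cfg.cover_patch["forest"] * n_patch_cells
        assert abs(n_forest_patch - expected) <= 1  # largest-remainder exactness

    def test_single_category_config(self):
        frac = {k: 0.0 for k in tiny_config().cover_patch}
        frac["forest"] = 1.0
        cfg = tiny_config(cover_patch=dict(frac), cover_background=dict(frac))
        survey, truth = generate_soil_survey(cfg)
        cover = generate_landcover(cfg, truth)
        assert np.isin(cover.values, (41, 42, 43)).all()


class TestOccurrences:
    def _smap(self, bundle):
        thr = bundle.config.true_thresholds()
        return build_suitability_map(
            bundle.survey, ThresholdRule(float(thr[0]), float(thr[1])),
            exclusion_mask=bundle.exclusion_mask, grid=bundle.landcover.grid,
        )

    def test_perfect_affinity_gives_full_overlap(self):
        cfg = tiny_config(affinity_high=1.0, affinity_other=1.0)
        bundle = generate_scenario(cfg)
        rep = overlap_proportion_points(bundle.species, self._smap(bundle))
        assert (rep["overlap"] == 1.0).all()

    def test_zero_affinity_overlap_near_suitable_fraction(self):
        """Simulation oracle: with no affinity, points are uniform, so overlap
        approaches the suitable-area fraction of the extent (20 seeds)."""
        overlaps, fracs = [], []
        for seed in range(20):
            cfg = tiny_config(affinity_high=0.0, affinity_other=0.0, seed=seed)
            bundle = generate_scenario(cfg)
            smap = self._smap(bundle)
            rep = overlap_proportion_points(bundle.species, smap)
            overlaps.append(rep["overlap"].mean())
            fracs.append(
                (smap.raster.values == 1).mean()
            )
        n_pts = 20 * 4 * 10
        p = np.mean(fracs)
        se = np.sqrt(p * (1 - p) / n_pts)
        assert abs(np.mean(overlaps) - p) < 4 * se


class TestScenarioBundle:
    def test_manifest_area_bookkeeping(self, small_bundle):
        m = small_bundle.manifest
        extent_km2 = m["extent_m"][0] * m["extent_m"][1] / 1e6
        cell_km2 = m["cell_size_m"] ** 2 / 1e6
        assert m["total_cells"] * cell_km2 == pytest.approx(extent_km2)
        assert m["true_suitable_area_km2"] <= extent_km2
        suitable_cells = sum(m["suitable_cover_cells"].values())
        excl = sum(m["suitable_cover_cells"][c] for c in ("water", "wetland"))
        assert (suitable_cells - excl) * cell_km2 == pytest.approx(
            m["true_suitable_area_km2"]
        )

    def test_disk_round_trip_equals_memory(self, tmp_path):
        from edaphic.io_formats import read_soil_tables, read_species_csv, read_vector_layer
        from edaphic.raster import read_geotiff

        cfg = tiny_config()
        bundle = generate_scenario(cfg, outdir=tmp_path)
        survey = read_soil_tables(
            {
                "mapunits": tmp_path / "soils/mapunits.geojson",
                "soil_types": tmp_path / "soils/soil_types.csv",
                "horizons": tmp_path / "soils/horizons.csv",
                "components": tmp_path / "soils/components.csv",
            }
        )
        pd.testing.assert_frame_equal(survey.horizons, bundle.survey.horizons)
        locs = read_vector_layer(tmp_path / "locations.geojson")
        assert len(locs) == len(bundle.locations)
        assert locs.total_area() == pytest.approx(bundle.locations.total_area(), rel=1e-9)
        cover = read_geotiff(tmp_path / "landcover.tif")
        np.testing.assert_array_equal(cover.values, bundle.landcover.values)
        sp = read_species_csv(tmp_path / "species.csv")
        assert len(sp.records) == len(bundle.species.records)

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = tiny_config(patch_fraction=0.25, seed=99)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = SyntheticConfig.from_yaml(path)
        assert back == cfg

    def test_end_to_end_suitable_area_matches_truth(self, small_bundle):
        """Ground-truth oracle: classifying the generated survey at the true
        thresholds recovers the manifest's suitable area within 2%."""
        thr = small_bundle.config.true_thresholds()
        smap = build_suitability_map(
            small_bundle.survey, ThresholdRule(float(thr[0]), float(thr[1])),
            exclusion_mask=small_bundle.exclusion_mask,
            grid=small_bundle.landcover.grid,
        )
        from edaphic.suitability_mapping import suitable_area

        assert suitable_area(smap) == pytest.approx(
            small_bundle.manifest["true_suitable_area_km2"], rel=0.02
        )
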