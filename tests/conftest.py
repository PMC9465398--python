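import numpy as np
import pandas as pd
import pytest
import shapely

from edaphic.io_formats import SoilSurveyDataset, VectorLayer
from edaphic.synthetic_data import SyntheticConfig, generate_scenario


@pytest.fixture(scope="session")
def small_config():
    """A fast 5 km x 5 km scenario used across the suite."""
    return SyntheticConfig(
        extent=(5000.0, 5000.0),
        mapunit_size=500.0,
        cell_size=50.0,
        n_locations=40,
        n_species=6,
        points_per_species=15,
        n_nonfocal=6,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_scenario(small_config)


def make_survey(units, crs="EPSG:32618"):
    """Build a survey from a compact spec.

    ``units`` is a list of dicts: geometry, mapunit_id, components — a list
    of (fraction, restrictive_depth_or_None, horizons) where horizons is a
    list of (top, bottom, sand_or_None).
    """
    mu_rows, st_rows, hz_rows, comp_rows = [], [], [], []
    for u in units:
        mu_rows.append({"mapunit_id": u["mapunit_id"], "geometry": u["geometry"]})
        for j, (frac, rdepth, horizons) in enumerate(u["components"]):
            stid = f"{u['mapunit_id']}_C{j}"
            st_rows.append({"soil_type_id": stid, "restrictive_depth": rdepth})
            comp_rows.append(
                {"mapunit_id": u["mapunit_id"], "soil_type_id": stid, "fraction": frac}
            )
            for top, bot, sand in horizons:
                hz_rows.append(
                    {
                        "soil_type_id": stid,
                        "top_depth": top,
                        "bottom_depth": bot,
                        "percent_sand": sand,
                    }
                )
    survey = SoilSurveyDataset(
        mapunits=VectorLayer(table=pd.DataFrame(mu_rows), crs=crs),
        soil_types=pd.DataFrame(st_rows).astype({"restrictive_depth": float}),
        horizons=pd.DataFrame(hz_rows).astype({"percent_sand": float}),
        components=pd.DataFrame(comp_rows),
    )
    survey.validate()
    return survey


def square_unit(mapunit_id, x0, y0, size, components):
    return {
        "mapunit_id": mapunit_id,
        "geometry": shapely.box(x0, y0, x0 + size, y0 + size),
        "components": components,
    }


@pytest.fixture
def uniform_survey():
    """A 4x4 grid of 100 m units, all one deep sandy soil type."""
    units = [
        square_unit(
            f"U{r}{c}", c * 100.0, r * 100.0, 100.0,
            [(1.0, None, [(0.0, 200.0, 90.0)])],
        )
        for r in range(4)
        for c in range(4)
    ]
    return make_survey(units)
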