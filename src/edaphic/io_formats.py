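"""External representations: soil-survey tables, vector layers, reports, config.

Soil surveys follow the SSURGO-style hierarchy: map-unit polygons, each made
up of one or more soil types (components) with areal fractions, each soil
type described by depth-ordered horizons and an optional depth to a
restrictive layer. Tables are delimited text (CSV); map-unit, location and
occurrence geometries travel as GeoJSON in a projected, metre-unit CRS.

Two table dialects are understood:

``native``
    Column names used throughout this package (``soil_type_id``,
    ``top_depth`` ...).
``ssurgo``
    gSSURGO export names (``mukey``, ``cokey``, ``hzdept_r``, ``hzdepb_r``,
    ``sandtotal_r``, ``comppct_r``, ``resdept_r``); component percentages are
    converted from 0-100 to 0-1 fractions. A "soil type" is an SSURGO
    component, and its area inside a polygon is the polygon area times the
    component's areal fraction — the only within-map-unit area information
    the survey carries.

Missing percent sand and missing restrictive depth are explicit nulls (NaN),
never 0: zero is a legal sand value.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape

__all__ = [
    "SchemaError",
    "SurveyValidationError",
    "EmptyCompositionError",
    "SoilSurveyDataset",
    "VectorLayer",
    "OccurrenceSet",
    "read_soil_tables",
    "write_soil_tables",
    "read_vector_layer",
    "write_vector_layer",
    "read_species_csv",
    "write_species_csv",
    "write_report",
    "read_report",
    "load_run_config",
    "load_focus_ecosystem_areas",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class SurveyValidationError(ValueError):
    """Input rows violate soil-survey invariants (reported, never dropped)."""


class EmptyCompositionError(ValueError):
    """A location polygon intersects no soil polygon."""


FRACTION_TOL = 1e-6


def _exact_float(v) -> str:
    """CSV float formatter that round-trips float64 exactly."""
    return repr(float(v))

# ---------------------------------------------------------------------------
# table dialects

_NATIVE_COLUMNS = {
    "soil_types": ["soil_type_id", "restrictive_depth"],
    "horizons": ["soil_type_id", "top_depth", "bottom_depth", "percent_sand"],
    "components": ["mapunit_id", "soil_type_id", "fraction"],
}

_SSURGO_RENAME = {
    "soil_types": {"cokey": "soil_type_id", "resdept_r": "restrictive_depth"},
    "horizons": {
        "cokey": "soil_type_id",
        "hzdept_r": "top_depth",
        "hzdepb_r": "bottom_depth",
        "sandtotal_r": "percent_sand",
    },
    "components": {"mukey": "mapunit_id", "cokey": "soil_type_id", "comppct_r": "fraction"},
}

DIALECTS = ("native", "ssurgo")


@dataclasses.dataclass
class VectorLayer:
    """A geometry table (shapely geometries + attributes) with a CRS tag."""

    table: pd.DataFrame  # must contain a "geometry" column
    crs: str | None = None

    def __len__(self) -> int:
        return len(self.table)

    @property
    def geometries(self) -> np.ndarray:
        return self.table["geometry"].to_numpy()

    def total_area(self) -> float:
        return float(shapely.area(self.geometries).sum())


@dataclasses.dataclass
class SoilSurveyDataset:
    """A soil survey: map-unit polygons, components and horizons.

    ``mapunits``   : mapunit_id, geometry
    ``soil_types`` : soil_type_id, restrictive_depth (cm, NaN = none reported)
    ``horizons``   : soil_type_id, top_depth, bottom_depth (cm), percent_sand
                     (0-100, NaN = not measured)
    ``components`` : mapunit_id, soil_type_id, fraction (0-1, sums to 1 per unit)
    """

    mapunits: VectorLayer
    soil_types: pd.DataFrame
    horizons: pd.DataFrame
    components: pd.DataFrame

    def validate(self) -> None:
        """Raise :class:`SurveyValidationError` naming every offending entity."""
        problems: list[str] = []
        hz = self.horizons
        for stid, grp in hz.groupby("soil_type_id", sort=False):
            g = grp.sort_values("top_depth")
            if (g["bottom_depth"].to_numpy() <= g["top_depth"].to_numpy()).any():
                problems.append(f"soil type {stid}: horizon with non-positive thickness")
            tops = g["top_depth"].to_numpy()[1:]
            bots = g["bottom_depth"].to_numpy()[:-1]
            if (tops < bots - 1e-9).any():
                problems.append(f"soil type {stid}: overlapping horizons")
        sand = hz["percent_sand"]
        bad_sand = hz.loc[sand.notna() & ((sand < 0) | (sand > 100)), "soil_type_id"]
        for stid in bad_sand.unique():
            problems.append(f"soil type {stid}: percent sand outside [0, 100]")
        sums = self.components.groupby("mapunit_id")["fraction"].sum()
        bad = sums[(sums - 1.0).abs() > FRACTION_TOL]
        for muid, s in bad.items():
            problems.append(f"map unit {muid}: component fractions sum to {s:.8f}")
        rd = self.soil_types["restrictive_depth"]
        for stid in self.soil_types.loc[rd.notna() & (rd <= 0), "soil_type_id"]:
            problems.append(f"soil type {stid}: non-positive restrictive depth")
        if not shapely.is_valid(self.mapunits.geometries).all():
            problems.append("map-unit layer contains invalid geometries")
        if problems:
            raise SurveyValidationError("; ".join(problems))

    def sorted_horizons(self, soil_type_id) -> pd.DataFrame:
        grp = self.horizons[self.horizons["soil_type_id"] == soil_type_id]
        return grp.sort_values("top_depth")


@dataclasses.dataclass
class OccurrenceSet:
    """Labelled occurrence records (points or polygons) with an affinity class.

    ``records`` columns: label, affinity ('high' or 'other'), geometry.
    """

    records: pd.DataFrame
    kind: str  # 'point' or 'polygon'

    def __post_init__(self) -> None:
        if self.kind not in ("point", "polygon"):
            raise ValueError("kind must be 'point' or 'polygon'")
        if len(self.records):
            labels = self.records["label"].astype(str)
            if (labels.str.len() == 0).any():
                raise ValueError("occurrence labels must be non-empty")
            if not shapely.is_valid(self.records["geometry"].to_numpy()).all():
                raise ValueError("occurrence set contains invalid geometries")


# ---------------------------------------------------------------------------
# soil tables


def _require_columns(df: pd.DataFrame, required, table: str, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: table '{table}' is missing column(s) {missing}")


def read_soil_tables(paths: dict, dialect: str = "native") -> SoilSurveyDataset:
    """Read a soil survey from CSV tables plus a map-unit GeoJSON.

    ``paths`` keys: 'mapunits' (GeoJSON), 'soil_types', 'horizons',
    'components' (CSV). ``dialect`` selects the column schema.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    for key in ("mapunits", "soil_types", "horizons", "components"):
        if key not in paths:
            raise SchemaError(f"missing path for table '{key}'")
        if not Path(paths[key]).exists():
            raise FileNotFoundError(paths[key])

    tables = {}
    for name in ("soil_types", "horizons", "components"):
        df = pd.read_csv(paths[name], float_precision="round_trip")
        if dialect == "ssurgo":
            rename = _SSURGO_RENAME[name]
            _require_columns(df, rename.keys(), name, paths[name])
            df = df.rename(columns=rename)
            if name == "components":
                df["fraction"] = df["fraction"] / 100.0
        _require_columns(df, _NATIVE_COLUMNS[name], name, paths[name])
        tables[name] = df[_NATIVE_COLUMNS[name]].copy()

    mapunits = read_vector_layer(paths["mapunits"])
    if "mapunit_id" not in mapunits.table.columns:
        raise SchemaError(f"{paths['mapunits']}: missing 'mapunit_id' property")

    survey = SoilSurveyDataset(mapunits=mapunits, **tables)
    survey.validate()
    return survey


def write_soil_tables(survey: SoilSurveyDataset, outdir) -> dict:
    """Write a survey to ``outdir`` in the native dialect; returns the path dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mapunits": outdir / "mapunits.geojson",
        "soil_types": outdir / "soil_types.csv",
        "horizons": outdir / "horizons.csv",
        "components": outdir / "components.csv",
    }
    write_vector_layer(survey.mapunits, paths["mapunits"])
    survey.soil_types.to_csv(paths["soil_types"], index=False, float_format=_exact_float)
    survey.horizons.to_csv(paths["horizons"], index=False, float_format=_exact_float)
    survey.components.to_csv(paths["components"], index=False, float_format=_exact_float)
    return paths


# ---------------------------------------------------------------------------
# vector layers (GeoJSON)


def read_vector_layer(path) -> VectorLayer:
    """Read a GeoJSON FeatureCollection into a :class:`VectorLayer`.

    A missing CRS member raises a warning and coordinates are assumed to be
    planar metres. Invalid geometries are flagged in an ``is_valid`` column
    and warned about, never dropped.
    """
    path = Path(path)
    if path.suffix.lower() in (".shp", ".shx", ".dbf"):
        raise ValueError(
            f"{path}: Shapefile input is not supported; convert to GeoJSON"
        )
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise IOError(f"could not read vector layer {path}: {exc}") from exc

    crs = None
    if isinstance(doc.get("crs"), dict):
        crs = doc["crs"].get("properties", {}).get("name")
    if crs is None:
        warnings.warn(
            f"{path}: no CRS declared; assuming planar coordinates in metres",
            stacklevel=2,
        )

    rows = []
    for feat in doc.get("features", []):
        geom = geom_shape(feat["geometry"])
        props = dict(feat.get("properties") or {})
        props["geometry"] = geom
        rows.append(props)
    table = pd.DataFrame(rows) if rows else pd.DataFrame({"geometry": []})
    if len(table):
        valid = shapely.is_valid(table["geometry"].to_numpy())
        table["is_valid"] = valid
        if not valid.all():
            warnings.warn(f"{path}: {(~valid).sum()} invalid geometries", stacklevel=2)
    return VectorLayer(table=table, crs=crs)


def write_vector_layer(layer: VectorLayer, path) -> None:
    """Write a :class:`VectorLayer` as a GeoJSON FeatureCollection."""
    features = []
    for _, row in layer.table.iterrows():
        props = {
            k: (v.item() if isinstance(v, np.generic) else v)
            for k, v in row.items()
            if k not in ("geometry", "is_valid")
        }
        features.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": geom_mapping(row["geometry"]),
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    if layer.crs is not None:
        doc["crs"] = {"type": "name", "properties": {"name": layer.crs}}
    try:
        with open(path, "w") as fh:
            json.dump(doc, fh)
    except OSError as exc:
        raise IOError(f"could not write vector layer {path}: {exc}") from exc


def occurrences_from_layer(layer: VectorLayer, kind: str) -> OccurrenceSet:
    """Build an :class:`OccurrenceSet` from a vector layer with label/affinity."""
    table = layer.table
    if "label" not in table.columns:
        raise SchemaError("occurrence layer is missing a 'label' property")
    affinity = (
        table["affinity"]
        if "affinity" in table.columns
        else pd.Series("other", index=table.index)
    )
    records = pd.DataFrame(
        {
            "label": table["label"].astype(str),
            "affinity": affinity,
            "geometry": table["geometry"],
        }
    ).reset_index(drop=True)
    return OccurrenceSet(records=records, kind=kind)


# ---------------------------------------------------------------------------
# species points


def read_species_csv(path) -> OccurrenceSet:
    """Read species occurrence points from CSV columns label, affinity, x, y."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    _require_columns(df, ["label", "affinity", "x", "y"], "species", path)
    records = pd.DataFrame(
        {
            "label": df["label"].astype(str),
            "affinity": df["affinity"].astype(str),
            "geometry": shapely.points(df["x"].to_numpy(), df["y"].to_numpy()),
        }
    )
    return OccurrenceSet(records=records, kind="point")


def write_species_csv(occ: OccurrenceSet, path) -> None:
    if occ.kind != "point":
        raise ValueError("species CSV holds point occurrences")
    geoms = occ.records["geometry"].to_numpy()
    df = pd.DataFrame(
        {
            "label": occ.records["label"],
            "affinity": occ.records["affinity"],
            "x": shapely.get_x(geoms),
            "y": shapely.get_y(geoms),
        }
    )
    df.to_csv(path, index=False, float_format=_exact_float)


# ---------------------------------------------------------------------------
# reports


def write_report(report, path, column_docs: dict | None = None) -> None:
    """Write a tabular report as CSV with a commented header documenting columns.

    ``report`` is a DataFrame or any object with a ``to_frame()`` method
    returning one. Values round-trip at full precision through
    :func:`read_report`.
    """
    df = report if isinstance(report, pd.DataFrame) else report.to_frame()
    try:
        with open(path, "w") as fh:
            for col in df.columns:
                doc = (column_docs or {}).get(col, "")
                fh.write(f"# {col}: {doc}\n" if doc else f"# {col}\n")
            df.to_csv(fh, index=False, float_format=_exact_float)
    except OSError as exc:
        raise IOError(f"could not write report {path}: {exc}") from exc


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


# ---------------------------------------------------------------------------
# config and packaged data


def load_run_config(path) -> dict:
    """Load a YAML run configuration as a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def load_focus_ecosystem_areas() -> pd.DataFrame:
    """NYNHP-recognized ecosystems on deep sandy soils and their mapped extents.

    Columns: ecosystem, area_km2 (lower bound when censored), censored
    (True where the published extent is given only as "<0.1 km²").
    """
    ref = resources.files("edaphic.data") / "nynhp_focus_ecosystems.csv"
    with resources.as_file(ref) as p:
        return pd.read_csv(p)
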