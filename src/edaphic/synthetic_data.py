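"""Seeded synthetic soil surveys, locations, land cover and occurrences.

Real inputs for this kind of analysis — a gridded soil survey, a Landsat
land-cover product and heritage-program ecosystem/species records — are
multi-gigabyte downloads or proprietary. This module generates structurally
faithful stand-ins with known ground truth, so every pipeline stage can be
tested end to end and its answers checked against what was actually
generated.

The emulated landscape is a rectangular extent tessellated into square map
units. A minority of map units form contiguous "sandy patches": their soil
components draw percent sand from a high-sand distribution (truncated
normal, mean 87, SD 11 by default — the regime of remnant pine-barren
soils) and deep restrictive depths (normal, mean 193 cm, SD 33, capped at
200 cm); the background is loamier and shallower. Ecosystem locations are
placed preferentially on patches, occurrence points concentrate on truly
suitable cells, and the land-cover raster mixes forest/open/agriculture/
urban/water/wetland in patch- and background-conditional proportions.

Determinism: every operation derives its generator from the configured seed
plus a fixed stream id, so the same config always produces byte-identical
outputs, and each stage is reproducible in isolation.

Ground truth is bookkept from the same random draws that produced the data,
never re-estimated: horizon sand jitter is constructed mean-preserving
(zero thickness-weighted mean, rescaled to stay inside [0, 100]) so each
soil type's depth-weighted mean sand equals its component draw exactly, and
land-cover category counts are allocated by largest-remainder apportionment
(exact to one cell) rather than sampled per cell.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml
from scipy import stats

from .io_formats import (
    OccurrenceSet,
    SoilSurveyDataset,
    VectorLayer,
    write_soil_tables,
    write_species_csv,
    write_vector_layer,
)
from .raster import GridSpec, Raster, write_geotiff
from .threshold_calibration import round_half_up

__all__ = [
    "SyntheticConfig",
    "ScenarioBundle",
    "generate_soil_survey",
    "generate_locations",
    "generate_landcover",
    "generate_occurrences",
    "generate_scenario",
]

# NLCD-style codes per generated category
CATEGORY_CODES = {
    "forest": (41, 42, 43),
    "open": (31, 52, 71),
    "agriculture": (81, 82),
    "urban": (21, 22, 23, 24),
    "water": (11,),
    "wetland": (90, 95),
    "other": (12,),
}
EXCLUDED_CATEGORIES = ("water", "wetland")
EXCLUDED_CODES = tuple(
    c for name in EXCLUDED_CATEGORIES for c in CATEGORY_CODES[name]
)

_DEF_COVER_PATCH = {
    "forest": 0.50, "open": 0.12, "agriculture": 0.08, "urban": 0.14,
    "water": 0.04, "wetland": 0.05, "other": 0.07,
}
_DEF_COVER_BACKGROUND = {
    "forest": 0.40, "open": 0.05, "agriculture": 0.25, "urban": 0.12,
    "water": 0.06, "wetland": 0.08, "other": 0.04,
}


@dataclasses.dataclass
class SyntheticConfig:
    """Everything the generator needs; defaults define the study conditions.

    Distances in metres, depths in cm, sand in percent. ``mapunit_size``
    must divide both extent dimensions and be an integer multiple of
    ``cell_size``.
    """

    extent: tuple[float, float] = (20000.0, 20000.0)
    mapunit_size: float = 1000.0
    cell_size: float = 50.0
    patch_fraction: float = 0.3
    patch_sand: tuple[float, float] = (87.0, 11.0)
    background_sand: tuple[float, float] = (45.0, 15.0)
    patch_depth: tuple[float, float] = (193.0, 33.0)
    background_depth: tuple[float, float] = (90.0, 40.0)
    depth_cap: float = 200.0
    depth_floor: float = 10.0
    horizons_range: tuple[int, int] = (2, 5)
    horizon_sand_jitter: float = 3.0
    components_range: tuple[int, int] = (1, 3)
    dirichlet_alpha: float = 2.0
    n_locations: int = 156
    location_patch_bias: float = 1.0
    location_area_range: tuple[float, float] = (1.0e4, 2.5e5)
    n_species: int = 10
    points_per_species: int = 20
    species_high_fraction: float = 0.5
    affinity_high: float = 0.9
    affinity_other: float = 0.6
    n_nonfocal: int = 15
    nonfocal_patch_bias: float = 0.2
    cover_patch: dict = dataclasses.field(default_factory=lambda: dict(_DEF_COVER_PATCH))
    cover_background: dict = dataclasses.field(
        default_factory=lambda: dict(_DEF_COVER_BACKGROUND))
    crs: str = "EPSG:32618"
    seed: int = 0

    # -- validation and derived quantities ---------------------------------

    def validate(self) -> None:
        w, h = self.extent
        if w <= 0 or h <= 0:
            raise ValueError("extent must be positive")
        for name in ("patch_fraction", "location_patch_bias", "nonfocal_patch_bias",
                     "species_high_fraction", "affinity_high", "affinity_other"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mapunit_size <= 0 or self.cell_size <= 0:
            raise ValueError("sizes must be positive")
        if (w % self.mapunit_size) or (h % self.mapunit_size):
            raise ValueError("mapunit_size must divide both extent dimensions")
        ratio = self.mapunit_size / self.cell_size
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("mapunit_size must be an integer multiple of cell_size")
        for dist in ("patch_sand", "background_sand", "patch_depth", "background_depth"):
            _, sd = getattr(self, dist)
            if sd < 0:
                raise ValueError(f"{dist} SD must be non-negative")
        for name in ("cover_patch", "cover_background"):
            fr = getattr(self, name)
            if set(fr) != set(CATEGORY_CODES):
                raise ValueError(f"{name} must map exactly {sorted(CATEGORY_CODES)}")
            if abs(sum(fr.values()) - 1.0) > 1e-6:
                raise ValueError(f"{name} fractions must sum to 1")
        n_units = self.n_mapunits
        if self.patch_fraction > 0 and round(self.patch_fraction * n_units) == 0:
            raise ValueError("patch_fraction too small: would place 0 patch units")

    @property
    def unit_shape(self) -> tuple[int, int]:
        return (int(self.extent[1] // self.mapunit_size),
                int(self.extent[0] // self.mapunit_size))

    @property
    def n_mapunits(self) -> int:
        r, c = self.unit_shape
        return r * c

    @property
    def cells_per_unit(self) -> int:
        return int(round(self.mapunit_size / self.cell_size))

    def grid(self) -> GridSpec:
        w, h = self.extent
        return GridSpec(x0=0.0, y_top=h, cell=self.cell_size,
                        nrows=int(h // self.cell_size), ncols=int(w // self.cell_size))

    def expected_sand_stats(self) -> tuple[float, float]:
        """Analytic mean/SD of patch component sand after [0, 100] truncation."""
        mu, sd = self.patch_sand
        a, b = (0.0 - mu) / sd, (100.0 - mu) / sd
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sd, moments="mv")
        return float(m), float(np.sqrt(v))

    def expected_depth_stats(self) -> tuple[float, float]:
        """Analytic mean/SD of patch depth after capping at ``depth_cap``.

        The lower clip at ``depth_floor`` is ignored (beyond 5 SD for the
        defaults).
        """
        mu, sd = self.patch_depth
        c = self.depth_cap
        z = (c - mu) / sd
        p, phi = stats.norm.cdf(z), stats.norm.pdf(z)
        e1 = mu * p - sd * phi + c * (1.0 - p)
        e2 = (mu**2 + sd**2) * p - sd * (mu + c) * phi + c**2 * (1.0 - p)
        return float(e1), float(np.sqrt(e2 - e1**2))

    def true_thresholds(self) -> tuple[int, int]:
        """Mean − 1 SD of the generating patch distributions, integer-rounded."""
        sm, ss = self.expected_sand_stats()
        dm, ds = self.expected_depth_stats()
        return round_half_up(sm - ss), round_half_up(dm - ds)

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _patch_mask(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Contiguous rectangular sandy patches covering ~patch_fraction of units."""
    nuy, nux = config.unit_shape
    mask = np.zeros((nuy, nux), dtype=bool)
    target = int(round(config.patch_fraction * nuy * nux))
    guard = 0
    while mask.sum() < target and guard < 10000:
        h = int(rng.integers(2, 6))
        w = int(rng.integers(2, 6))
        r0 = int(rng.integers(0, max(1, nuy - h + 1)))
        c0 = int(rng.integers(0, max(1, nux - w + 1)))
        mask[r0:r0 + h, c0:c0 + w] = True
        guard += 1
    return mask


def _draw_depth(rng, mu, sd, cap, floor):
    """Raw restrictive-layer draw: NaN when deeper than the survey describes."""
    raw = rng.normal(mu, sd)
    if raw < floor:
        raw = floor
    return (np.nan, cap) if raw >= cap else (raw, raw)


def _jittered_horizon_sands(rng, target, thickness, jitter):
    """Horizon sands whose thickness-weighted mean equals ``target`` exactly."""
    k = len(thickness)
    if jitter <= 0 or k == 1:
        return np.full(k, target)
    eps = rng.normal(0.0, jitter, k)
    w = thickness / thickness.sum()
    eps = eps - (w * eps).sum()
    hi, lo = eps.max(), eps.min()
    scale = 1.0
    if hi > 0:
        scale = min(scale, (100.0 - target) / hi)
    if lo < 0:
        scale = min(scale, (target - 0.0) / (-lo))
    # slight shrink keeps float round-off inside [0, 100]; rescaling a
    # zero-weighted-mean jitter preserves the exact profile mean
    sands = target + max(0.0, scale) * (1.0 - 1e-9) * eps
    return np.clip(sands, 0.0, 100.0)


def generate_soil_survey(config: SyntheticConfig):
    """Tessellate the extent into map units and sample components/horizons.

    Returns ``(survey, truth)``: the dataset and a per-map-unit ground-truth
    table (mapunit_id, unit_row, unit_col, is_patch, true_sand, true_depth,
    suitable) computed from the same draws.
    """
    config.validate()
    rng = _rng(config, 1)
    nuy, nux = config.unit_shape
    size = config.mapunit_size
    patch = _patch_mask(config, rng)
    sand_thr, depth_thr = config.true_thresholds()

    mu_rows, st_rows, hz_rows, comp_rows, truth_rows = [], [], [], [], []
    c_lo, c_hi = config.components_range
    h_lo, h_hi = config.horizons_range
    height = config.extent[1]

    for ur in range(nuy):
        for uc in range(nux):
            muid = f"MU{ur * nux + uc:04d}"
            x0, y1 = uc * size, height - ur * size
            mu_rows.append(
                {"mapunit_id": muid,
                 "geometry": shapely.box(x0, y1 - size, x0 + size, y1)}
            )
            is_patch = bool(patch[ur, uc])
            sand_mu, sand_sd = config.patch_sand if is_patch else config.background_sand
            dep_mu, dep_sd = config.patch_depth if is_patch else config.background_depth

            k = int(rng.integers(c_lo, c_hi + 1))
            fracs = rng.dirichlet(np.full(k, config.dirichlet_alpha))
            true_sand = 0.0
            true_depth = 0.0
            for j in range(k):
                stid = f"{muid}_C{j}"
                a = (0.0 - sand_mu) / max(sand_sd, 1e-9)
                b = (100.0 - sand_mu) / max(sand_sd, 1e-9)
                s = float(stats.truncnorm.rvs(a, b, loc=sand_mu, scale=sand_sd,
                                              random_state=rng)) if sand_sd > 0 else sand_mu
                restrictive, depth_true = _draw_depth(
                    rng, dep_mu, dep_sd, config.depth_cap, config.depth_floor)

                nh = int(rng.integers(h_lo, h_hi + 1))
                thickness = rng.dirichlet(np.full(nh, 1.5)) * depth_true
                thickness = np.maximum(thickness, 1e-3)
                sands = _jittered_horizon_sands(
                    rng, s, thickness, config.horizon_sand_jitter)
                top = 0.0
                for t, hs in zip(thickness, sands):
                    hz_rows.append(
                        {"soil_type_id": stid, "top_depth": top,
                         "bottom_depth": top + t, "percent_sand": float(hs)}
                    )
                    top += t
                st_rows.append({"soil_type_id": stid, "restrictive_depth": restrictive})
                comp_rows.append(
                    {"mapunit_id": muid, "soil_type_id": stid, "fraction": float(fracs[j])}
                )
                true_sand += fracs[j] * s
                true_depth += fracs[j] * depth_true

            truth_rows.append(
                {"mapunit_id": muid, "unit_row": ur, "unit_col": uc,
                 "is_patch": is_patch, "true_sand": true_sand,
                 "true_depth": true_depth,
                 "suitable": bool(true_sand >= sand_thr and true_depth >= depth_thr)}
            )

    survey = SoilSurveyDataset(
        mapunits=VectorLayer(table=pd.DataFrame(mu_rows), crs=config.crs),
        soil_types=pd.DataFrame(st_rows),
        horizons=pd.DataFrame(hz_rows),
        components=pd.DataFrame(comp_rows),
    )
    survey.validate()
    return survey, pd.DataFrame(truth_rows)


def _place_box_in_unit(rng, config, ur, uc):
    size = config.mapunit_size
    height = config.extent[1]
    a0, a1 = config.location_area_range
    area = float(np.exp(rng.uniform(np.log(a0), np.log(a1))))
    side = min(np.sqrt(area), size)
    x0u, y1u = uc * size, height - ur * size
    x = x0u + rng.uniform(0.0, size - side)
    y = y1u - side - rng.uniform(0.0, size - side)
    return shapely.box(x, y, x + side, y + side)


def _biased_units(truth: pd.DataFrame):
    patch_units = truth[truth["is_patch"]][["unit_row", "unit_col"]].to_numpy()
    back_units = truth[~truth["is_patch"]][["unit_row", "unit_col"]].to_numpy()
    return patch_units, back_units


def _generate_sites(config, truth, rng, n, bias, id_fmt, extra=None):
    patch_units, back_units = _biased_units(truth)
    rows = []
    for i in range(n):
        on_patch = bool(rng.random() < bias) and len(patch_units) > 0
        pool = patch_units if on_patch else back_units
        if len(pool) == 0:
            pool = patch_units if len(patch_units) else back_units
            on_patch = pool is patch_units
        ur, uc = pool[int(rng.integers(len(pool)))]
        row = {"location_id" if extra is None else "label": id_fmt.format(i),
               "on_patch": on_patch,
               "geometry": _place_box_in_unit(rng, config, int(ur), int(uc))}
        if extra:
            row.update(extra)
        rows.append(row)
    return pd.DataFrame(rows)


def generate_locations(config: SyntheticConfig, survey, truth: pd.DataFrame) -> VectorLayer:
    """Ecosystem-location polygons placed on sandy patches with the configured bias.

    Each location is a square (area log-uniform within the configured range)
    placed fully inside one map unit, chosen among patch units with
    probability ``location_patch_bias`` and among background units otherwise.
    """
    rng = _rng(config, 2)
    table = _generate_sites(config, truth, rng, config.n_locations,
                            config.location_patch_bias, "L{:03d}")
    return VectorLayer(table=table, crs=config.crs)


def generate_landcover(config: SyntheticConfig, truth: pd.DataFrame) -> Raster:
    """Categorical land-cover raster with exact patch/background category counts.

    Per-category cell counts are fixed by largest-remainder apportionment of
    the configured fractions over the patch and background cell populations,
    then placed by a seeded shuffle; each cell then receives a random code
    from its category's code list.
    """
    rng = _rng(config, 3)
    grid = config.grid()
    cpu = config.cells_per_unit
    nuy, nux = config.unit_shape
    patch_units = np.zeros((nuy, nux), dtype=bool)
    for r in truth.itertuples():
        patch_units[r.unit_row, r.unit_col] = r.is_patch
    patch_cells = np.kron(patch_units, np.ones((cpu, cpu), dtype=bool))

    values = np.zeros(grid.shape, dtype=np.uint8)
    order = list(CATEGORY_CODES)
    for is_patch, fractions in ((True, config.cover_patch),
                                (False, config.cover_background)):
        idx = np.flatnonzero(patch_cells.ravel() == is_patch)
        n = idx.size
        if n == 0:
            continue
        counts = _largest_remainder([fractions[c] for c in order], n)
        labels = np.repeat(np.arange(len(order)), counts)
        rng.shuffle(labels)
        flat = values.ravel()
        for li, cat in enumerate(order):
            codes = CATEGORY_CODES[cat]
            cells = idx[labels == li]
            flat[cells] = rng.choice(codes, size=cells.size)
    return Raster(values=values, grid=grid, crs=config.crs, nodata=0)


def _largest_remainder(fractions, n: int) -> np.ndarray:
    exact = np.asarray(fractions, dtype=float) * n
    counts = np.floor(exact).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(exact - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def _suitable_cell_mask(config, truth, cover: Raster) -> np.ndarray:
    """Cells on truly suitable map units whose cover is not water/wetland."""
    cpu = config.cells_per_unit
    nuy, nux = config.unit_shape
    suit_units = np.zeros((nuy, nux), dtype=bool)
    for r in truth.itertuples():
        suit_units[r.unit_row, r.unit_col] = r.suitable
    suit_cells = np.kron(suit_units, np.ones((cpu, cpu), dtype=bool))
    return suit_cells & ~np.isin(cover.values, EXCLUDED_CODES)


def generate_occurrences(
    config: SyntheticConfig, truth: pd.DataFrame, cover: Raster
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Species points and non-focal ecosystem polygons.

    Each species point lands on a uniformly chosen truly-suitable,
    non-excluded cell with its affinity probability (``affinity_high`` for
    high-affinity species, ``affinity_other`` otherwise) and uniformly in
    the extent otherwise. Non-focal ecosystems are polygons placed mostly on
    background soil (``nonfocal_patch_bias``).
    """
    rng = _rng(config, 4)
    grid = config.grid()
    suit = _suitable_cell_mask(config, truth, cover)
    suit_idx = np.flatnonzero(suit.ravel())
    w, h = config.extent

    n_high = round_half_up(config.species_high_fraction * config.n_species)
    rows = []
    for i in range(config.n_species):
        affinity = "high" if i < n_high else "other"
        p = config.affinity_high if affinity == "high" else config.affinity_other
        label = f"species_{i + 1:02d}"
        for _ in range(config.points_per_species):
            if suit_idx.size and rng.random() < p:
                cell = suit_idx[int(rng.integers(suit_idx.size))]
                r, c = divmod(int(cell), grid.ncols)
                x = grid.x0 + (c + rng.random()) * grid.cell
                y = grid.y_top - (r + rng.random()) * grid.cell
            else:
                x, y = rng.uniform(0, w), rng.uniform(0, h)
            rows.append({"label": label, "affinity": affinity,
                         "geometry": shapely.Point(x, y)})
    species = OccurrenceSet(records=pd.DataFrame(rows), kind="point")

    nf_table = _generate_sites(
        config, truth, rng, config.n_nonfocal, config.nonfocal_patch_bias,
        "nonfocal_{:02d}", extra={"affinity": "other"},
    )
    nonfocal = OccurrenceSet(
        records=nf_table[["label", "affinity", "geometry"]], kind="polygon"
    )
    return species, nonfocal


@dataclasses.dataclass
class ScenarioBundle:
    """Everything one synthetic study needs, plus its ground-truth manifest."""

    config: SyntheticConfig
    survey: SoilSurveyDataset
    truth: pd.DataFrame
    locations: VectorLayer
    landcover: Raster
    species: OccurrenceSet
    nonfocal: OccurrenceSet
    manifest: dict

    @property
    def exclusion_mask(self) -> Raster:
        vals = np.isin(self.landcover.values, EXCLUDED_CODES).astype(np.uint8)
        return Raster(values=vals, grid=self.landcover.grid,
                      crs=self.landcover.crs, nodata=None)


def _build_manifest(config, truth, cover: Raster) -> dict:
    grid = config.grid()
    cell_km2 = grid.cell_area / 1e6
    suit = _suitable_cell_mask(config, truth, cover)
    sand_m, sand_s = config.expected_sand_stats()
    depth_m, depth_s = config.expected_depth_stats()
    sand_thr, depth_thr = config.true_thresholds()

    suitable_cover_cells = {}
    cpu = config.cells_per_unit
    nuy, nux = config.unit_shape
    suit_units = np.zeros((nuy, nux), dtype=bool)
    for r in truth.itertuples():
        suit_units[r.unit_row, r.unit_col] = r.suitable
    suit_unit_cells = np.kron(suit_units, np.ones((cpu, cpu), dtype=bool))
    for cat, codes in CATEGORY_CODES.items():
        suitable_cover_cells[cat] = int(
            (suit_unit_cells & np.isin(cover.values, codes)).sum()
        )

    return {
        "seed": int(config.seed),
        "extent_m": [float(config.extent[0]), float(config.extent[1])],
        "cell_size_m": float(config.cell_size),
        "mapunit_size_m": float(config.mapunit_size),
        "n_mapunits": int(config.n_mapunits),
        "n_patch_units": int(truth["is_patch"].sum()),
        "n_suitable_units": int(truth["suitable"].sum()),
        "expected_sand_mean": sand_m,
        "expected_sand_sd": sand_s,
        "expected_depth_mean": depth_m,
        "expected_depth_sd": depth_s,
        "true_sand_threshold": int(sand_thr),
        "true_depth_threshold": int(depth_thr),
        "true_suitable_area_km2": float(suit.sum()) * cell_km2,
        "suitable_cover_cells": suitable_cover_cells,
        "total_cells": int(grid.nrows * grid.ncols),
        "n_locations": int(config.n_locations),
        "n_species": int(config.n_species),
        "n_nonfocal": int(config.n_nonfocal),
    }


def generate_scenario(config: SyntheticConfig, outdir=None) -> ScenarioBundle:
    """Generate the full bundle; optionally write every artifact to ``outdir``.

    Files written: soils/ (map-unit GeoJSON + CSV tables), locations.geojson,
    nonfocal.geojson, landcover.tif, species.csv, truth_mapunits.csv,
    manifest.yaml.
    """
    config.validate()
    survey, truth = generate_soil_survey(config)
    locations = generate_locations(config, survey, truth)
    landcover = generate_landcover(config, truth)
    species, nonfocal = generate_occurrences(config, truth, landcover)
    manifest = _build_manifest(config, truth, landcover)

    bundle = ScenarioBundle(
        config=config, survey=survey, truth=truth, locations=locations,
        landcover=landcover, species=species, nonfocal=nonfocal, manifest=manifest,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_soil_tables(survey, outdir / "soils")
        write_vector_layer(locations, outdir / "locations.geojson")
        write_vector_layer(
            VectorLayer(table=nonfocal.records, crs=config.crs),
            outdir / "nonfocal.geojson",
        )
        write_geotiff(outdir / "landcover.tif", landcover)
        write_species_csv(species, outdir / "species.csv")
        truth.to_csv(outdir / "truth_mapunits.csv", index=False)
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump({"config": config.to_dict(), "truth": manifest}, fh,
                           sort_keys=False)
    return bundle
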