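"""Per-soil-type aggregation: depth-weighted mean sand and capped soil depth.

A soil type (an SSURGO-style component) is described by depth-ordered
horizons. Its single percent-sand value is the mean over the whole profile,
weighting each horizon's percent sand by the horizon's thickness in cm.
Its soil depth is the depth to the nearest restrictive layer (bedrock,
fragipan, ...), capped at ``cap_depth`` (200 cm by default — the maximum
depth soil surveys describe); a profile with no reported restrictive layer
is assigned the cap.

Horizons with unmeasured (null) percent sand are excluded from both the
numerator and denominator of the weighted mean rather than imputed; a
profile where every horizon is null yields a null mean, flagged so callers
can exclude the soil type downstream. The cap applies only to restrictive
depth, never to horizon weighting: the profile mean covers the entire
described profile.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .io_formats import SoilSurveyDataset

__all__ = [
    "Horizon",
    "SoilProfile",
    "profile_mean_sand",
    "profile_depth",
    "profiles_from_survey",
    "soil_type_values",
]

DEFAULT_CAP_DEPTH = 200.0


@dataclasses.dataclass(frozen=True)
class Horizon:
    """One soil layer: depth interval (cm from the surface) and percent sand."""

    top_depth: float
    bottom_depth: float
    percent_sand: float | None = None

    def __post_init__(self) -> None:
        if not self.bottom_depth > self.top_depth:
            raise ValueError(
                f"horizon bottom ({self.bottom_depth}) must exceed top ({self.top_depth})"
            )
        ps = self.percent_sand
        if ps is not None and not math.isnan(ps) and not (0.0 <= ps <= 100.0):
            raise ValueError(f"percent sand {ps} outside [0, 100]")

    @property
    def length(self) -> float:
        return self.bottom_depth - self.top_depth


@dataclasses.dataclass
class SoilProfile:
    """A soil type's ordered horizons plus its restrictive-layer depth."""

    soil_type_id: object
    horizons: list[Horizon]
    restrictive_depth: float | None = None
    cap_depth: float = DEFAULT_CAP_DEPTH

    def __post_init__(self) -> None:
        hs = sorted(self.horizons, key=lambda h: h.top_depth)
        for a, b in zip(hs, hs[1:]):
            if b.top_depth < a.bottom_depth - 1e-9:
                raise ValueError(
                    f"soil type {self.soil_type_id}: overlapping horizons "
                    f"({a.top_depth}-{a.bottom_depth} and {b.top_depth}-{b.bottom_depth})"
                )
        self.horizons = hs
        rd = self.restrictive_depth
        if rd is not None and not math.isnan(rd) and rd <= 0:
            raise ValueError(f"soil type {self.soil_type_id}: restrictive depth must be > 0")


def _is_null(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def profile_mean_sand(profile: SoilProfile) -> float | None:
    """Thickness-weighted mean percent sand over the whole profile.

    Returns ``None`` when no horizon has a measured percent sand (the
    caller's cue to exclude the soil type rather than treat it as sand-free).
    """
    num = 0.0
    den = 0.0
    for h in profile.horizons:
        if _is_null(h.percent_sand):
            continue
        num += h.length * h.percent_sand
        den += h.length
    if den == 0.0:
        return None
    return num / den


def profile_depth(profile: SoilProfile) -> float:
    """Depth (cm) to the nearest restrictive layer, capped at ``cap_depth``."""
    rd = profile.restrictive_depth
    if _is_null(rd):
        return profile.cap_depth
    return min(rd, profile.cap_depth)


def profiles_from_survey(
    survey: SoilSurveyDataset, cap_depth: float = DEFAULT_CAP_DEPTH
) -> list[SoilProfile]:
    """Materialize one :class:`SoilProfile` per soil type in a survey."""
    rd_map = survey.soil_types.set_index("soil_type_id")["restrictive_depth"]
    profiles = []
    for stid, grp in survey.horizons.groupby("soil_type_id", sort=False):
        horizons = [
            Horizon(
                top_depth=float(r.top_depth),
                bottom_depth=float(r.bottom_depth),
                percent_sand=None if pd.isna(r.percent_sand) else float(r.percent_sand),
            )
            for r in grp.itertuples()
        ]
        rd = rd_map.get(stid)
        profiles.append(
            SoilProfile(
                soil_type_id=stid,
                horizons=horizons,
                restrictive_depth=None if pd.isna(rd) else float(rd),
                cap_depth=cap_depth,
            )
        )
    return profiles


def soil_type_values(
    survey: SoilSurveyDataset, cap_depth: float = DEFAULT_CAP_DEPTH
) -> pd.DataFrame:
    """Aggregate every soil type to (mean_sand, depth).

    Returns a DataFrame indexed by soil_type_id with columns ``mean_sand``
    (NaN where no horizon carries sand data) and ``depth`` (always present
    thanks to the cap rule).
    """
    rows = []
    for prof in profiles_from_survey(survey, cap_depth=cap_depth):
        ms = profile_mean_sand(prof)
        rows.append(
            {
                "soil_type_id": prof.soil_type_id,
                "mean_sand": np.nan if ms is None else ms,
                "depth": profile_depth(prof),
            }
        )
    # soil types listed without horizons still get a depth via the cap rule
    seen = {r["soil_type_id"] for r in rows}
    for r in survey.soil_types.itertuples():
        if r.soil_type_id not in seen:
            rd = r.restrictive_depth
            depth = cap_depth if pd.isna(rd) else min(float(rd), cap_depth)
            rows.append({"soil_type_id": r.soil_type_id, "mean_sand": np.nan, "depth": depth})
    return pd.DataFrame(rows).set_index("soil_type_id")
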