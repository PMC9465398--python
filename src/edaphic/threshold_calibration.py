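"""Suitability-threshold calibration from known ecosystem locations.

The model's two thresholds — minimum percent sand and minimum soil depth —
are calibrated from a random training subset (70% by default) of the known
ecosystem locations. Over the training locations, the statewide mean and SD
of percent sand and soil depth are computed weighting each location by its
mapped area, and each threshold is set one area-weighted SD below the
area-weighted mean (e.g. 87 − 11 = 76% sand, 193 − 33 = 160 cm depth on the
New York training set). The held-out locations feed the validation stage.

The weighted SD is the population form, sqrt(Σw(x−m)²/Σw): it equals the
ordinary population SD of the data with each value replicated in proportion
to its weight, and is invariant to rescaling all weights.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd

from .location_aggregation import (
    LocationComposition,
    location_mean_depth,
    location_mean_sand,
)

__all__ = [
    "CalibrationResult",
    "round_half_up",
    "split_train_validation",
    "area_weighted_stats",
    "derive_thresholds",
    "calibrate",
]

logger = logging.getLogger(__name__)


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties away from zero-point-five up."""
    return int(math.floor(x + 0.5))


@dataclasses.dataclass
class CalibrationResult:
    """Training-set statistics and the derived suitability thresholds."""

    n_train: int
    n_validation: int
    mean_sand: float
    sd_sand: float
    mean_depth: float
    sd_depth: float
    sand_threshold: float
    depth_threshold: float
    sand_threshold_raw: float
    depth_threshold_raw: float
    seed: int
    split_fraction: float
    rounding: str
    train_ids: list
    validation_ids: list
    n_excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        scalars = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name not in ("train_ids", "validation_ids")
        }
        return pd.DataFrame([scalars])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CalibrationResult":
        row = df.iloc[0].to_dict()
        row["rounding"] = str(row["rounding"])
        return cls(train_ids=[], validation_ids=[], **{
            k: row[k] for k in row
            if k in {f.name for f in dataclasses.fields(cls)} - {"train_ids", "validation_ids"}
        })


def split_train_validation(location_ids, fraction: float, seed: int):
    """Random train/validation partition of location ids.

    The training size is round-half-up of ``fraction × N`` (so 156 locations
    at 70% give 109 training and 47 validation); sampling is uniform without
    replacement and deterministic for a given seed. Returned lists preserve
    the input ordering.
    """
    ids = list(location_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 locations to split")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    n_train = min(n, max(1, round_half_up(fraction * n)))
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(n, size=n_train, replace=False).tolist())
    train = [ids[i] for i in range(n) if i in chosen]
    validation = [ids[i] for i in range(n) if i not in chosen]
    return train, validation


def area_weighted_stats(values, weights) -> tuple[float, float]:
    """Weighted mean and population-form weighted SD.

    Equivalent to ordinary population statistics with each value replicated
    proportionally to its weight.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if x.size == 0:
        raise ValueError("empty input")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    mean = float((w * x).sum() / w.sum())
    sd = float(np.sqrt((w * (x - mean) ** 2).sum() / w.sum()))
    return mean, sd


def derive_thresholds(mean: float, sd: float, rounding: str = "integer") -> float:
    """Threshold = mean − one SD, optionally rounded half-up to an integer."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    raw = mean - sd
    if rounding == "integer":
        return float(round_half_up(raw))
    if rounding == "none":
        return raw
    raise ValueError(f"unknown rounding mode {rounding!r}")


def calibrate(
    locations: list[LocationComposition],
    fraction: float = 0.7,
    seed: int = 0,
    rounding: str = "integer",
) -> CalibrationResult:
    """Run the full calibration: split, area-weighted stats, thresholds.

    Locations whose entire composition lacks sand data are excluded (the
    location mean is undefined for them) and counted in the run log.
    """
    usable = [c for c in locations if c.has_sand_data]
    n_excluded = len(locations) - len(usable)
    if n_excluded:
        logger.info("calibration: excluded %d location(s) with no sand data", n_excluded)
    if len(usable) < 2:
        raise ValueError("need at least 2 usable locations to calibrate")

    ids = [c.location_id for c in usable]
    train_ids, validation_ids = split_train_validation(ids, fraction, seed)
    train_set = set(train_ids)
    train = [c for c in usable if c.location_id in train_set]

    sands = [location_mean_sand(c) for c in train]
    depths = [location_mean_depth(c) for c in train]
    areas = [c.total_area for c in train]

    mean_sand, sd_sand = area_weighted_stats(sands, areas)
    mean_depth, sd_depth = area_weighted_stats(depths, areas)
    result = CalibrationResult(
        n_train=len(train_ids),
        n_validation=len(validation_ids),
        mean_sand=mean_sand,
        sd_sand=sd_sand,
        mean_depth=mean_depth,
        sd_depth=sd_depth,
        sand_threshold=derive_thresholds(mean_sand, sd_sand, rounding),
        depth_threshold=derive_thresholds(mean_depth, sd_depth, rounding),
        sand_threshold_raw=mean_sand - sd_sand,
        depth_threshold_raw=mean_depth - sd_depth,
        seed=seed,
        split_fraction=fraction,
        rounding=rounding,
        train_ids=train_ids,
        validation_ids=validation_ids,
        n_excluded=n_excluded,
    )
    logger.info(
        "calibration: n_train=%d n_validation=%d sand %.2f±%.2f -> %g; depth %.2f±%.2f -> %g",
        result.n_train, result.n_validation, mean_sand, sd_sand,
        result.sand_threshold, mean_depth, sd_depth, result.depth_threshold,
    )
    return result
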