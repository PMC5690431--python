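"""Variable construction for the neighbourhood obesity panel.

Implements the study's preprocessing conventions: BMI-percentile weight
categories, per-1000 prevalence normalization, straight-line 800 m walkshed
exposure, walkability banding, and assembly of the regression-ready table
with an explicit exclusion log.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

WEIGHT_CATEGORIES = ("underweight", "healthy", "overweight", "obese")

#: default covariate block (Table-2 ordering: SES, foodscape, built environment)
DEFAULT_COVARIATES = (
    "education_norm",
    "immigrants_norm",
    "income",
    "fastfood_exposure",
    "park_exposure",
    "walkscore",
    "pathway_km",
)

REQUIRED_RAW_COLUMNS = (
    "id",
    "u",
    "v",
    "total_children",
    "underweight",
    "healthy",
    "overweight",
    "obese",
    "education_raw",
    "immigrants_raw",
    "income",
    "fastfood_exposure",
    "park_exposure",
    "walkscore",
    "pathway_km",
)

#: BMI-percentile cut points: underweight below the 5th percentile, overweight
#: from the 85th, obese from the 95th; lower bounds are closed.
BMI_CUTS = {"underweight": 5.0, "overweight": 85.0, "obese": 95.0}

#: walkscore band edges (public Walkscore scheme): below 50 car dependent,
#: 50-70 somewhat walkable, 70+ highly walkable.
WALKABILITY_BANDS = (50.0, 70.0)


def classify_bmi_percentile(percentile: float) -> str:
    """Map an age/sex-specific BMI percentile to a weight category.

    Obese at or above the 95th percentile, overweight from the 85th up to
    (but excluding) the 95th, underweight below the 5th, healthy otherwise.
    """
    p = float(percentile)
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"BMI percentile must be in [0, 100], got {percentile!r}")
    if p >= BMI_CUTS["obese"]:
        return "obese"
    if p >= BMI_CUTS["overweight"]:
        return "overweight"
    if p < BMI_CUTS["underweight"]:
        return "underweight"
    return "healthy"


def normalize_per_thousand(count: float, denominator: float) -> float:
    """Per-1000 rate: ``1000 * count / denominator``.

    The exact value is returned; rounding to integer happens only at report
    time (see :func:`report_per_thousand`).
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive (unit should have been excluded)")
    if count < 0 or count > denominator:
        raise ValueError(f"count must lie in [0, denominator], got {count} of {denominator}")
    return 1000.0 * count / denominator


def report_per_thousand(count: float, denominator: float) -> int:
    """Per-1000 rate rounded to the nearest integer, the reporting convention."""
    return int(round(normalize_per_thousand(count, denominator)))


def weight_category_shares(counts: Mapping[str, float]) -> dict[str, float]:
    """Percentage share of each weight category in a sample.

    ``counts`` maps category name to child count; shares are percentages of
    the total across the supplied categories (unrounded).
    """
    total = float(sum(counts.values()))
    if total <= 0:
        raise ValueError("total count must be positive")
    return {k: 100.0 * v / total for k, v in counts.items()}


def walkshed_exposure(
    child_points: np.ndarray,
    amenity_points: np.ndarray,
    radius: float = 800.0,
    total_children: int | None = None,
) -> float:
    """Per-1000 count of children within ``radius`` metres of any amenity.

    Each child is counted once even when several walksheds overlap: the test
    is on the distance to the *nearest* amenity. Distances are straight-line
    on projected coordinates. With no amenities the exposure is 0.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    child_points = np.atleast_2d(np.asarray(child_points, dtype=float))
    if child_points.size == 0:
        child_points = child_points.reshape(0, 2)
    n_children = len(child_points)
    total = n_children if total_children is None else int(total_children)
    if total <= 0:
        raise ValueError("total_children must be positive")
    amenity_points = np.atleast_2d(np.asarray(amenity_points, dtype=float))
    if amenity_points.size == 0 or n_children == 0:
        return 0.0
    tree = cKDTree(amenity_points)
    nearest, _ = tree.query(child_points, k=1)
    inside = int(np.sum(nearest <= radius))
    return normalize_per_thousand(inside, total)


def classify_walkability(walkscore: float, bands: Sequence[float] = WALKABILITY_BANDS) -> str:
    """Band a 0-100 walkscore: car_dependent / somewhat_walkable / highly_walkable."""
    s = float(walkscore)
    if not 0.0 <= s <= 100.0:
        raise ValueError(f"walkscore must be in [0, 100], got {walkscore!r}")
    lo, hi = bands
    if s < lo:
        return "car_dependent"
    if s < hi:
        return "somewhat_walkable"
    return "highly_walkable"


def build_model_table(
    raw: pd.DataFrame,
    min_children: int = 8,
    required_columns: Iterable[str] = REQUIRED_RAW_COLUMNS,
    n_covariates: int = len(DEFAULT_COVARIATES),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the regression-ready neighbourhood table.

    Rows with fewer than ``min_children`` children or any missing required
    value are dropped and logged with a reason. Underweight children stay in
    the totals but never enter a response variable: only the obese and
    overweight counts are normalized into per-1000 prevalences. Adult
    education and immigrant counts are normalized by the total child
    population, the study's convention.

    Returns ``(table, exclusion_log)``; the log has one row per dropped
    neighbourhood with columns ``id`` and ``reason``.
    """
    required_columns = list(required_columns)
    missing_cols = [c for c in required_columns if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"raw table is missing required columns: {missing_cols}")

    exclusions: list[dict[str, object]] = []
    keep_mask = np.ones(len(raw), dtype=bool)
    for pos, (_, row) in enumerate(raw.iterrows()):
        if any(pd.isna(row[c]) for c in required_columns):
            exclusions.append({"id": row["id"], "reason": "missing variables"})
            keep_mask[pos] = False
        elif row["total_children"] < max(min_children, 1):
            exclusions.append({"id": row["id"], "reason": "low population"})
            keep_mask[pos] = False

    table = raw.loc[keep_mask].copy()
    n_min = n_covariates + 2
    if len(table) < n_min:
        raise ValueError(
            f"only {len(table)} neighbourhoods survive exclusion; "
            f"at least {n_min} are needed to fit the model"
        )

    total = table["total_children"].to_numpy(dtype=float)
    table["normalized_obese"] = 1000.0 * table["obese"].to_numpy(dtype=float) / total
    table["normalized_overweight"] = 1000.0 * table["overweight"].to_numpy(dtype=float) / total
    table["education_norm"] = 1000.0 * table["education_raw"].to_numpy(dtype=float) / total
    table["immigrants_norm"] = 1000.0 * table["immigrants_raw"].to_numpy(dtype=float) / total
    table["walkability_band"] = [classify_walkability(s) for s in table["walkscore"]]

    log = pd.DataFrame(exclusions, columns=["id", "reason"])
    if len(log):
        logger.info("excluded %d of %d neighbourhoods", len(log), len(raw))
    return table.reset_index(drop=True), log
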