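"""Synthetic neighbourhood panel generator.

Emulates a 174-neighbourhood urban panel with the statistical structure the
analysis assumes: covariates drawn from truncated normals whose moments match
the study city's published descriptive statistics, user-controlled spatially
varying coefficient surfaces linking covariates to per-1000 obesity and
overweight prevalence, multinomial weight-category counts, and amenity/child
point clouds for the walkshed-exposure operation. Because the true local
coefficient surfaces are stored alongside the table, parameter recovery by
the GWR engine is directly testable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .preprocess import walkshed_exposure

logger = logging.getLogger(__name__)

#: published city-wide descriptive statistics (min, max, mean, sd) used to
#: calibrate the truncated-normal covariate draws
CITY_CALIBRATION: dict[str, tuple[float, float, float, float]] = {
    "total_children": (8, 1232, 215, 215.02),
    "immigrants_norm": (93, 818, 231, 97.48),
    "education_norm": (0, 381, 102, 77.85),
    "income": (27, 280, 96, 36.90),
    "fastfood_exposure": (0, 1000, 388, 340.37),
    "park_exposure": (0, 1000, 845, 204.41),
    "walkscore": (15, 93, 52, 17.68),
    "pathway_km": (0, 22, 4, 4.04),
}

#: default true obesity-model coefficient surfaces (per-1000 response units).
#: Means follow the published local-coefficient means; the walkscore effect
#: carries a strong negative Gaussian bump in the city's northeast quadrant
#: so that spatial nonstationarity is present and recoverable.
def _default_obesity_surfaces(extent: tuple[float, float, float, float]) -> dict[str, dict]:
    x0, y0, x1, y1 = extent
    return {
        "education_norm": {"kind": "constant", "value": 0.06},
        "immigrants_norm": {"kind": "constant", "value": 0.08},
        "income": {"kind": "constant", "value": -0.12},
        "fastfood_exposure": {"kind": "constant", "value": 0.01},
        "park_exposure": {"kind": "constant", "value": -0.02},
        "walkscore": {
            "kind": "gaussian",
            "base": -0.05,
            "centre": (x0 + 0.75 * (x1 - x0), y0 + 0.75 * (y1 - y0)),
            "radius": 8000.0,
            "amplitude": -1.5,
        },
        "pathway_km": {"kind": "constant", "value": -1.26},
    }


def _default_overweight_surfaces(extent) -> dict[str, dict]:
    # overweight effects are small; walkability is not a significant driver
    return {
        "education_norm": {"kind": "constant", "value": 0.03},
        "immigrants_norm": {"kind": "constant", "value": 0.05},
        "income": {"kind": "constant", "value": -0.08},
        "fastfood_exposure": {"kind": "constant", "value": 0.01},
        "park_exposure": {"kind": "constant", "value": -0.01},
        "walkscore": {"kind": "constant", "value": -0.01},
        "pathway_km": {"kind": "constant", "value": -0.5},
    }


@dataclass
class CityConfig:
    """Configuration of the synthetic city.

    The defaults reproduce the study conditions: 174 neighbourhoods on a
    25 km x 25 km projected plane, covariates calibrated to the published
    city-wide statistics, a spatially varying (Gaussian-bump) walkscore
    effect on obesity prevalence, and ~4.7% underweight children.
    """

    n_neighbourhoods: int = 174
    seed: int = 0
    extent: tuple[float, float, float, float] = (0.0, 0.0, 25000.0, 25000.0)
    covariate_specs: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(CITY_CALIBRATION)
    )
    coefficient_surfaces: dict[str, dict] | None = None
    overweight_surfaces: dict[str, dict] | None = None
    baseline_prevalence: dict | float = 130.0
    overweight_baseline: dict | float = 128.0
    noise_sd: float = 20.0
    underweight_rate: float = 0.047
    n_fastfood: int = 110
    n_extra_parks: int = 60
    park_probability: float = 0.85
    walkshed_radius: float = 800.0
    expected_counts: bool = False
    exposures_from_points: bool = True

    def __post_init__(self) -> None:
        if self.n_neighbourhoods < 2:
            raise ValueError("need at least 2 neighbourhoods")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        x0, y0, x1, y1 = self.extent
        if x1 <= x0 or y1 <= y0:
            raise ValueError("degenerate extent: bounding box must have positive area")
        for name, (lo, hi, mean, sd) in self.covariate_specs.items():
            if hi <= lo or sd <= 0:
                raise ValueError(f"degenerate range for covariate {name!r}")
        if not 0 <= self.underweight_rate < 1:
            raise ValueError("underweight_rate must be a proportion in [0, 1)")
        if self.coefficient_surfaces is None:
            self.coefficient_surfaces = _default_obesity_surfaces(self.extent)
        if self.overweight_surfaces is None:
            self.overweight_surfaces = _default_overweight_surfaces(self.extent)


@dataclass
class SyntheticCity:
    """A generated city: the panel, its true coefficient surfaces and points."""

    table: pd.DataFrame
    true_surfaces: pd.DataFrame  # per-id true local coefficients + true rates
    amenity_points: dict[str, np.ndarray]  # 'fastfood' and 'park' coordinate arrays
    child_points: pd.DataFrame  # columns: id, x, y
    config: CityConfig


def make_coefficient_surface(spec: Mapping, coords: np.ndarray) -> np.ndarray:
    """Evaluate a coefficient surface at each coordinate.

    Families: ``constant`` (value), ``linear`` (base + gradient . (x, y)),
    ``gaussian`` (base + amplitude * exp(-d^2 / (2 r^2)) around a centre).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.size == 0:
        raise ValueError("coords must be non-empty")
    kind = spec.get("kind")
    if kind == "constant":
        return np.full(len(coords), float(spec["value"]))
    if kind == "linear":
        gx, gy = spec["gradient"]
        return float(spec.get("base", 0.0)) + gx * coords[:, 0] + gy * coords[:, 1]
    if kind == "gaussian":
        cx, cy = spec["centre"]
        r = float(spec["radius"])
        d2 = (coords[:, 0] - cx) ** 2 + (coords[:, 1] - cy) ** 2
        return float(spec.get("base", 0.0)) + float(spec["amplitude"]) * np.exp(-0.5 * d2 / r**2)
    raise ValueError(f"unknown surface family {kind!r}")


def sample_weight_categories(
    obese_rate: float,
    overweight_rate: float,
    underweight_rate: float,
    total: int,
    seed: int | np.random.Generator,
) -> tuple[int, int, int, int]:
    """Draw (underweight, healthy, overweight, obese) counts for one neighbourhood.

    ``obese_rate`` and ``overweight_rate`` are per-1000; ``underweight_rate``
    is a proportion. Counts are multinomial on the implied probabilities and
    always sum to ``total``.
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    p_ob, p_ow, p_uw = obese_rate / 1000.0, overweight_rate / 1000.0, float(underweight_rate)
    if min(p_ob, p_ow, p_uw) < 0:
        raise ValueError("rates must be non-negative")
    if p_ob + p_ow > 1.0 + 1e-12:
        raise ValueError("obese_rate + overweight_rate exceeds 1000 per-1000")
    p_healthy = 1.0 - p_ob - p_ow - p_uw
    if p_healthy < -1e-12:
        raise ValueError("category probabilities sum above 1")
    p = np.clip([p_uw, p_healthy, p_ow, p_ob], 0.0, None)
    p = p / p.sum()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    uw, he, ow, ob = rng.multinomial(int(total), p)
    return int(uw), int(he), int(ow), int(ob)


def expected_weight_categories(
    obese_rate: float, overweight_rate: float, underweight_rate: float, total: int
) -> tuple[int, int, int, int]:
    """Deterministic expected counts (rates x total, rounded; healthy absorbs the remainder)."""
    ob = int(round(obese_rate / 1000.0 * total))
    ow = int(round(overweight_rate / 1000.0 * total))
    uw = int(round(underweight_rate * total))
    he = int(total) - ob - ow - uw
    if he < 0:  # rounding can overshoot by a child or two; take them back from uw, then ow
        give_back = min(uw, -he)
        uw -= give_back
        he += give_back
        if he < 0:
            ow += he
            he = 0
        if min(uw, he, ow, ob) < 0:
            raise ValueError("expected counts exceed total; rates are inconsistent")
    return uw, he, ow, ob


def _truncnorm_rvs(lo: float, hi: float, mean: float, sd: float, size: int, rng) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _jittered_grid(n: int, extent, rng) -> np.ndarray:
    x0, y0, x1, y1 = extent
    m = math.ceil(math.sqrt(n))
    sx, sy = (x1 - x0) / m, (y1 - y0) / m
    cells = [(i, j) for j in range(m) for i in range(m)][:n]
    pts = np.array(
        [
            (
                x0 + (i + 0.5) * sx,
                y0 + (j + 0.5) * sy,
            )
            for i, j in cells
        ]
    )
    pts += rng.uniform(-0.3, 0.3, size=pts.shape) * np.array([sx, sy])
    return pts


def generate_city(config: CityConfig) -> SyntheticCity:
    """Generate a reproducible synthetic city from ``config``.

    True per-1000 obesity and overweight prevalences are built as
    ``intercept surface + sum_k surface_k(u, v) * covariate_k + noise``,
    clamped to [0, 1000] (with a logged warning if clamping occurs), and
    converted to integer category counts either multinomially or, in
    expected-count mode, deterministically.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_neighbourhoods
    coords = _jittered_grid(n, cfg.extent, rng)
    x0, y0, x1, y1 = cfg.extent
    spacing = (x1 - x0) / math.ceil(math.sqrt(n))

    cov: dict[str, np.ndarray] = {}
    for name, (lo, hi, mean, sd) in cfg.covariate_specs.items():
        cov[name] = _truncnorm_rvs(lo, hi, mean, sd, n, rng)
    total_children = np.maximum(
        np.round(cov.pop("total_children")).astype(int), int(cfg.covariate_specs["total_children"][0])
    )

    # child point clouds: children live in a disc around their centroid
    child_frames = []
    for i in range(n):
        k = total_children[i]
        ang = rng.uniform(0, 2 * np.pi, k)
        rad = 0.45 * spacing * np.sqrt(rng.uniform(0, 1, k))
        child_frames.append(
            pd.DataFrame(
                {
                    "id": f"N{i:03d}",
                    "x": coords[i, 0] + rad * np.cos(ang),
                    "y": coords[i, 1] + rad * np.sin(ang),
                }
            )
        )
    child_points = pd.concat(child_frames, ignore_index=True)
    child_points["x"] = child_points["x"].clip(x0, x1)
    child_points["y"] = child_points["y"].clip(y0, y1)

    # amenities: fast food uniform city-wide; most neighbourhoods host a local park
    fastfood = rng.uniform([x0, y0], [x1, y1], size=(cfg.n_fastfood, 2))
    park_rows = [
        np.clip(coords[i] + rng.normal(0, 300.0, 2), [x0, y0], [x1, y1])
        for i in range(n)
        if rng.uniform() < cfg.park_probability
    ]
    parks = np.vstack([np.array(park_rows).reshape(-1, 2), rng.uniform([x0, y0], [x1, y1], size=(cfg.n_extra_parks, 2))])

    if cfg.exposures_from_points:
        ff_exp = np.empty(n)
        pk_exp = np.empty(n)
        for i in range(n):
            pts = child_frames[i][["x", "y"]].to_numpy()
            ff_exp[i] = walkshed_exposure(pts, fastfood, cfg.walkshed_radius, total_children[i])
            pk_exp[i] = walkshed_exposure(pts, parks, cfg.walkshed_radius, total_children[i])
        cov["fastfood_exposure"] = ff_exp
        cov["park_exposure"] = pk_exp

    covariate_names = [c for c in cfg.covariate_specs if c != "total_children"]
    true_surf: dict[str, np.ndarray] = {}
    ob_rate = np.asarray(
        make_coefficient_surface(
            cfg.baseline_prevalence
            if isinstance(cfg.baseline_prevalence, Mapping)
            else {"kind": "constant", "value": cfg.baseline_prevalence},
            coords,
        ),
        dtype=float,
    ).copy()
    ow_rate = np.asarray(
        make_coefficient_surface(
            cfg.overweight_baseline
            if isinstance(cfg.overweight_baseline, Mapping)
            else {"kind": "constant", "value": cfg.overweight_baseline},
            coords,
        ),
        dtype=float,
    ).copy()
    true_surf["intercept_obese"] = ob_rate.copy()
    true_surf["intercept_overweight"] = ow_rate.copy()
    for name in covariate_names:
        s_ob = make_coefficient_surface(cfg.coefficient_surfaces[name], coords)
        s_ow = make_coefficient_surface(cfg.overweight_surfaces[name], coords)
        true_surf[f"beta_obese_{name}"] = s_ob
        true_surf[f"beta_overweight_{name}"] = s_ow
        ob_rate += s_ob * cov[name]
        ow_rate += s_ow * cov[name]
    if cfg.noise_sd > 0:
        ob_rate += rng.normal(0.0, cfg.noise_sd, n)
        ow_rate += rng.normal(0.0, cfg.noise_sd, n)

    uw_budget = 1000.0 * (1.0 - cfg.underweight_rate)
    clamped = (ob_rate < 0) | (ob_rate + ow_rate > uw_budget) | (ow_rate < 0)
    if clamped.any():
        logger.warning("prevalence clamped to [0, 1000] in %d of %d neighbourhoods", int(clamped.sum()), n)
    ob_rate = np.clip(ob_rate, 0.0, 1000.0)
    ow_rate = np.clip(ow_rate, 0.0, np.maximum(uw_budget - ob_rate, 0.0))
    true_surf["true_obese_rate"] = ob_rate
    true_surf["true_overweight_rate"] = ow_rate

    counts = np.empty((n, 4), dtype=int)
    for i in range(n):
        if cfg.expected_counts:
            counts[i] = expected_weight_categories(
                ob_rate[i], ow_rate[i], cfg.underweight_rate, total_children[i]
            )
        else:
            counts[i] = sample_weight_categories(
                ob_rate[i], ow_rate[i], cfg.underweight_rate, total_children[i], rng
            )

    total_f = total_children.astype(float)
    if cfg.expected_counts:
        norm_ob, norm_ow = ob_rate, ow_rate  # exact linear construction, no rounding
    else:
        norm_ob = 1000.0 * counts[:, 3] / total_f
        norm_ow = 1000.0 * counts[:, 2] / total_f

    ids = [f"N{i:03d}" for i in range(n)]
    table = pd.DataFrame(
        {
            "id": ids,
            "u": coords[:, 0],
            "v": coords[:, 1],
            "total_children": total_children,
            "underweight": counts[:, 0],
            "healthy": counts[:, 1],
            "overweight": counts[:, 2],
            "obese": counts[:, 3],
            "education_raw": np.round(cov["education_norm"] * total_f / 1000.0).astype(int),
            "immigrants_raw": np.round(cov["immigrants_norm"] * total_f / 1000.0).astype(int),
            "income": cov["income"],
            "fastfood_exposure": cov["fastfood_exposure"],
            "park_exposure": cov["park_exposure"],
            "walkscore": cov["walkscore"],
            "pathway_km": cov["pathway_km"],
            "normalized_obese": norm_ob,
            "normalized_overweight": norm_ow,
            "education_norm": cov["education_norm"],
            "immigrants_norm": cov["immigrants_norm"],
        }
    )
    true_surfaces = pd.DataFrame({"id": ids, **true_surf})
    return SyntheticCity(
        table=table,
        true_surfaces=true_surfaces,
        amenity_points={"fastfood": fastfood, "park": parks},
        child_points=child_points,
        config=cfg,
    )
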