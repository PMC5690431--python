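"""Closing the loop: feedback GWR re-run, significance transitions, map export.

After a simulated intervention, the end-year obese counts are re-normalized
per-1000, the walkscore column is updated by the scenario's change, and the
GWR model is re-fit with the baseline kernel settings. Comparing the local
walkscore coefficient's significance class before and after quantifies how
far the intervention "explains away" walkability as a local risk factor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gwr import GWRResults, fit_gwr
from .preprocess import DEFAULT_COVARIATES
from .simulate import Trajectory
from .targeting import TargetSet


@dataclass
class TransitionReport:
    """Before/after comparison for the targeted neighbourhoods under one scenario.

    ``rows`` is indexed by id with the stock changes, the walkscore
    coefficient, t value and significance class before and after;
    ``transitions`` tallies class movements (99->95, 95->90, any->below-90).
    """

    rows: pd.DataFrame
    transitions: dict[str, int]
    scenario_name: str


def feedback_rerun(
    traj: Trajectory,
    table: pd.DataFrame,
    scenario=None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    response: str = "normalized_obese",
    spec=None,
    baseline: GWRResults | None = None,
) -> GWRResults:
    """Re-fit the GWR model on post-intervention prevalence and walkscore.

    ``spec`` defaults to the baseline fit's kernel spec (like-for-like
    comparison; the bandwidth is reused, not re-selected). The trajectory
    must cover every model-table neighbourhood — non-targets ride along at
    baseline so the base scenario reproduces the baseline fit exactly.
    """
    scenario = scenario if scenario is not None else traj.scenario
    if scenario.name != traj.scenario.name:
        raise ValueError(
            f"scenario {scenario.name!r} does not match the trajectory's {traj.scenario.name!r}"
        )
    if spec is None:
        if baseline is None:
            raise ValueError("pass either a kernel spec or the baseline GWRResults")
        spec = baseline.spec

    final = traj.final()
    missing = pd.Index(table["id"]).difference(final.index)
    if len(missing):
        raise ValueError(f"trajectory does not cover neighbourhoods: {list(missing)[:5]}")

    post = table.copy()
    idx = pd.Index(post["id"])
    total = post["total_children"].to_numpy(dtype=float)
    end_obese = final.loc[idx, "obese"].to_numpy(dtype=float)
    end_overweight = final.loc[idx, "overweight"].to_numpy(dtype=float)
    post["obese"] = end_obese
    post["overweight"] = end_overweight
    post["normalized_obese"] = 1000.0 * end_obese / total
    post["normalized_overweight"] = 1000.0 * end_overweight / total
    delta = scenario.delta_for(idx).to_numpy()
    post["walkscore"] = np.clip(post["walkscore"].to_numpy(dtype=float) + delta, 0.0, 100.0)
    return fit_gwr(post, response, covariates, spec)


def significance_transitions(
    before: GWRResults,
    after: GWRResults,
    targets: TargetSet,
    coefficient: str = "walkscore",
    traj: Trajectory | None = None,
    table: pd.DataFrame | None = None,
    scenario_name: str | None = None,
) -> TransitionReport:
    """Per-target significance-class pairs and aggregate transition tallies.

    Optionally joins the stock changes (count and per-1000) when a trajectory
    and table are supplied. Non-target neighbourhoods are excluded.
    """
    ids = pd.Index(targets.ids, name="id")
    for fits, label in ((before, "before"), (after, "after")):
        missing = ids.difference(fits.local.index)
        if len(missing):
            raise ValueError(f"target ids missing from the {label} fits: {list(missing)[:5]}")
    cols = {f"beta_{coefficient}", f"t_{coefficient}", f"sig_{coefficient}"}
    if not cols <= set(before.local.columns) & set(after.local.columns):
        raise ValueError(f"before/after fits do not share the {coefficient!r} coefficient block")

    rows = pd.DataFrame(index=ids)
    rows["beta_before"] = before.local.loc[ids, f"beta_{coefficient}"]
    rows["beta_after"] = after.local.loc[ids, f"beta_{coefficient}"]
    rows["t_before"] = before.local.loc[ids, f"t_{coefficient}"]
    rows["t_after"] = after.local.loc[ids, f"t_{coefficient}"]
    rows["sig_before"] = before.local.loc[ids, f"sig_{coefficient}"].astype(int)
    rows["sig_after"] = after.local.loc[ids, f"sig_{coefficient}"].astype(int)

    if traj is not None and table is not None:
        start = traj.at_year(traj.scenario.start_year)
        final = traj.final()
        total = table.set_index("id").loc[ids, "total_children"].astype(float)
        for stock in ("obese", "overweight", "healthy"):
            change = final.loc[ids, stock] - start.loc[ids, stock]
            rows[f"{stock}_change"] = change
            rows[f"{stock}_change_per1000"] = 1000.0 * change / total

    tallies = {
        "99_to_95": int(((rows["sig_before"] == 99) & (rows["sig_after"] == 95)).sum()),
        "95_to_90": int(((rows["sig_before"] == 95) & (rows["sig_after"] == 90)).sum()),
        "below_90": int(((rows["sig_before"] >= 90) & (rows["sig_after"] == 0)).sum()),
        "unchanged": int((rows["sig_before"] == rows["sig_after"]).sum()),
    }
    name = scenario_name or (traj.scenario.name if traj is not None else "")
    return TransitionReport(rows=rows, transitions=tallies, scenario_name=name)


def export_map_layer(
    fits: GWRResults,
    geometry: Mapping,
    coefficient: str,
    r2_bands: tuple[float, float] = (0.25, 0.5),
) -> dict:
    """Combined attribute layer: coefficient, significance class, local-R2 band.

    ``geometry`` maps neighbourhood id to a GeoJSON geometry dict (or a
    shapely geometry). Every feature carries the three attributes behind the
    study's single-map visualisation. Returns a GeoJSON FeatureCollection.
    """
    beta_col = f"beta_{coefficient}"
    if beta_col not in fits.local.columns:
        raise ValueError(f"unknown coefficient {coefficient!r}")
    unmatched = [i for i in fits.local.index if i not in geometry]
    if unmatched:
        raise ValueError(f"geometry missing for neighbourhoods: {unmatched[:5]}")

    lo, hi = r2_bands
    features = []
    for nid, row in fits.local.iterrows():
        geom = geometry[nid]
        if hasattr(geom, "__geo_interface__"):
            geom = json.loads(json.dumps(geom.__geo_interface__))
        r2 = row["local_r2"]
        band = "low" if r2 < lo else ("medium" if r2 < hi else "high")
        features.append(
            {
                "type": "Feature",
                "id": str(nid),
                "geometry": geom,
                "properties": {
                    "coefficient": float(row[beta_col]) if np.isfinite(row[beta_col]) else None,
                    "significance": int(row[f"sig_{coefficient}"]),
                    "local_r2_band": band,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}
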