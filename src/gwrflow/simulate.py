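"""Subscripted stock-flow simulation of neighbourhood weight categories.

Each neighbourhood carries three stocks — healthy, overweight and obese
children — connected by two one-directional-per-gap flows: obese <->
overweight (governed by the local obesity model) and overweight <-> healthy
(governed by the local overweight model). Transitions are progressive: a
child can only move to an adjacent stock, never directly between obese and
healthy. A walkscore intervention shifts each targeted neighbourhood's
GWR-implied goal prevalence, and first-order goal-seeking flows (gap over an
adjustment time tau, default one year) move children toward the goals under
explicit Euler integration.

The overweight <-> healthy flow seeks the overweight model's own goal,
measured on the overweight stock net of the cumulative "backup" inflow
received from the obese stock. This keeps children displaced from the obese
stock inside the overweight stock unless the overweight model itself pushes
them onward — reproducing the transient backup influx of overweight children
during the first year after an intervention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwr import GWRResults

logger = logging.getLogger(__name__)

STOCKS = ("healthy", "overweight", "obese")


@dataclass
class FlowSpec:
    """Per-neighbourhood flow parameters derived from the two GWR fits.

    ``frame`` is indexed by id with columns ``beta_ws_obese`` and
    ``beta_ws_overweight`` (per-1000 prevalence change per walkscore point)
    and ``total_children``. ``tau`` is the adjustment time in years.
    """

    frame: pd.DataFrame
    tau: float = 1.0
    significance_gate: int | None = None

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("adjustment time tau must be positive")


@dataclass(frozen=True)
class Scenario:
    """A named walkscore intervention on a subset of neighbourhoods."""

    name: str
    delta_walkscore: float = 0.0
    target_ids: tuple = ()
    start_year: int = 2009
    end_year: int = 2015
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.end_year <= self.start_year:
            raise ValueError("end_year must be after start_year")
        n_steps = (self.end_year - self.start_year) / self.dt
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("dt must divide the simulation horizon")

    def delta_for(self, ids) -> pd.Series:
        d = pd.Series(0.0, index=pd.Index(ids, name="id"))
        d.loc[[i for i in self.target_ids if i in d.index]] = float(self.delta_walkscore)
        return d


BASE_SCENARIO = Scenario(name="base")


@dataclass
class Trajectory:
    """Per-neighbourhood time series of the three stocks and the two flows."""

    frame: pd.DataFrame  # columns: id, year, healthy, overweight, obese, + flows
    scenario: Scenario
    spec: FlowSpec
    goals: pd.DataFrame = field(default=None)

    def at_year(self, year: int) -> pd.DataFrame:
        sub = self.frame[self.frame["year"] == year]
        if sub.empty:
            raise ValueError(f"year {year} not simulated")
        return sub.set_index("id")

    def final(self) -> pd.DataFrame:
        return self.at_year(int(self.frame["year"].max()))


def build_flow_model(
    obesity_fits: GWRResults,
    overweight_fits: GWRResults,
    table: pd.DataFrame,
    tau: float = 1.0,
    significance_gate: int | None = None,
    coefficient: str = "walkscore",
) -> FlowSpec:
    """Link the local walkscore coefficients of both GWR models to flows.

    A walkscore change of ``delta`` shifts the obese goal by
    ``beta_ws_obese * delta * total_children / 1000`` children (likewise the
    overweight goal via the overweight model). By default coefficients enter
    at face value whatever their significance; ``significance_gate`` zeroes
    any coefficient whose class falls below the gate.
    """
    ids = pd.Index(table["id"], name="id")
    for fits, label in ((obesity_fits, "obesity"), (overweight_fits, "overweight")):
        missing = ids.difference(fits.local.index)
        if len(missing):
            raise ValueError(f"{label} fits missing coefficients for neighbourhoods: {list(missing)[:5]}")
    b_ob = obesity_fits.local.loc[ids, f"beta_{coefficient}"].astype(float)
    b_ow = overweight_fits.local.loc[ids, f"beta_{coefficient}"].astype(float)
    if significance_gate is not None:
        g_ob = obesity_fits.local.loc[ids, f"sig_{coefficient}"] >= significance_gate
        g_ow = overweight_fits.local.loc[ids, f"sig_{coefficient}"] >= significance_gate
        b_ob = b_ob.where(g_ob, 0.0)
        b_ow = b_ow.where(g_ow, 0.0)
    frame = pd.DataFrame(
        {
            "beta_ws_obese": b_ob.to_numpy(),
            "beta_ws_overweight": b_ow.to_numpy(),
            "total_children": table["total_children"].to_numpy(dtype=float),
        },
        index=ids,
    )
    return FlowSpec(frame=frame, tau=tau, significance_gate=significance_gate)


def goal_stocks(initial: pd.DataFrame, spec: FlowSpec, delta_walkscore: pd.Series) -> pd.DataFrame:
    """GWR-implied post-intervention goal stocks, fixed at intervention time.

    Per-1000 prevalence shifts convert to child counts via total/1000; goals
    are clamped at zero.
    """
    f = spec.frame.loc[initial.index]
    scale = f["total_children"] / 1000.0
    d = delta_walkscore.loc[initial.index]
    obese_goal = np.maximum(initial["obese"] + f["beta_ws_obese"] * d * scale, 0.0)
    ow_goal = np.maximum(initial["overweight"] + f["beta_ws_overweight"] * d * scale, 0.0)
    return pd.DataFrame({"obese_goal": obese_goal, "overweight_goal": ow_goal}, index=initial.index)


def step(
    state: pd.DataFrame, spec: FlowSpec, targets: pd.DataFrame, dt: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One explicit Euler step of the goal-seeking flows.

    ``state`` has columns healthy/overweight/obese plus ``backup_in`` (the
    cumulative net transfer received from the obese stock); ``targets`` the
    goal stocks. Flows are ``gap / tau`` in their own model's gap, clamped so
    no stock goes negative within the step; only adjacent transitions occur.
    Returns the new state and the instantaneous flows.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    tau = spec.tau
    obese = state["obese"].to_numpy(dtype=float)
    ow = state["overweight"].to_numpy(dtype=float)
    healthy = state["healthy"].to_numpy(dtype=float)
    backup = state["backup_in"].to_numpy(dtype=float)

    # obese <-> overweight, driven by the obesity model's gap
    flow_oo = (obese - targets["obese_goal"].to_numpy()) / tau
    # overweight <-> healthy, driven by the overweight model's gap on the
    # overweight stock net of backup inflow
    flow_oh = (ow - backup - targets["overweight_goal"].to_numpy()) / tau

    # clamp against source stocks (positive flow drains obese/overweight,
    # negative flow drains overweight/healthy)
    flow_oo = np.clip(flow_oo, -ow / dt, obese / dt)
    new_ow_after_oo = ow + flow_oo * dt
    flow_oh = np.clip(flow_oh, -healthy / dt, new_ow_after_oo / dt)
    n_clamped = int(np.sum((flow_oo == -ow / dt) & (ow > 0)) + np.sum((flow_oh == -healthy / dt) & (healthy > 0)))
    if n_clamped:
        logger.info("flow clamping engaged in %d neighbourhoods", n_clamped)

    new = pd.DataFrame(
        {
            "healthy": healthy + flow_oh * dt,
            "overweight": ow + (flow_oo - flow_oh) * dt,
            "obese": obese - flow_oo * dt,
            "backup_in": backup + flow_oo * dt,
        },
        index=state.index,
    )
    flows = pd.DataFrame(
        {"flow_obese_to_overweight": flow_oo, "flow_overweight_to_healthy": flow_oh},
        index=state.index,
    )
    return new, flows


def run_scenario(
    initial: pd.DataFrame, spec: FlowSpec, scenario: Scenario = BASE_SCENARIO
) -> Trajectory:
    """Simulate a scenario from start_year to end_year.

    ``initial`` is indexed by id with columns healthy/overweight/obese
    (child counts at the start year). The walkscore change applies at
    start_year, the goal stocks are fixed there, and the state advances by
    explicit Euler steps of ``dt``. The base scenario (zero change) keeps
    every stock constant — the equilibrium baseline.
    """
    unknown = [i for i in scenario.target_ids if i not in initial.index]
    if unknown:
        raise ValueError(f"scenario names unknown neighbourhoods: {unknown[:5]}")
    missing = initial.index.difference(spec.frame.index)
    if len(missing):
        raise ValueError(f"flow spec missing neighbourhoods: {list(missing)[:5]}")

    delta = scenario.delta_for(initial.index)
    goals = goal_stocks(initial, spec, delta)
    state = initial[["healthy", "overweight", "obese"]].astype(float).copy()
    state["backup_in"] = 0.0

    records = []
    year = float(scenario.start_year)
    zero_flows = pd.DataFrame(
        {"flow_obese_to_overweight": 0.0, "flow_overweight_to_healthy": 0.0}, index=state.index
    )

    def snap(state, flows, year):
        rec = state[["healthy", "overweight", "obese"]].copy()
        rec["flow_obese_to_overweight"] = flows["flow_obese_to_overweight"]
        rec["flow_overweight_to_healthy"] = flows["flow_overweight_to_healthy"]
        rec["year"] = year
        rec.index.name = "id"
        return rec.reset_index()

    n_steps = round((scenario.end_year - scenario.start_year) / scenario.dt)
    for k in range(n_steps):
        new, flows = step(state, spec, goals, scenario.dt)
        records.append(snap(state, flows, scenario.start_year + k * scenario.dt))
        state = new
    records.append(snap(state, zero_flows, float(scenario.end_year)))

    frame = pd.concat(records, ignore_index=True)
    return Trajectory(frame=frame, scenario=scenario, spec=spec, goals=goals)


def trajectory_report(trajectories: Trajectory | list[Trajectory], ids=None) -> pd.DataFrame:
    """Tidy long table (neighbourhood, scenario, year, stock, value) for plotting."""
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    frames = []
    for traj in trajectories:
        sub = traj.frame
        if ids is not None:
            unknown = [i for i in ids if i not in set(sub["id"])]
            if unknown:
                raise ValueError(f"unknown neighbourhood ids: {unknown[:5]}")
            sub = sub[sub["id"].isin(ids)]
        long = sub.melt(
            id_vars=["id", "year"],
            value_vars=list(STOCKS),
            var_name="stock",
            value_name="value",
        )
        long.insert(1, "scenario", traj.scenario.name)
        long = long.rename(columns={"id": "neighbourhood"})
        frames.append(long)
    return pd.concat(frames, ignore_index=True)
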