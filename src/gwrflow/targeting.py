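"""Selection of intervention neighbourhoods.

A neighbourhood is targeted when childhood obesity is high, walkability is
low, and the local walkscore coefficient is negative and significant at the
configured level — the places where a walkability intervention has the
greatest probability of success.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .gwr import GWRResults
from .preprocess import classify_walkability


@dataclass(frozen=True)
class TargetCriteria:
    """Rules a neighbourhood must pass to be targeted.

    significance_floor: minimum two-sided significance class (90/95/99) of
    the local coefficient. required_sign: 'negative', 'positive' or None.
    prevalence_rule: 'above_mean' (normalized obese above the city mean) or
    None to disable. walkability_rule: 'below_median_or_car_dependent' or
    None to disable. coefficient: which local coefficient the sign and
    significance rules inspect.
    """

    significance_floor: int = 95
    required_sign: str | None = "negative"
    prevalence_rule: str | None = "above_mean"
    walkability_rule: str | None = "below_median_or_car_dependent"
    coefficient: str = "walkscore"

    def __post_init__(self) -> None:
        if self.significance_floor not in (90, 95, 99):
            raise ValueError("significance_floor must be one of 90, 95, 99")
        if self.required_sign not in (None, "negative", "positive"):
            raise ValueError("required_sign must be 'negative', 'positive' or None")


@dataclass
class TargetSet:
    """Selected neighbourhoods with a snapshot of the evidence behind each."""

    ids: list
    snapshot: pd.DataFrame  # per-id: coefficient, t value, normalized obese, walkscore
    criteria: TargetCriteria

    def __len__(self) -> int:
        return len(self.ids)


def select_targets(
    fits: GWRResults, table: pd.DataFrame, criteria: TargetCriteria = TargetCriteria()
) -> TargetSet:
    """Apply the targeting rules row by row; the empty set is a valid outcome."""
    name = criteria.coefficient
    for col in (f"beta_{name}", f"t_{name}", f"sig_{name}"):
        if col not in fits.local.columns:
            raise ValueError(f"local fits lack column {col!r}; criteria reference a missing coefficient")
    for col in ("id", "normalized_obese", "walkscore"):
        if col not in table.columns:
            raise ValueError(f"table lacks required column {col!r}")

    tab = table.set_index("id")
    shared = [i for i in fits.local.index if i in tab.index]
    if len(shared) != len(fits.local):
        raise ValueError("fits and table do not share neighbourhood ids")

    beta = fits.local[f"beta_{name}"]
    tval = fits.local[f"t_{name}"]
    sig = fits.local[f"sig_{name}"]

    mask = pd.Series(True, index=fits.local.index)
    mask &= sig >= criteria.significance_floor
    if criteria.required_sign == "negative":
        mask &= beta < 0
    elif criteria.required_sign == "positive":
        mask &= beta > 0
    if criteria.prevalence_rule == "above_mean":
        city_mean = tab["normalized_obese"].mean()
        mask &= tab.loc[fits.local.index, "normalized_obese"] > city_mean
    elif criteria.prevalence_rule is not None:
        raise ValueError(f"unknown prevalence_rule {criteria.prevalence_rule!r}")
    if criteria.walkability_rule == "below_median_or_car_dependent":
        ws = tab.loc[fits.local.index, "walkscore"]
        median = tab["walkscore"].median()
        car = ws.map(lambda s: classify_walkability(s) == "car_dependent")
        mask &= (ws < median) | car
    elif criteria.walkability_rule is not None:
        raise ValueError(f"unknown walkability_rule {criteria.walkability_rule!r}")

    ids = list(fits.local.index[mask])
    snapshot = pd.DataFrame(
        {
            f"beta_{name}": beta[mask],
            f"t_{name}": tval[mask],
            f"sig_{name}": sig[mask],
            "normalized_obese": tab.loc[ids, "normalized_obese"].to_numpy(),
            "walkscore": tab.loc[ids, "walkscore"].to_numpy(),
        },
        index=pd.Index(ids, name="id"),
    )
    return TargetSet(ids=ids, snapshot=snapshot, criteria=criteria)
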