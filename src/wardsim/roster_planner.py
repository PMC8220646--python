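"""Baseline rosters from the 20-day establishment sample.

Three plans differ only in the statistic applied to the sampled daily
totals: the low-baseline "flexible" plan targets 80% of the mean, the
"standard" plan the mean, and the high-baseline "resilient" plan the 90th
percentile (nearest-rank).  The statistic is taken on daily totals; the
role and shift splits are applied afterwards, and headcounts are rounded to
the nearest half person (ties up) so that rosters share the half-shift
deployment currency used for floats and temporary hires.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _rng
from .constants import ROLES, SHIFTS
from .demand_model import CareLevelMultipliers, DemandSample, establishment_sample
from .errors import ConfigurationError, InputError

__all__ = [
    "PlanKind",
    "EstablishmentPlan",
    "plan_baseline_daily_hours",
    "shift_roster",
    "establishment_wte",
    "build_establishment",
    "round_half",
]


class PlanKind(str, enum.Enum):
    FLEXIBLE = "flexible"  # 0.8 x sample mean
    STANDARD = "standard"  # sample mean
    RESILIENT = "resilient"  # 90th percentile (nearest rank)

    @property
    def target_statistic(self) -> str:
        return {
            PlanKind.FLEXIBLE: "0.8 x mean",
            PlanKind.STANDARD: "mean",
            PlanKind.RESILIENT: "90th percentile",
        }[self]


@dataclass
class EstablishmentPlan:
    """Baseline rostered headcounts per unit x shift x role for one plan.

    headcount has shape (n_units, n_shifts, n_roles) in half-person units;
    baseline hours are always headcount x shift_length.
    """

    plan_kind: PlanKind
    unit_ids: list[str]
    headcount: np.ndarray
    shift_length_hours: float

    def __post_init__(self) -> None:
        if self.shift_length_hours <= 0:
            raise ConfigurationError("shift_length_hours must be positive")
        hc = np.asarray(self.headcount, dtype=float)
        if np.any(hc < 0):
            raise ConfigurationError("headcounts must be non-negative")
        if not np.allclose(hc * 2, np.round(hc * 2)):
            raise ConfigurationError("headcounts must be multiples of 0.5")
        self.headcount = hc

    @property
    def baseline_hours(self) -> np.ndarray:
        return self.headcount * self.shift_length_hours

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, uid in enumerate(self.unit_ids):
            for s, shift in enumerate(SHIFTS):
                for r, role in enumerate(ROLES):
                    rows.append(
                        {
                            "plan": self.plan_kind.value,
                            "unit_id": uid,
                            "shift": shift,
                            "role": role,
                            "headcount": self.headcount[i, s, r],
                            "hours": self.headcount[i, s, r] * self.shift_length_hours,
                        }
                    )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, shift_length_hours: float) -> "EstablishmentPlan":
        plan = PlanKind(frame["plan"].iloc[0])
        unit_ids = list(dict.fromkeys(frame["unit_id"]))
        hc = np.zeros((len(unit_ids), len(SHIFTS), len(ROLES)))
        uix = {u: i for i, u in enumerate(unit_ids)}
        for row in frame.itertuples():
            hc[uix[row.unit_id], SHIFTS.index(row.shift), ROLES.index(row.role)] = row.headcount
        return cls(plan, unit_ids, hc, shift_length_hours)


def round_half(x: float) -> float:
    """Round to the nearest 0.5, ties rounding up."""
    return math.floor(2.0 * x + 0.5) / 2.0


def _nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    """q-th percentile by the nearest-rank method: ceil(q*n)-th order stat."""
    v = np.sort(np.asarray(values, dtype=float))
    rank = math.ceil(q * len(v))
    return float(v[max(rank, 1) - 1])


def plan_baseline_daily_hours(sample: DemandSample, plan_kind: PlanKind) -> dict[str, float]:
    """Target daily hours per role under a plan.

    The plan statistic is computed on the 20 daily totals; the RN/NA split
    (the sample's aggregate RN fraction) is applied afterwards.
    """
    totals = np.asarray(sample.daily_total_hours, dtype=float)
    if totals.size == 0:
        raise InputError("demand sample is empty")
    plan_kind = PlanKind(plan_kind)
    if plan_kind is PlanKind.FLEXIBLE:
        target = 0.8 * float(totals.mean())
    elif plan_kind is PlanKind.STANDARD:
        target = float(totals.mean())
    else:
        target = _nearest_rank_percentile(totals, 0.9)
    rn = sample.rn_fraction
    return {"RN": target * rn, "NA": target * (1.0 - rn), "total": target}


def shift_roster(
    daily_hours_by_role: dict[str, float],
    shift_weights,
    shift_length_hours: float,
    unit_id: str = "",
    plan_kind: PlanKind = PlanKind.STANDARD,
) -> np.ndarray:
    """Distribute target daily hours over shifts and round to half people.

    Returns headcounts with shape (n_shifts, n_roles).  Per-shift hours are
    daily hours x shift weight; headcount = hours / shift length rounded to
    the nearest 0.5 with ties up.
    """
    if shift_length_hours <= 0:
        raise ConfigurationError("shift length must be positive")
    weights = np.asarray(shift_weights, dtype=float)
    hc = np.zeros((len(SHIFTS), len(ROLES)))
    for r, role in enumerate(ROLES):
        daily = float(daily_hours_by_role[role])
        if daily < 0:
            raise InputError("daily hours must be non-negative")
        for s in range(len(SHIFTS)):
            hc[s, r] = round_half(daily * weights[s] / shift_length_hours)
    return hc


def establishment_wte(
    daily_hours: float, uplift_fraction: float, weekly_contracted_hours: float = 37.5
) -> float:
    """Whole-time-equivalent establishment implied by daily worked hours.

    WTE = daily_hours x 7 / (contracted weekly hours x (1 - uplift)); the
    uplift covers annual leave, education and other time away, so it exists
    only in this reporting conversion, never in bedside demand.
    """
    if not 0.0 <= uplift_fraction < 1.0:
        raise ConfigurationError("uplift_fraction must lie in [0, 1)")
    if weekly_contracted_hours <= 0:
        raise ConfigurationError("weekly contracted hours must be positive")
    return daily_hours * 7.0 / (weekly_contracted_hours * (1.0 - uplift_fraction))


def build_establishment(
    units,
    plan_kind: PlanKind,
    master_seed: int,
    n_days: int = 20,
    shift_length_hours: float = 8.0,
    multipliers: CareLevelMultipliers | None = None,
) -> EstablishmentPlan:
    """Roster a whole hospital under one plan from per-unit 20-day samples.

    All plans share the same establishment sample for a given master seed,
    so plan orderings (flexible <= standard, and resilient >= standard when
    the sampled 90th percentile is at least the mean) hold unit by unit.
    """
    plan_kind = PlanKind(plan_kind)
    hc = np.zeros((len(units), len(SHIFTS), len(ROLES)))
    for i, unit in enumerate(units):
        rng = _rng.substream(master_seed, _rng.ESTABLISHMENT, i)
        sample = establishment_sample(unit, n_days, rng=rng, multipliers=multipliers)
        targets = plan_baseline_daily_hours(sample, plan_kind)
        hc[i] = shift_roster(
            targets, unit.shift_weights, shift_length_hours, unit.unit_id, plan_kind
        )
    return EstablishmentPlan(
        plan_kind, [u.unit_id for u in units], hc, shift_length_hours
    )
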