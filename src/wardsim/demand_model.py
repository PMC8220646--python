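"""Required nursing hours per shift from a patient mix.

Converts acuity/dependency classification counts into care hours (hours per
patient per day by care level, plus 24 h per one-to-one specialing patient),
splits the daily total across shifts by each unit's shift weights and across
roles by its RN/assistant skill mix, and provides the independent daily
draws used both for the 20-day establishment-setting sample and for the
simulation period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _rng
from .constants import CARE_LEVELS, DEFAULT_CARE_HOURS, ROLES, SHIFTS, SPECIALING_HOURS
from .errors import ConfigurationError, InputError
from .synthetic_hospital import PatientMix, UnitProfile, sample_patient_mix_block

__all__ = [
    "CareLevelMultipliers",
    "DemandRealisation",
    "DemandSample",
    "DemandArrays",
    "required_care_hours",
    "draw_shift_demand",
    "establishment_sample",
    "simulate_demand",
]


@dataclass(frozen=True)
class CareLevelMultipliers:
    """Care hours per patient per day for each acuity/dependency level."""

    hours: dict = field(default_factory=lambda: dict(DEFAULT_CARE_HOURS))
    specialing_hours: float = SPECIALING_HOURS

    def __post_init__(self) -> None:
        missing = [lv for lv in CARE_LEVELS if lv not in self.hours]
        if missing:
            raise ConfigurationError(f"care-level multipliers missing levels: {missing}")
        if any(v <= 0 for v in self.hours.values()) or self.specialing_hours <= 0:
            raise ConfigurationError("all care-hour multipliers must be positive")
        if self.hours[CARE_LEVELS[-1]] < self.hours[CARE_LEVELS[0]]:
            raise ConfigurationError(
                "highest care level must require at least as many hours as the lowest"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.hours[lv] for lv in CARE_LEVELS], dtype=float)


@dataclass(frozen=True)
class DemandRealisation:
    """Required care hours for one unit-shift."""

    unit_id: str
    day: int
    shift: str
    required_rn_hours: float
    required_na_hours: float
    census: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.required_rn_hours) and np.isfinite(self.required_na_hours)):
            raise InputError("required hours must be finite")
        if self.required_rn_hours < 0 or self.required_na_hours < 0 or self.census < 0:
            raise InputError("required hours and census must be non-negative")

    @property
    def required_total_hours(self) -> float:
        return self.required_rn_hours + self.required_na_hours


@dataclass
class DemandSample:
    """The n-day (default 20) establishment-setting sample for one unit."""

    unit_id: str
    daily_total_hours: np.ndarray  # (n_days,)
    per_shift_hours: np.ndarray  # (n_days, n_shifts)
    per_role_hours: np.ndarray  # (n_days, n_roles)

    def __post_init__(self) -> None:
        if len(self.daily_total_hours) < 1:
            raise InputError("demand sample must contain at least one day")
        if np.any(np.asarray(self.daily_total_hours) < 0):
            raise InputError("daily totals must be non-negative")

    @property
    def n_days(self) -> int:
        return len(self.daily_total_hours)

    @property
    def rn_fraction(self) -> float:
        total = float(np.sum(self.daily_total_hours))
        if total == 0:
            return 0.5
        return float(np.sum(self.per_role_hours[:, 0]) / total)


def required_care_hours(
    patient_mix: PatientMix,
    multipliers: CareLevelMultipliers,
    rn_skill_mix: float,
    shift_weights,
    unit_id: str = "",
    day: int = 0,
) -> list[DemandRealisation]:
    """SNCT-style conversion of a patient mix into per-shift demand.

    Daily total = sum(level count x level hours) + specialing x 24 h, split
    across shifts by ``shift_weights`` and across roles by ``rn_skill_mix``.
    """
    counts = np.asarray(patient_mix.level_counts, dtype=float)
    if np.any(counts < 0) or patient_mix.specialing < 0:
        raise InputError("patient-mix counts must be non-negative")
    weights = np.asarray(shift_weights, dtype=float)
    total = float(counts @ multipliers.as_array()) + (
        patient_mix.specialing * multipliers.specialing_hours
    )
    out = []
    for s, shift in enumerate(SHIFTS):
        shift_hours = total * weights[s]
        rn = shift_hours * rn_skill_mix
        out.append(
            DemandRealisation(
                unit_id=unit_id,
                day=day,
                shift=shift,
                required_rn_hours=rn,
                required_na_hours=shift_hours - rn,
                census=patient_mix.census,
            )
        )
    return out


def draw_shift_demand(
    unit: UnitProfile,
    day: int,
    shift: str,
    rng: np.random.Generator,
    multipliers: CareLevelMultipliers | None = None,
) -> DemandRealisation:
    """One independent demand draw for (unit, day, shift).

    Composes a patient-mix draw with the care-hours conversion; successive
    calls on one stream are serially independent (no day-to-day carryover).
    """
    multipliers = multipliers or CareLevelMultipliers()
    census, counts, specialing = sample_patient_mix_block(unit, 1, rng)
    mix = PatientMix(int(census[0]), counts[0], int(specialing[0]))
    shifts = required_care_hours(
        mix, multipliers, unit.rn_skill_mix, unit.shift_weights, unit.unit_id, day
    )
    return shifts[SHIFTS.index(shift)]


def _daily_draws(
    unit: UnitProfile,
    n_days: int,
    rng: np.random.Generator,
    multipliers: CareLevelMultipliers,
) -> tuple[np.ndarray, np.ndarray]:
    """(daily_total_hours, census) for n_days independent draws."""
    census, counts, specialing = sample_patient_mix_block(unit, n_days, rng)
    totals = counts @ multipliers.as_array() + specialing * multipliers.specialing_hours
    return totals, census


def establishment_sample(
    unit: UnitProfile,
    n_days: int = 20,
    rng: np.random.Generator | None = None,
    master_seed: int | None = None,
    unit_index: int = 0,
    multipliers: CareLevelMultipliers | None = None,
) -> DemandSample:
    """The n-day demand sample used to set baseline rosters.

    Drawn from a sub-stream disjoint from simulation-period demand so that
    establishment setting and simulation never share randomness.
    """
    if n_days < 1:
        raise InputError("n_days must be >= 1")
    multipliers = multipliers or CareLevelMultipliers()
    if rng is None:
        if master_seed is None:
            raise InputError("provide either rng or master_seed")
        rng = _rng.substream(master_seed, _rng.ESTABLISHMENT, unit_index)
    totals, _ = _daily_draws(unit, n_days, rng, multipliers)
    weights = np.asarray(unit.shift_weights, dtype=float)
    per_shift = totals[:, None] * weights[None, :]
    per_role = np.stack(
        [totals * unit.rn_skill_mix, totals * (1.0 - unit.rn_skill_mix)], axis=1
    )
    return DemandSample(unit.unit_id, totals, per_shift, per_role)


@dataclass
class DemandArrays:
    """Dense simulation-period demand for a set of units.

    required has shape (n_units, n_days, n_shifts, n_roles); census
    (n_units, n_days).  Patient days are counted once per unit-day.
    """

    unit_ids: list[str]
    required: np.ndarray
    census: np.ndarray

    @property
    def daily_total(self) -> np.ndarray:
        return self.required.sum(axis=(2, 3))

    def to_frame(self) -> pd.DataFrame:
        n_units, n_days, n_shifts, n_roles = self.required.shape
        idx = pd.MultiIndex.from_product(
            [self.unit_ids, range(n_days), SHIFTS, ROLES],
            names=["unit_id", "day", "shift", "role"],
        )
        frame = pd.DataFrame({"required_hours": self.required.ravel()}, index=idx).reset_index()
        census = pd.DataFrame(
            {
                "unit_id": np.repeat(self.unit_ids, n_days),
                "day": np.tile(np.arange(n_days), n_units),
                "census": self.census.ravel(),
            }
        )
        return frame.merge(census, on=["unit_id", "day"])


def simulate_demand(
    units,
    n_days: int,
    master_seed: int,
    multipliers: CareLevelMultipliers | None = None,
) -> DemandArrays:
    """Independent daily demand draws for every unit over the horizon.

    Each unit has its own demand sub-stream keyed by position, so demand is
    identical across staffing plans and availability scenarios that share a
    master seed (common random numbers).
    """
    multipliers = multipliers or CareLevelMultipliers()
    n_units = len(units)
    required = np.zeros((n_units, n_days, len(SHIFTS), len(ROLES)))
    census = np.zeros((n_units, n_days), dtype=np.int64)
    for i, unit in enumerate(units):
        rng = _rng.substream(master_seed, _rng.DEMAND, i)
        totals, cens = _daily_draws(unit, n_days, rng, multipliers)
        weights = np.asarray(unit.shift_weights, dtype=float)
        per_shift = totals[:, None] * weights[None, :]
        required[i, :, :, 0] = per_shift * unit.rn_skill_mix
        required[i, :, :, 1] = per_shift * (1.0 - unit.rn_skill_mix)
        census[i] = cens
    return DemandArrays([u.unit_id for u in units], required, census)
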