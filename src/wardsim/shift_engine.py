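"""Shift-by-shift staffing simulation.

For every unit-shift the engine draws demand and short-notice sickness
absence, classifies the unit as understaffed / adequate / overstaffed
against a relative tolerance (default 15%, the trigger threshold), and then
attempts to close triggered shortfalls: first by floating staff from
overstaffed units in the same specialty group, then by requesting bank
staff, then agency staff, all in half-shift blocks with role-matched
substitution (RNs replace RNs, assistants replace assistants).

Randomness is organised as named sub-streams of one master seed so that
demand, absence and fulfilment draws are shared across staffing plans and
availability scenarios (common random numbers): scenario comparisons then
differ only through the fill rules, not through sampling noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import _rng
from .constants import ROLES, SHIFTS
from .demand_model import CareLevelMultipliers, DemandArrays, simulate_demand
from .errors import ConfigurationError, InputError, LogicError
from .roster_planner import EstablishmentPlan
from .synthetic_hospital import AvailabilityScenario, HospitalProfile

__all__ = [
    "SimulatorConfig",
    "SimulationResult",
    "draw_absences",
    "classify_status",
    "fill_target",
    "float_staff",
    "hire_temporary",
    "resolve_shift",
    "run_shift",
    "run_scenario",
]

STATUS_ADEQUATE, STATUS_UNDERSTAFFED, STATUS_OVERSTAFFED = 0, 1, 2
STATUS_NAMES = ("adequate", "understaffed", "overstaffed")

_EPS = 1e-9


@dataclass
class SimulatorConfig:
    """Simulation parameters (trigger tolerance, absence, horizon, seeding)."""

    tolerance: float = 0.15
    absence_rates: dict = field(default_factory=lambda: {"RN": 0.03, "NA": 0.04})
    allow_floating: bool = True
    days: int = 365
    deployment_granularity: str = "half"  # half or full shift blocks
    shift_length_hours: float = 8.0
    master_seed: int = 0
    crn: bool = True  # common random numbers across plans/availabilities
    max_headcount: int = 32  # per unit-shift-role cap for the absence slot table
    multipliers: CareLevelMultipliers = field(default_factory=CareLevelMultipliers)

    def __post_init__(self) -> None:
        if not 0.0 <= self.tolerance < 1.0:
            raise ConfigurationError("tolerance must lie in [0, 1)")
        for role, rate in self.absence_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"absence rate for {role} outside [0, 1]")
        if self.days < 1:
            raise ConfigurationError("days must be >= 1")
        if self.deployment_granularity not in ("half", "full"):
            raise ConfigurationError("deployment_granularity must be 'half' or 'full'")
        if self.shift_length_hours <= 0:
            raise ConfigurationError("shift_length_hours must be positive")

    @property
    def block_hours(self) -> float:
        scale = 0.5 if self.deployment_granularity == "half" else 1.0
        return self.shift_length_hours * scale

    def rates_array(self) -> np.ndarray:
        return np.array([self.absence_rates[r] for r in ROLES], dtype=float)


# ---------------------------------------------------------------------------
# elemental operations


def draw_absences(headcount: float, rate: float, rng: np.random.Generator) -> float:
    """Absent headcount (in half-person units) for one unit-shift-role.

    Binomial over the 2 x headcount half-person slots, so the expectation is
    headcount x rate while fractional rosters still lose whole half-people.
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError("absence rate must lie in [0, 1]")
    if headcount < 0 or abs(headcount * 2 - round(headcount * 2)) > _EPS:
        raise InputError("headcount must be a non-negative multiple of 0.5")
    slots = int(round(headcount * 2))
    return float(rng.binomial(slots, rate)) * 0.5


def classify_status(
    required_hours: float, available_hours: float, tolerance: float
) -> tuple[str, float, float]:
    """Status plus (shortfall, surplus) hours for one unit-shift.

    Understaffed iff the relative shortfall exceeds the tolerance (this is
    what triggers fill attempts); overstaffed iff available exceeds
    required; adequate otherwise.  Zero demand is never understaffed.
    """
    if required_hours < 0 or available_hours < 0:
        raise InputError("hours must be non-negative")
    surplus = max(available_hours - required_hours, 0.0)
    shortfall = max(required_hours - available_hours, 0.0)
    if required_hours > 0 and shortfall / required_hours > tolerance + _EPS:
        return STATUS_NAMES[STATUS_UNDERSTAFFED], shortfall, 0.0
    if surplus > _EPS:
        return STATUS_NAMES[STATUS_OVERSTAFFED], 0.0, surplus
    return STATUS_NAMES[STATUS_ADEQUATE], shortfall, 0.0


def _classify_codes(required: np.ndarray, available: np.ndarray, tolerance: float) -> np.ndarray:
    out = np.full(required.shape, STATUS_ADEQUATE, dtype=np.int8)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(required > 0, (required - available) / np.where(required > 0, required, 1.0), 0.0)
    out[(required > 0) & (frac > tolerance + _EPS)] = STATUS_UNDERSTAFFED
    out[available - required > _EPS] = STATUS_OVERSTAFFED
    return out


def fill_target(required_hours: float, tolerance: float) -> float:
    """Hours a triggered unit is filled back up to: the tolerance boundary.

    The tolerance defines the band of adequate staffing, so fill actions
    return a unit into that band ((1 - tolerance) x required) rather than
    chasing the full requirement; with whole-block deployments the final
    block may overshoot the boundary.
    """
    return (1.0 - tolerance) * required_hours


def float_staff(
    required: np.ndarray,
    available: np.ndarray,
    tolerance: float,
    block_hours: float,
) -> tuple[list[tuple[int, int, float]], np.ndarray, np.ndarray]:
    """Float staff within one specialty group for one shift and one role.

    Triggered units (relative shortfall > tolerance) receive whole blocks
    from units with true surplus (available > required), recipients in
    descending shortfall order, donors in descending current surplus order,
    ties broken by position.  A donor never drops below its own requirement;
    a recipient stops once its available hours are back inside the
    tolerance band (the final block may overshoot the boundary).  Returns
    (transfers, floated_in, floated_out) with transfers as
    (donor, recipient, hours).
    """
    req = np.asarray(required, dtype=float)
    avail = np.asarray(available, dtype=float).copy()
    n = len(req)
    floated_in = np.zeros(n)
    floated_out = np.zeros(n)
    transfers: list[tuple[int, int, float]] = []

    codes = _classify_codes(req, avail, tolerance)
    recipients = [i for i in range(n) if codes[i] == STATUS_UNDERSTAFFED]
    recipients.sort(key=lambda i: (-(req[i] - avail[i]), i))

    def donor_blocks(i: int) -> int:
        return int(math.floor((avail[i] - req[i]) / block_hours + _EPS))

    for rec in recipients:
        target = fill_target(req[rec], tolerance)
        while avail[rec] < target - _EPS:
            donors = [(donor_blocks(i), i) for i in range(n) if i != rec and donor_blocks(i) > 0]
            if not donors:
                break
            donors.sort(key=lambda t: (-t[0], t[1]))
            blocks_avail, donor = donors[0]
            need = int(math.ceil((target - avail[rec]) / block_hours - _EPS))
            give = min(need, blocks_avail)
            hours = give * block_hours
            avail[donor] -= hours
            avail[rec] += hours
            floated_out[donor] += hours
            floated_in[rec] += hours
            transfers.append((donor, rec, hours))
    return transfers, floated_in, floated_out


def hire_temporary(
    shortfall_hours: float,
    p_bank: float,
    p_agency: float,
    u_bank: np.ndarray,
    u_agency: np.ndarray,
    block_hours: float,
) -> tuple[float, float]:
    """Bank-then-agency hires for one triggered unit-shift-role.

    The request is the minimum number of half-shift blocks covering the
    residual shortfall; each block is independently fulfilled by the bank
    with probability ``p_bank``, and blocks the bank declines are offered
    once to the agency with probability ``p_agency``.  Returns
    (bank_hours, agency_hours); hires never exceed the request.
    """
    if shortfall_hours <= _EPS:
        return 0.0, 0.0
    k = int(math.ceil(shortfall_hours / block_hours - _EPS))
    if len(u_bank) < k or len(u_agency) < k:
        raise LogicError("insufficient fulfilment draws for the requested blocks")
    bank_fill = u_bank[:k] < p_bank
    agency_fill = (~bank_fill) & (u_agency[:k] < p_agency)
    return float(bank_fill.sum()) * block_hours, float(agency_fill.sum()) * block_hours


UniformProvider = Callable[[int, int, int], np.ndarray]  # (unit, role, n) -> uniforms


def resolve_shift(
    required: np.ndarray,
    available: np.ndarray,
    group_of: np.ndarray,
    tolerance: float,
    block_hours: float,
    p_bank: np.ndarray,
    p_agency: np.ndarray,
    u_bank: UniformProvider,
    u_agency: UniformProvider,
    allow_floating: bool = True,
) -> dict[str, np.ndarray]:
    """Deterministically resolve one shift given demand, supply and draws.

    ``required``/``available`` have shape (n_units, n_roles); ``p_bank`` and
    ``p_agency`` are per-role fulfilment probabilities; ``u_bank``/
    ``u_agency`` supply the per-block uniforms.  Fill actions target only
    units whose pre-fill shortfall exceeds the tolerance and fill them back
    to the tolerance boundary (see :func:`fill_target`).
    """
    required = np.asarray(required, dtype=float)
    avail = np.asarray(available, dtype=float).copy()
    n, n_roles = required.shape
    floated_in = np.zeros((n, n_roles))
    floated_out = np.zeros((n, n_roles))
    bank = np.zeros((n, n_roles))
    agency = np.zeros((n, n_roles))
    status_pre = _classify_codes(required, avail, tolerance)

    for r in range(n_roles):
        triggered = status_pre[:, r] == STATUS_UNDERSTAFFED
        if allow_floating:
            for g in np.unique(group_of):
                members = np.where(group_of == g)[0]
                if len(members) < 2 or not triggered[members].any():
                    continue
                _, fin, fout = float_staff(
                    required[members, r], avail[members, r], tolerance, block_hours
                )
                floated_in[members, r] += fin
                floated_out[members, r] += fout
                avail[members, r] += fin - fout
        for i in np.where(triggered)[0]:
            shortfall = fill_target(required[i, r], tolerance) - avail[i, r]
            if shortfall <= _EPS:
                continue
            k = int(math.ceil(shortfall / block_hours - _EPS))
            b_hours, a_hours = hire_temporary(
                shortfall, p_bank[r], p_agency[r], u_bank(i, r, k), u_agency(i, r, k), block_hours
            )
            bank[i, r] += b_hours
            agency[i, r] += a_hours
            avail[i, r] += b_hours + a_hours

    status_post = _classify_codes(required, avail, tolerance)
    return {
        "floated_in": floated_in,
        "floated_out": floated_out,
        "bank": bank,
        "agency": agency,
        "achieved": avail,
        "status_pre": status_pre,
        "status_post": status_post,
    }


# ---------------------------------------------------------------------------
# scenario runs


@dataclass
class SimulationResult:
    """The full ledger of one scenario run.

    All hour arrays have shape (n_units, n_days, n_shifts, n_roles);
    ``census`` is (n_units, n_days) and patient days are counted once per
    unit-day.
    """

    plan_kind: str
    availability_name: str
    unit_ids: list[str]
    specialty_groups: list[str]
    seed: int
    shift_length_hours: float
    census: np.ndarray
    required: np.ndarray
    rostered: np.ndarray
    absent: np.ndarray
    floated_in: np.ndarray
    floated_out: np.ndarray
    bank: np.ndarray
    agency: np.ndarray
    status_pre: np.ndarray
    status_post: np.ndarray

    @property
    def achieved(self) -> np.ndarray:
        return (
            self.rostered
            - self.absent
            - self.floated_out
            + self.floated_in
            + self.bank
            + self.agency
        )

    @property
    def patient_days(self) -> float:
        return float(self.census.sum())

    def conservation_residual(self) -> float:
        """Max |sum achieved - sum(rostered - absent) - bank - agency| per shift-role."""
        lhs = self.achieved.sum(axis=0)
        rhs = (self.rostered - self.absent + self.bank + self.agency).sum(axis=0)
        return float(np.abs(lhs - rhs).max())

    def float_imbalance(self) -> float:
        """Max |net float hours| across units per shift-role (should be 0)."""
        net = (self.floated_in - self.floated_out).sum(axis=0)
        return float(np.abs(net).max())

    def unit_day_achieved(self) -> np.ndarray:
        """(n_units, n_days) achieved hours summed over shifts and roles."""
        return self.achieved.sum(axis=(2, 3))

    def unit_day_temporary(self) -> np.ndarray:
        return (self.bank + self.agency).sum(axis=(2, 3))

    def hppd(self, role: str | None = None) -> np.ndarray:
        """(n_units, n_days) achieved hours per patient day; NaN when census 0."""
        if role is None:
            hours = self.unit_day_achieved()
        else:
            hours = self.achieved[:, :, :, ROLES.index(role)].sum(axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.census > 0, hours / np.where(self.census > 0, self.census, 1), np.nan)

    def mean_hppd(self, role: str | None = None) -> float:
        """Hours per patient day over the whole run (total hours / patient days)."""
        if role is None:
            hours = self.unit_day_achieved()
        else:
            hours = self.achieved[:, :, :, ROLES.index(role)].sum(axis=2)
        return float(hours.sum() / self.census.sum())

    def hours_by_cost_cell(self) -> pd.DataFrame:
        """Worked hours aggregated by (role, source, shift, daytype).

        Substantive worked hours are rostered - absent: floating relocates
        staff without changing the hours worked or paid, so float columns
        net out of the pay bill.
        """
        n_units, n_days = self.census.shape
        weekend = (np.arange(n_days) % 7) >= 5
        rows = []
        substantive = self.rostered - self.absent
        for r, role in enumerate(ROLES):
            for s, shift in enumerate(SHIFTS):
                for daytype, mask in (("weekday", ~weekend), ("weekend", weekend)):
                    for source, arr in (
                        ("substantive", substantive),
                        ("bank", self.bank),
                        ("agency", self.agency),
                    ):
                        rows.append(
                            {
                                "role": role,
                                "source": source,
                                "shift": shift,
                                "daytype": daytype,
                                "hours": float(arr[:, mask, s, r].sum()),
                            }
                        )
        return pd.DataFrame(rows)

    def unit_day_table(self) -> pd.DataFrame:
        n_units, n_days = self.census.shape
        achieved = self.achieved
        frame = pd.DataFrame(
            {
                "unit_id": np.repeat(self.unit_ids, n_days),
                "day": np.tile(np.arange(n_days), n_units),
                "census": self.census.ravel(),
                "required_hours": self.required.sum(axis=(2, 3)).ravel(),
                "achieved_hours": achieved.sum(axis=(2, 3)).ravel(),
                "achieved_rn_hours": achieved[:, :, :, 0].sum(axis=2).ravel(),
                "achieved_na_hours": achieved[:, :, :, 1].sum(axis=2).ravel(),
                "temporary_hours": (self.bank + self.agency).sum(axis=(2, 3)).ravel(),
            }
        )
        return frame

    def to_frame(self) -> pd.DataFrame:
        """Long ledger: one row per unit x day x shift x role."""
        n_units, n_days, n_shifts, n_roles = self.required.shape
        idx = pd.MultiIndex.from_product(
            [self.unit_ids, range(n_days), SHIFTS, ROLES],
            names=["unit_id", "day", "shift", "role"],
        )
        cols = {
            "required_hours": self.required,
            "rostered_hours": self.rostered,
            "absent_hours": self.absent,
            "floated_out_hours": self.floated_out,
            "floated_in_hours": self.floated_in,
            "bank_hours": self.bank,
            "agency_hours": self.agency,
            "achieved_hours": self.achieved,
        }
        frame = pd.DataFrame({k: v.ravel() for k, v in cols.items()}, index=idx).reset_index()
        frame["status_pre"] = np.asarray(STATUS_NAMES)[self.status_pre.ravel()]
        frame["status_post"] = np.asarray(STATUS_NAMES)[self.status_post.ravel()]
        return frame


def _absence_counts(
    units: Sequence,
    headcount: np.ndarray,
    config: SimulatorConfig,
    rng_fallback: np.random.Generator | None,
) -> np.ndarray:
    """Absent half-person counts, shape (n_units, days, n_shifts, n_roles).

    Under common random numbers each unit owns a fixed table of per-slot
    uniforms, so plans with larger rosters reuse the smaller plan's slots
    and add more: absence can then only grow with the roster, which is what
    makes plan comparisons noise-free.
    """
    n = len(units)
    days = config.days
    rates = config.rates_array()
    slot_cap = 2 * config.max_headcount
    slots = np.rint(headcount * 2).astype(int)  # (n, shifts, roles)
    if slots.max(initial=0) > slot_cap:
        raise ConfigurationError(
            "a rostered headcount exceeds max_headcount; raise SimulatorConfig.max_headcount"
        )
    counts = np.zeros((n, days, len(SHIFTS), len(ROLES)), dtype=np.int32)
    for i in range(n):
        if config.crn:
            rng = _rng.substream(config.master_seed, _rng.ABSENCE, i)
            u = rng.random((days, len(SHIFTS), len(ROLES), slot_cap))
            cum = np.cumsum(u < rates[None, None, :, None], axis=-1)
            for s in range(len(SHIFTS)):
                for r in range(len(ROLES)):
                    k = slots[i, s, r]
                    if k > 0:
                        counts[i, :, s, r] = cum[:, s, r, k - 1]
        else:
            for s in range(len(SHIFTS)):
                for r in range(len(ROLES)):
                    counts[i, :, s, r] = rng_fallback.binomial(slots[i, s, r], rates[r], size=days)
    return counts


def run_scenario(
    hospital: HospitalProfile | Sequence,
    plan: EstablishmentPlan,
    availability: AvailabilityScenario,
    config: SimulatorConfig,
    demand: DemandArrays | None = None,
) -> SimulationResult:
    """Simulate one (plan, availability) scenario over the whole horizon.

    ``demand`` may be passed in to share one set of demand draws across
    scenarios; by default it is derived from the master seed and is
    identical for every plan and availability anyway (common random
    numbers).
    """
    units = hospital.units if isinstance(hospital, HospitalProfile) else list(hospital)
    if plan.unit_ids != [u.unit_id for u in units]:
        raise InputError("establishment plan does not cover these units in order")
    n = len(units)
    days = config.days
    if demand is None:
        demand = simulate_demand(units, days, config.master_seed, config.multipliers)
    required = demand.required
    if required.shape[1] != days:
        raise InputError("demand horizon does not match config.days")

    group_names = [u.specialty_group for u in units]
    _, group_of = np.unique(group_names, return_inverse=True)

    rostered = np.broadcast_to(
        plan.baseline_hours[:, None, :, :], required.shape
    ).copy()
    fallback = None if config.crn else _rng.substream(config.master_seed, _rng.ABSENCE)
    absent_halves = _absence_counts(units, plan.headcount, config, fallback)
    absent = absent_halves * (0.5 * config.shift_length_hours)

    lookup = availability.as_lookup()
    p_bank_tab, p_agency_tab = lookup["bank"], lookup["agency"]
    block = config.block_hours

    floated_in = np.zeros_like(required)
    floated_out = np.zeros_like(required)
    bank = np.zeros_like(required)
    agency = np.zeros_like(required)
    status_pre = np.zeros(required.shape, dtype=np.int8)
    status_post = np.zeros(required.shape, dtype=np.int8)

    fill_rng = None if config.crn else _rng.substream(config.master_seed, _rng.FILLS)

    for d in range(days):
        wd = d % 7
        for s in range(len(SHIFTS)):
            if config.crn:

                def u_bank(i: int, r: int, k: int, _d=d, _s=s) -> np.ndarray:
                    return _rng.keyed_uniforms(
                        config.master_seed, _rng.FILLS, 0, i, _d, _s, r, n=k
                    )

                def u_agency(i: int, r: int, k: int, _d=d, _s=s) -> np.ndarray:
                    return _rng.keyed_uniforms(
                        config.master_seed, _rng.FILLS, 1, i, _d, _s, r, n=k
                    )

            else:

                def u_bank(i: int, r: int, k: int) -> np.ndarray:
                    return fill_rng.random(k)

                u_agency = u_bank

            res = resolve_shift(
                required[:, d, s, :],
                rostered[:, d, s, :] - absent[:, d, s, :],
                group_of,
                config.tolerance,
                block,
                p_bank_tab[s, wd],
                p_agency_tab[s, wd],
                u_bank,
                u_agency,
                config.allow_floating,
            )
            floated_in[:, d, s, :] = res["floated_in"]
            floated_out[:, d, s, :] = res["floated_out"]
            bank[:, d, s, :] = res["bank"]
            agency[:, d, s, :] = res["agency"]
            status_pre[:, d, s, :] = res["status_pre"]
            status_post[:, d, s, :] = res["status_post"]

    return SimulationResult(
        plan_kind=plan.plan_kind.value,
        availability_name=availability.name,
        unit_ids=[u.unit_id for u in units],
        specialty_groups=group_names,
        seed=config.master_seed,
        shift_length_hours=config.shift_length_hours,
        census=demand.census,
        required=required,
        rostered=rostered,
        absent=absent,
        floated_in=floated_in,
        floated_out=floated_out,
        bank=bank,
        agency=agency,
        status_pre=status_pre,
        status_post=status_post,
    )


def run_shift(
    hospital: HospitalProfile | Sequence,
    day: int,
    shift: str,
    plan: EstablishmentPlan,
    availability: AvailabilityScenario,
    config: SimulatorConfig,
) -> pd.DataFrame:
    """Ledger rows for a single (day, shift), consistent with run_scenario."""
    if day >= config.days:
        config = replace(config, days=day + 1)
    result = run_scenario(hospital, plan, availability, config)
    frame = result.to_frame()
    return frame[(frame["day"] == day) & (frame["shift"] == shift)].reset_index(drop=True)
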