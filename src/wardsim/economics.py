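"""Costing, exposure, mortality and cost-effectiveness evaluation.

The economic layer prices the achieved staffing of a simulation run
(substantive / bank / agency hourly rates with unsocial-hours multipliers),
measures each plan's exposure to low staffing (achieved hours per patient
day below the unit's mean under the standard plan) and to high temporary
staffing (> 1.5 temporary hours per patient day), converts exposure
differences into deaths and excess bed days via risk ratios per exposure
day, and reports NNT/NNH and incremental cost per life saved, with a
sensitivity grid over the cost and effect parameters.

Effect estimates ship as clearly-labelled illustrative defaults in the
magnitude range reported by longitudinal staffing-outcomes studies; they
are config inputs, not outputs, and every report echoes the values used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from .constants import ROLES, SHIFTS, TEMPORARY_SOURCES
from .errors import ConfigurationError, InputError
from .shift_engine import SimulationResult

__all__ = [
    "CostParameters",
    "EffectEstimates",
    "ExposureSummary",
    "EconomicResult",
    "CostSummary",
    "PlanComparison",
    "staffing_cost_summary",
    "recost",
    "reference_levels",
    "exposure_summary",
    "outcome_effects",
    "cost_effectiveness",
    "compare_plans",
    "implied_cross_nnt",
    "sensitivity_grid",
    "SENSITIVITY_PERTURBATIONS",
]

_SOURCES = ("substantive",) + TEMPORARY_SOURCES


def _default_hourly_cost() -> dict:
    # Illustrative 2017-era NHS-like rates (GBP/hour, salary + on-costs);
    # bank below substantive (reduced pension contributions), agency capped
    # above substantive.
    return {
        ("RN", "substantive"): 27.0,
        ("RN", "bank"): 25.0,
        ("RN", "agency"): 35.0,
        ("NA", "substantive"): 17.0,
        ("NA", "bank"): 16.0,
        ("NA", "agency"): 22.0,
    }


def _default_unsocial() -> dict:
    # Unsocial-hours multipliers: nights and weekends attract enhancements.
    out = {}
    for shift in SHIFTS:
        out[(shift, "weekday")] = 1.30 if shift == "night" else 1.0
        out[(shift, "weekend")] = 1.60 if shift == "night" else 1.35
    return out


@dataclass
class CostParameters:
    hourly_cost: dict = field(default_factory=_default_hourly_cost)
    unsocial_multiplier: dict = field(default_factory=_default_unsocial)
    excess_bed_day_cost: float = 337.0
    currency: str = "GBP"

    def __post_init__(self) -> None:
        for role in ROLES:
            for source in _SOURCES:
                if (role, source) not in self.hourly_cost:
                    raise ConfigurationError(f"missing hourly cost for ({role}, {source})")
                if self.hourly_cost[(role, source)] < 0:
                    raise ConfigurationError("hourly costs must be non-negative")
        for key, m in self.unsocial_multiplier.items():
            if m < 1.0:
                raise ConfigurationError(f"unsocial multiplier {key} must be >= 1")
        if self.excess_bed_day_cost < 0:
            raise ConfigurationError("excess_bed_day_cost must be non-negative")

    def scaled(self, factor: float) -> "CostParameters":
        return CostParameters(
            hourly_cost={k: v * factor for k, v in self.hourly_cost.items()},
            unsocial_multiplier=dict(self.unsocial_multiplier),
            excess_bed_day_cost=self.excess_bed_day_cost * factor,
            currency=self.currency,
        )


@dataclass
class EffectEstimates:
    """Exposure-outcome effect parameters (illustrative defaults).

    Risk ratios are per day of exposure per admission; the length-of-stay
    effect is a percent change per day of low-staffing exposure.
    """

    rr_death_per_low_day: float = 1.03
    rr_death_per_low_day_ci: tuple[float, float] = (1.01, 1.05)
    los_pct_per_low_day: float = 0.30
    rr_death_high_temp: float = 1.02
    high_temp_threshold: float = 1.5
    baseline_mortality_risk: float = 0.035
    baseline_los_days: float = 5.0

    def __post_init__(self) -> None:
        for rr in (self.rr_death_per_low_day, self.rr_death_high_temp, *self.rr_death_per_low_day_ci):
            if rr <= 0:
                raise ConfigurationError("risk ratios must be positive")
        if self.high_temp_threshold <= 0:
            raise ConfigurationError("high_temp_threshold must be positive")
        if not 0.0 < self.baseline_mortality_risk < 1.0:
            raise ConfigurationError("baseline mortality risk must lie in (0, 1)")
        if self.baseline_los_days <= 0:
            raise ConfigurationError("baseline length of stay must be positive")


VARIANTS = ("low_staffing_only", "including_temporary_effects")


# ---------------------------------------------------------------------------
# costing


@dataclass
class CostSummary:
    total: float
    per_patient_day: float
    patient_days: float
    breakdown: pd.DataFrame  # role, source, shift, daytype, hours, cost


def recost(breakdown: pd.DataFrame, costs: CostParameters) -> pd.DataFrame:
    """Price an hours-by-cell table under a (possibly perturbed) cost set."""
    out = breakdown.copy()
    rate = out.apply(lambda row: costs.hourly_cost[(row["role"], row["source"])], axis=1)
    mult = out.apply(lambda row: costs.unsocial_multiplier[(row["shift"], row["daytype"])], axis=1)
    out["cost"] = out["hours"] * rate * mult
    return out


def staffing_cost_summary(result: SimulationResult, costs: CostParameters) -> CostSummary:
    """Total and per-patient-day staffing cost of a run.

    cost = hours x hourly rate(role, source) x unsocial multiplier(shift,
    daytype); the denominator is patient days (census summed over unit-days).
    """
    breakdown = recost(result.hours_by_cost_cell(), costs)
    total = float(breakdown["cost"].sum())
    pdays = result.patient_days
    if pdays <= 0:
        raise InputError("cannot compute per-patient-day cost: zero patient days")
    return CostSummary(total, total / pdays, pdays, breakdown)


# ---------------------------------------------------------------------------
# exposure


def reference_levels(standard_result: SimulationResult) -> dict[str, float]:
    """Per-unit mean achieved hours per patient day under the standard plan.

    The unit mean (over unit-days with patients present) is the yardstick
    against which that unit's days are later judged low-staffed.
    """
    hppd = standard_result.hppd()
    refs: dict[str, float] = {}
    for i, uid in enumerate(standard_result.unit_ids):
        valid = ~np.isnan(hppd[i])
        if not valid.any():
            warnings.warn(f"unit {uid}: no patient days; excluded from reference levels",
                          stacklevel=2)
            continue
        refs[uid] = float(hppd[i, valid].mean())
    return refs


@dataclass
class ExposureSummary:
    """Patient-day-weighted exposure of one run."""

    plan_kind: str
    availability_name: str
    patient_days: float
    prop_low_staffed: float
    prop_high_temporary: float

    def exposure_days_per_admission(self, which: str, baseline_los_days: float) -> float:
        prop = self.prop_low_staffed if which == "low" else self.prop_high_temporary
        return prop * baseline_los_days


def exposure_summary(
    result: SimulationResult,
    reference: dict[str, float],
    threshold_high_temp: float = 1.5,
) -> ExposureSummary:
    """Exposure proportions for one run.

    A unit-day is low-staffed iff its achieved hours per patient day fall
    strictly below that unit's reference mean, and high-temporary iff
    temporary (bank + agency) hours per patient day strictly exceed the
    threshold.  Proportions are weighted by patient days.
    """
    missing = [u for u in result.unit_ids if u not in reference]
    if missing:
        raise InputError(f"no reference level for unit(s): {missing}")
    hppd = result.hppd()
    ref = np.array([reference[u] for u in result.unit_ids])[:, None]
    census = result.census.astype(float)
    present = census > 0
    low = present & (hppd < ref - 0.0)  # strict: exactly-at-reference is not low
    with np.errstate(divide="ignore", invalid="ignore"):
        temp_hppd = np.where(present, result.unit_day_temporary() / np.where(present, census, 1), 0.0)
    high = present & (temp_hppd > threshold_high_temp)
    pdays = census[present].sum()
    if pdays <= 0:
        raise InputError("run contains no patient days")
    return ExposureSummary(
        plan_kind=result.plan_kind,
        availability_name=result.availability_name,
        patient_days=float(pdays),
        prop_low_staffed=float(census[low].sum() / pdays),
        prop_high_temporary=float(census[high].sum() / pdays),
    )


# ---------------------------------------------------------------------------
# outcomes and cost-effectiveness


def outcome_effects(
    d_exposure_low_days: float,
    d_exposure_temp_days: float,
    effects: EffectEstimates,
    admissions: float,
    variant: str = "low_staffing_only",
    literal: bool = False,
) -> tuple[float, float]:
    """(delta deaths, delta bed days) from exposure differences.

    Default form is the linear excess-risk model: delta deaths =
    baseline risk x admissions x (RR - 1) x delta exposure days, summed over
    the low-staffing term and, for the secondary-analysis variant, the
    high-temporary-staffing term.  ``literal=True`` instead evaluates the
    compact published expression (exposure x RR x risk x population) minus
    the baseline death count, retained for audit only.
    """
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown analysis variant '{variant}'")
    if admissions <= 0:
        raise InputError("admissions must be positive")
    risk, pop = effects.baseline_mortality_risk, admissions
    if literal:
        d_deaths = d_exposure_low_days * effects.rr_death_per_low_day * risk * pop - risk * pop
        if variant == "including_temporary_effects":
            d_deaths += d_exposure_temp_days * effects.rr_death_high_temp * risk * pop - risk * pop
    else:
        d_deaths = risk * pop * (effects.rr_death_per_low_day - 1.0) * d_exposure_low_days
        if variant == "including_temporary_effects":
            d_deaths += risk * pop * (effects.rr_death_high_temp - 1.0) * d_exposure_temp_days
    d_bed_days = pop * effects.baseline_los_days * (effects.los_pct_per_low_day / 100.0) * d_exposure_low_days
    return float(d_deaths), float(d_bed_days)


@dataclass
class EconomicResult:
    """Cost-effectiveness of one plan comparison (intervention vs comparator)."""

    comparison: str
    availability_name: str
    variant: str
    admissions: float
    d_exposure_low_days: float
    d_exposure_temp_days: float
    d_staff_cost: float
    d_staff_cost_pct: float
    d_bed_days: float
    d_bed_days_pct: float
    d_deaths: float
    d_deaths_pct: float
    risk_change: float | None  # ARR (>0) or ARI, per admission; None if no effect
    nnt_kind: str  # "NNT", "NNH" or "no-effect"
    nnt: float | None
    staff_cost_per_life: float | None
    net_cost_per_life: float | None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def cost_effectiveness(
    comparison: str,
    availability_name: str,
    variant: str,
    d_staff_cost: float,
    d_bed_days: float,
    d_deaths: float,
    admissions: float,
    excess_bed_day_cost: float,
    comparator_staff_cost: float | None = None,
    baseline_deaths: float | None = None,
) -> EconomicResult:
    """Assemble NNT/NNH and cost-per-life figures from deltas.

    NNT = 1/ARR when the intervention saves lives, NNH = 1/ARI when it
    costs lives; a zero mortality difference yields an explicit no-effect
    marker rather than a division error.  Net cost adds the bed-day offset:
    net = delta staff cost + delta bed days x excess bed-day cost (shorter
    stays therefore reduce the net cost).
    """
    if admissions <= 0:
        raise InputError("admissions must be positive")
    d_bed_cost = d_bed_days * excess_bed_day_cost
    net = d_staff_cost + d_bed_cost
    if d_deaths == 0:
        kind, nnt, risk_change = "no-effect", None, None
        staff_per_life = net_per_life = None
    else:
        magnitude = abs(d_deaths) / admissions
        risk_change = magnitude
        kind = "NNT" if d_deaths < 0 else "NNH"
        nnt = 1.0 / magnitude
        staff_per_life = d_staff_cost / abs(d_deaths)
        net_per_life = net / abs(d_deaths)
    pct = lambda x, base: float("nan") if not base else 100.0 * x / base
    return EconomicResult(
        comparison=comparison,
        availability_name=availability_name,
        variant=variant,
        admissions=admissions,
        d_exposure_low_days=float("nan"),
        d_exposure_temp_days=float("nan"),
        d_staff_cost=d_staff_cost,
        d_staff_cost_pct=pct(d_staff_cost, comparator_staff_cost),
        d_bed_days=d_bed_days,
        d_bed_days_pct=float("nan"),
        d_deaths=d_deaths,
        d_deaths_pct=pct(d_deaths, baseline_deaths),
        risk_change=risk_change,
        nnt_kind=kind,
        nnt=nnt,
        staff_cost_per_life=staff_per_life,
        net_cost_per_life=net_per_life,
    )


def implied_cross_nnt(nnt_a: float, d_rr_a_pct: float, d_rr_b_pct: float) -> float:
    """NNT/NNH implied for comparison B from comparison A's NNT.

    Two comparisons sharing one baseline risk satisfy
    NNT_B = NNT_A x |dRR_A| / |dRR_B|, since NNT = 1/(risk x |dRR|).
    """
    if d_rr_b_pct == 0:
        raise InputError("comparison B has no mortality effect")
    return nnt_a * abs(d_rr_a_pct) / abs(d_rr_b_pct)


# ---------------------------------------------------------------------------
# plan comparison and sensitivity


@dataclass
class PlanComparison:
    """Everything needed to (re-)evaluate one comparison economically.

    Stores the hours-by-cost-cell tables and exposure summaries of both
    runs, so every sensitivity perturbation except "no floating" is a pure
    recosting/re-evaluation without re-simulation.
    """

    name: str
    availability_name: str
    breakdown_hi: pd.DataFrame
    breakdown_lo: pd.DataFrame
    exposure_hi: ExposureSummary
    exposure_lo: ExposureSummary
    patient_days: float

    def evaluate(
        self,
        costs: CostParameters,
        effects: EffectEstimates,
        variant: str = "low_staffing_only",
        literal: bool = False,
    ) -> EconomicResult:
        admissions = self.patient_days / effects.baseline_los_days
        cost_hi = float(recost(self.breakdown_hi, costs)["cost"].sum())
        cost_lo = float(recost(self.breakdown_lo, costs)["cost"].sum())
        d_low = self.exposure_hi.exposure_days_per_admission(
            "low", effects.baseline_los_days
        ) - self.exposure_lo.exposure_days_per_admission("low", effects.baseline_los_days)
        d_temp = self.exposure_hi.exposure_days_per_admission(
            "temp", effects.baseline_los_days
        ) - self.exposure_lo.exposure_days_per_admission("temp", effects.baseline_los_days)
        d_deaths, d_bed_days = outcome_effects(
            d_low, d_temp, effects, admissions, variant, literal
        )
        result = cost_effectiveness(
            self.name,
            self.availability_name,
            variant,
            cost_hi - cost_lo,
            d_bed_days,
            d_deaths,
            admissions,
            costs.excess_bed_day_cost,
            comparator_staff_cost=cost_lo,
            baseline_deaths=effects.baseline_mortality_risk * admissions,
        )
        result.d_exposure_low_days = d_low
        result.d_exposure_temp_days = d_temp
        result.d_bed_days_pct = 100.0 * d_bed_days / self.patient_days
        return result


def compare_plans(
    result_hi: SimulationResult,
    result_lo: SimulationResult,
    reference: dict[str, float],
    effects: EffectEstimates,
) -> PlanComparison:
    """Build a PlanComparison from two runs sharing demand streams."""
    exp_hi = exposure_summary(result_hi, reference, effects.high_temp_threshold)
    exp_lo = exposure_summary(result_lo, reference, effects.high_temp_threshold)
    return PlanComparison(
        name=f"{result_hi.plan_kind} vs {result_lo.plan_kind}",
        availability_name=result_lo.availability_name,
        breakdown_hi=result_hi.hours_by_cost_cell(),
        breakdown_lo=result_lo.hours_by_cost_cell(),
        exposure_hi=exp_hi,
        exposure_lo=exp_lo,
        patient_days=result_lo.patient_days,
    )


SENSITIVITY_PERTURBATIONS = (
    "identity",
    "mortality_rr_upper",
    "mortality_rr_lower",
    "bed_day_cost_plus25",
    "agency_cost_plus25",
    "agency_equals_bank",
    "bank_equals_substantive",
    "all_costs_plus25",
    "no_floating",
)


def _perturbed(
    name: str, costs: CostParameters, effects: EffectEstimates
) -> tuple[CostParameters, EffectEstimates]:
    hc = dict(costs.hourly_cost)
    if name == "identity":
        return costs, effects
    if name == "mortality_rr_upper":
        return costs, replace(effects, rr_death_per_low_day=effects.rr_death_per_low_day_ci[1])
    if name == "mortality_rr_lower":
        return costs, replace(effects, rr_death_per_low_day=effects.rr_death_per_low_day_ci[0])
    if name == "bed_day_cost_plus25":
        return replace(costs, excess_bed_day_cost=costs.excess_bed_day_cost * 1.25), effects
    if name == "agency_cost_plus25":
        for role in ROLES:
            hc[(role, "agency")] = hc[(role, "agency")] * 1.25
        return replace(costs, hourly_cost=hc), effects
    if name == "agency_equals_bank":
        for role in ROLES:
            hc[(role, "agency")] = hc[(role, "bank")]
        return replace(costs, hourly_cost=hc), effects
    if name == "bank_equals_substantive":
        for role in ROLES:
            hc[(role, "bank")] = hc[(role, "substantive")]
        return replace(costs, hourly_cost=hc), effects
    if name == "all_costs_plus25":
        return costs.scaled(1.25), effects
    raise ConfigurationError(
        f"unknown perturbation '{name}'; available: {', '.join(SENSITIVITY_PERTURBATIONS)}"
    )


def sensitivity_grid(
    comparison: PlanComparison,
    costs: CostParameters,
    effects: EffectEstimates,
    perturbations=SENSITIVITY_PERTURBATIONS,
    variant: str = "low_staffing_only",
    no_float_comparison: PlanComparison | None = None,
) -> pd.DataFrame:
    """Change in net cost per life saved under each parameter perturbation.

    All rows except "no_floating" are recostings of the stored run ledgers;
    "no_floating" re-evaluates a comparison built from runs simulated with
    floating disabled (supplied by the caller).
    """
    base = comparison.evaluate(costs, effects, variant)
    if base.net_cost_per_life is None:
        raise InputError("base comparison has no mortality effect; sensitivity undefined")
    rows = []
    for name in perturbations:
        if name == "no_floating":
            if no_float_comparison is None:
                raise ConfigurationError(
                    "perturbation 'no_floating' requires re-simulated runs "
                    "(pass no_float_comparison)"
                )
            res = no_float_comparison.evaluate(costs, effects, variant)
        else:
            p_costs, p_effects = _perturbed(name, costs, effects)
            res = comparison.evaluate(p_costs, p_effects, variant)
        rows.append(
            {
                "perturbation": name,
                "net_cost_per_life": res.net_cost_per_life,
                "change_vs_base": (
                    None
                    if res.net_cost_per_life is None
                    else res.net_cost_per_life - base.net_cost_per_life
                ),
            }
        )
    return pd.DataFrame(rows)
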