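"""Experiment grid: plans x availability scenarios x hospitals.

Runs the full factorial of staffing plans and temporary-staff availability
scenarios over each synthetic hospital, prices and evaluates every cell,
and emits three report tables: achieved staffing and daily cost per cell
(wide, one column set per availability), incremental cost-effectiveness
per plan comparison and analysis variant, and the sensitivity grid for the
high-baseline comparison.  Cross-hospital figures are unweighted averages
(ratios are computed from averaged deltas, i.e. pooled).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .demand_model import simulate_demand
from .economics import (
    SENSITIVITY_PERTURBATIONS,
    CostParameters,
    EconomicResult,
    EffectEstimates,
    ExposureSummary,
    PlanComparison,
    VARIANTS,
    compare_plans,
    reference_levels,
    sensitivity_grid,
    staffing_cost_summary,
)
from .errors import ConfigurationError
from .roster_planner import PlanKind, build_establishment
from .shift_engine import SimulatorConfig, run_scenario
from .synthetic_hospital import AVAILABILITY_PRESETS, GeneratorConfig, availability_preset, generate_hospital

__all__ = ["ExperimentConfig", "ExperimentBundle", "run_experiment_grid", "write_report_tables"]

_PLAN_ORDER = [PlanKind.FLEXIBLE, PlanKind.STANDARD, PlanKind.RESILIENT]


@dataclass
class ExperimentConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    costs: CostParameters = field(default_factory=CostParameters)
    effects: EffectEstimates = field(default_factory=EffectEstimates)
    plans: tuple = (PlanKind.FLEXIBLE, PlanKind.STANDARD, PlanKind.RESILIENT)
    availabilities: tuple = AVAILABILITY_PRESETS
    reference_plan: PlanKind = PlanKind.STANDARD
    variants: tuple = VARIANTS
    sensitivity_availabilities: tuple = ("limited", "unlimited")
    master_seed: int = 0

    def __post_init__(self) -> None:
        self.plans = tuple(PlanKind(p) for p in self.plans)
        self.reference_plan = PlanKind(self.reference_plan)
        if self.reference_plan not in self.plans:
            raise ConfigurationError("reference plan must be part of the plan grid")
        unknown = [v for v in self.variants if v not in VARIANTS]
        if unknown:
            raise ConfigurationError(f"unknown analysis variant(s): {unknown}")
        for a in tuple(self.availabilities) + tuple(self.sensitivity_availabilities):
            if a not in AVAILABILITY_PRESETS:
                raise ConfigurationError(f"unknown availability preset '{a}'")

    def ordered_plans(self) -> list[PlanKind]:
        return [p for p in _PLAN_ORDER if p in self.plans]

    def comparison_pairs(self) -> list[tuple[PlanKind, PlanKind]]:
        """Consecutive (higher, lower) baseline pairs, e.g. standard vs flexible."""
        ordered = self.ordered_plans()
        return [(ordered[i + 1], ordered[i]) for i in range(len(ordered) - 1)]


@dataclass
class ExperimentBundle:
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    per_hospital_table2: pd.DataFrame
    per_hospital_table3: pd.DataFrame
    manifest: dict


def _hospital_seed(master_seed: int, hospital_index: int) -> int:
    seq = np.random.SeedSequence(int(master_seed), spawn_key=(97, int(hospital_index)))
    return int(seq.generate_state(1)[0] % (2**31))


def _pool_comparisons(comparisons: list[PlanComparison]) -> PlanComparison:
    """Pool per-hospital comparisons (sums of hours, patient-day-weighted
    exposures); ratios of pooled deltas equal ratios of unweighted hospital
    averages."""
    breakdown_hi = (
        pd.concat([c.breakdown_hi for c in comparisons])
        .groupby(["role", "source", "shift", "daytype"], as_index=False)["hours"]
        .sum()
    )
    breakdown_lo = (
        pd.concat([c.breakdown_lo for c in comparisons])
        .groupby(["role", "source", "shift", "daytype"], as_index=False)["hours"]
        .sum()
    )
    pdays = sum(c.patient_days for c in comparisons)

    def pool_exposure(exps: list[ExposureSummary]) -> ExposureSummary:
        total = sum(e.patient_days for e in exps)
        return ExposureSummary(
            plan_kind=exps[0].plan_kind,
            availability_name=exps[0].availability_name,
            patient_days=total,
            prop_low_staffed=sum(e.prop_low_staffed * e.patient_days for e in exps) / total,
            prop_high_temporary=sum(e.prop_high_temporary * e.patient_days for e in exps)
            / total,
        )

    return PlanComparison(
        name=comparisons[0].name,
        availability_name=comparisons[0].availability_name,
        breakdown_hi=breakdown_hi,
        breakdown_lo=breakdown_lo,
        exposure_hi=pool_exposure([c.exposure_hi for c in comparisons]),
        exposure_lo=pool_exposure([c.exposure_lo for c in comparisons]),
        patient_days=pdays,
    )


def _result_row(res: EconomicResult, hospital: str) -> dict:
    row = {"hospital": hospital}
    row.update(res.to_dict())
    return row


def _config_dict(config: ExperimentConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, PlanKind):
            return obj.value
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    return convert(config)


def run_experiment_grid(config: ExperimentConfig) -> ExperimentBundle:
    """Run the full grid and assemble the report bundle.

    Deterministic given the master seed.  A failing cell is recorded in the
    manifest and the remaining cells still run.
    """
    gen, sim = config.generator, config.simulator
    t2_rows, t3_rows, failures = [], [], []
    comps_by_key: dict[tuple, list[PlanComparison]] = {}
    nofloat_by_key: dict[tuple, list[PlanComparison]] = {}
    pairs = config.comparison_pairs()

    for h in range(gen.n_hospitals):
        hospital = generate_hospital(gen, config.master_seed, h)
        hseed = _hospital_seed(config.master_seed, h)
        sim_h = dataclasses.replace(sim, master_seed=hseed)
        try:
            demand = simulate_demand(hospital.units, sim_h.days, hseed, sim_h.multipliers)
            plans = {
                p: build_establishment(
                    hospital.units, p, hseed, shift_length_hours=sim_h.shift_length_hours,
                    multipliers=sim_h.multipliers,
                )
                for p in config.plans
            }
        except Exception:  # pragma: no cover - defensive
            failures.append({"hospital": hospital.hospital_id, "error": traceback.format_exc()})
            continue
        for avail_name in config.availabilities:
            availability = availability_preset(avail_name)
            try:
                results = {
                    p: run_scenario(hospital, plans[p], availability, sim_h, demand)
                    for p in config.plans
                }
                for p in config.ordered_plans():
                    summary = staffing_cost_summary(results[p], config.costs)
                    t2_rows.append(
                        {
                            "hospital": hospital.hospital_id,
                            "availability": avail_name,
                            "plan": p.value,
                            "cost_per_patient_day": summary.per_patient_day,
                            "rn_hppd": results[p].mean_hppd("RN"),
                            "na_hppd": results[p].mean_hppd("NA"),
                        }
                    )
                refs = reference_levels(results[config.reference_plan])
                for hi, lo in pairs:
                    comp = compare_plans(results[hi], results[lo], refs, config.effects)
                    comps_by_key.setdefault((avail_name, comp.name), []).append(comp)
                if avail_name in config.sensitivity_availabilities and pairs:
                    hi, lo = pairs[-1]
                    sim_nf = dataclasses.replace(sim_h, allow_floating=False)
                    nf_results = {
                        p: run_scenario(hospital, plans[p], availability, sim_nf, demand)
                        for p in (hi, lo, config.reference_plan)
                    }
                    nf_refs = reference_levels(nf_results[config.reference_plan])
                    nofloat_by_key.setdefault((avail_name, f"{hi.value} vs {lo.value}"), []).append(
                        compare_plans(nf_results[hi], nf_results[lo], nf_refs, config.effects)
                    )
            except Exception:
                failures.append(
                    {
                        "hospital": hospital.hospital_id,
                        "availability": avail_name,
                        "error": traceback.format_exc(),
                    }
                )

    per_hosp_t3_rows = []
    pooled_rows = []
    for (avail_name, comp_name), comps in comps_by_key.items():
        for variant in config.variants:
            for c, hosp in zip(comps, [f"H{i + 1}" for i in range(len(comps))]):
                per_hosp_t3_rows.append(
                    _result_row(c.evaluate(config.costs, config.effects, variant), hosp)
                )
            pooled = _pool_comparisons(comps)
            pooled_rows.append(
                _result_row(pooled.evaluate(config.costs, config.effects, variant), "average")
            )

    t4_rows = []
    for (avail_name, comp_name), comps in comps_by_key.items():
        if avail_name not in config.sensitivity_availabilities:
            continue
        if pairs and comp_name != f"{pairs[-1][0].value} vs {pairs[-1][1].value}":
            continue
        pooled = _pool_comparisons(comps)
        nf = nofloat_by_key.get((avail_name, comp_name))
        grid = sensitivity_grid(
            pooled,
            config.costs,
            config.effects,
            SENSITIVITY_PERTURBATIONS,
            variant="low_staffing_only",
            no_float_comparison=_pool_comparisons(nf) if nf else None,
        )
        grid.insert(0, "availability", avail_name)
        grid.insert(1, "comparison", comp_name)
        t4_rows.append(grid)

    per_hospital_table2 = pd.DataFrame(t2_rows)
    if len(per_hospital_table2):
        table2 = (
            per_hospital_table2.groupby(["availability", "plan"], as_index=False)[
                ["cost_per_patient_day", "rn_hppd", "na_hppd"]
            ]
            .mean()
        )
        order = {p.value: i for i, p in enumerate(_PLAN_ORDER)}
        table2 = table2.sort_values(
            ["availability", "plan"], key=lambda s: s.map(order) if s.name == "plan" else s
        ).reset_index(drop=True)
    else:
        table2 = per_hospital_table2
    table3 = pd.DataFrame(pooled_rows)
    per_hospital_table3 = pd.DataFrame(per_hosp_t3_rows)
    table4 = pd.concat(t4_rows, ignore_index=True) if t4_rows else pd.DataFrame(
        columns=["availability", "comparison", "perturbation", "net_cost_per_life", "change_vs_base"]
    )

    cfg_dict = _config_dict(config)
    manifest = {
        "master_seed": config.master_seed,
        "hospital_seeds": [
            _hospital_seed(config.master_seed, h) for h in range(gen.n_hospitals)
        ],
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "failures": failures,
    }
    return ExperimentBundle(
        table2=table2,
        table3=table3,
        table4=table4,
        per_hospital_table2=per_hospital_table2,
        per_hospital_table3=per_hospital_table3,
        manifest=manifest,
    )


_TABLE_FILES = {
    "table2": "table2_staffing_costs.csv",
    "table3": "table3_cost_effectiveness.csv",
    "table4": "table4_sensitivity.csv",
    "per_hospital_table2": "per_hospital_staffing_costs.csv",
    "per_hospital_table3": "per_hospital_cost_effectiveness.csv",
}


def write_report_tables(bundle: ExperimentBundle, out_dir) -> dict[str, str]:
    """Write the bundle as CSV + JSON artifacts with stable column order."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for attr, fname in _TABLE_FILES.items():
        frame: pd.DataFrame = getattr(bundle, attr)
        path = out / fname
        frame.to_csv(path, index=False)
        written[attr] = str(path)
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
    written["manifest"] = str(manifest_path)
    return written
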