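"""Synthetic hospitals, ward profiles and temporary-staff availability.

The generator stands in for a year-long observational study of acuity,
dependency and census on general medical/surgical inpatient units.  Its
defaults emulate the statistical structure such data shows: daily required
care hours per unit with a slight positive skew (cross-unit median ~0.6,
with roughly one unit in six above 1) and positive excess kurtosis
(median ~0.7), unit censuses averaging ~23 occupied beds, an RN/assistant
skill mix near 50:50, and 1:1 specialing demand.

Daily demand is built structurally rather than drawn directly: a truncated
discrete census draw, a care-level mix perturbed day to day by a
right-skewed acuity factor, and a Poisson specialing count.  The acuity
factor is the shape control: a log-normal bulk whose per-unit spread is set
by inverting the log-normal skewness function from a per-unit skewness
target, plus a small symmetric scale-mixture tail (rare high-variability
days) that carries the excess kurtosis which the bounded care-level mix
would otherwise truncate away.  One global calibration constant rescales
the per-unit spreads to offset the interplay of these components with
census and multinomial sampling noise.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _rng
from .constants import CARE_LEVELS, DEFAULT_CARE_HOURS, ROLES, SHIFTS, TEMPORARY_SOURCES, WEEKDAYS
from .errors import ConfigurationError, InputError

__all__ = [
    "DistributionSpec",
    "UnitProfile",
    "HospitalProfile",
    "AvailabilityScenario",
    "GeneratorConfig",
    "PatientMix",
    "generate_hospital",
    "generate_hospitals",
    "sample_patient_mix",
    "availability_preset",
    "demand_shape_summary",
    "sigma_from_skewness",
    "lognormal_excess_kurtosis",
    "units_to_csv",
    "units_from_csv",
    "hospital_to_json",
    "hospital_from_json",
]

AVAILABILITY_PRESETS = ("none", "limited", "higher", "unlimited")

# Calibration constant: ratio between the acuity-factor log-scale actually
# used and the one implied by the unit's skewness target alone.  The
# scale-mixture tail, specialing jumps and census/multinomial noise all
# contribute shape of their own, so the log-normal bulk is rescaled to keep
# the cross-unit medians of sample skewness and excess kurtosis on target.
# Fixed once against the generator defaults (81 units x 365 days).
SHAPE_INFLATION = 0.455


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class DistributionSpec:
    """A small named-family distribution spec (serialisable)."""

    family: str
    params: dict

    def to_json(self) -> str:
        return json.dumps({"family": self.family, "params": self.params}, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DistributionSpec":
        obj = json.loads(text)
        return cls(obj["family"], obj["params"])


@dataclass
class UnitProfile:
    """One ward: its size, demand distributions and staffing structure."""

    unit_id: str
    specialty_group: str
    beds: int
    census_dist: DistributionSpec
    acuity_mix_dist: DistributionSpec
    specialing_rate: float
    shift_weights: tuple[float, float, float]
    rn_skill_mix: float
    demand_shape: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.beds <= 0:
            raise ConfigurationError(f"unit {self.unit_id}: beds must be positive")
        w = np.asarray(self.shift_weights, dtype=float)
        if w.shape != (len(SHIFTS),) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"unit {self.unit_id}: shift_weights must be {len(SHIFTS)} non-negative "
                "proportions summing to 1"
            )
        if not 0.0 < self.rn_skill_mix < 1.0:
            raise ConfigurationError(f"unit {self.unit_id}: rn_skill_mix must lie in (0, 1)")
        if self.specialing_rate < 0:
            raise ConfigurationError(f"unit {self.unit_id}: specialing_rate must be >= 0")


@dataclass
class HospitalProfile:
    hospital_id: str
    units: list[UnitProfile]

    def __post_init__(self) -> None:
        sizes = pd.Series([u.specialty_group for u in self.units]).value_counts()
        small = sizes[sizes < 2]
        if len(small):
            warnings.warn(
                f"hospital {self.hospital_id}: specialty group(s) {list(small.index)} have "
                "fewer than 2 units; floating between units is vacuous there",
                stacklevel=2,
            )

    @property
    def specialty_groups(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for u in self.units:
            groups.setdefault(u.specialty_group, []).append(u.unit_id)
        return groups


@dataclass
class AvailabilityScenario:
    """Probability that a temporary-staff request is fulfilled.

    Keyed by (source, role, shift, weekday); sources are the internal bank
    and the external agency.
    """

    name: str
    p_fulfil: dict[tuple[str, str, str, str], float]

    def __post_init__(self) -> None:
        expected = {
            (src, role, shift, wd)
            for src in TEMPORARY_SOURCES
            for role in ROLES
            for shift in SHIFTS
            for wd in WEEKDAYS
        }
        if set(self.p_fulfil) != expected:
            raise ConfigurationError(
                f"availability scenario '{self.name}': table must cover exactly "
                f"{len(expected)} (source, role, shift, weekday) cells"
            )
        for key, p in self.p_fulfil.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"availability scenario '{self.name}': probability {p} for {key} "
                    "outside [0, 1]"
                )

    def prob(self, source: str, role: str, shift: str, weekday: str) -> float:
        return self.p_fulfil[(source, role, shift, weekday)]

    @classmethod
    def uniform(cls, name: str, bank: float, agency: float) -> "AvailabilityScenario":
        table = {}
        for role in ROLES:
            for shift in SHIFTS:
                for wd in WEEKDAYS:
                    table[("bank", role, shift, wd)] = float(bank)
                    table[("agency", role, shift, wd)] = float(agency)
        return cls(name, table)

    def as_lookup(self) -> dict[str, np.ndarray]:
        """Dense lookup arrays indexed [shift, weekday, role]."""
        out = {}
        for src in TEMPORARY_SOURCES:
            arr = np.empty((len(SHIFTS), len(WEEKDAYS), len(ROLES)))
            for i, shift in enumerate(SHIFTS):
                for j, wd in enumerate(WEEKDAYS):
                    for k, role in enumerate(ROLES):
                        arr[i, j, k] = self.p_fulfil[(src, role, shift, wd)]
            out[src] = arr
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"source": s, "role": r, "shift": sh, "weekday": wd, "probability": p}
            for (s, r, sh, wd), p in sorted(self.p_fulfil.items())
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, name: str, frame: pd.DataFrame) -> "AvailabilityScenario":
        table = {
            (row.source, row.role, row.shift, row.weekday): float(row.probability)
            for row in frame.itertuples()
        }
        return cls(name, table)

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "AvailabilityScenario":
        # keep_default_na: the assistant role is literally named "NA"
        frame = pd.read_csv(path, keep_default_na=False)
        return cls.from_frame(name or str(path), frame)


@dataclass(frozen=True)
class PatientMix:
    """One unit-day's patients: census, care-level counts, specialing count."""

    census: int
    level_counts: np.ndarray  # aligned with CARE_LEVELS
    specialing: int


# ---------------------------------------------------------------------------
# log-normal shape helpers


def _lognormal_skewness(sigma: float) -> float:
    w = np.exp(sigma**2)
    return (w + 2.0) * np.sqrt(w - 1.0)


def lognormal_excess_kurtosis(sigma: float) -> float:
    """Excess kurtosis of a log-normal with log-scale ``sigma``."""
    s2 = sigma**2
    return float(np.exp(4 * s2) + 2 * np.exp(3 * s2) + 3 * np.exp(2 * s2) - 6.0)


def sigma_from_skewness(skew: float) -> float:
    """Invert the log-normal skewness function (skew > 0)."""
    if skew <= 0:
        raise InputError("target skewness must be positive")
    return float(optimize.brentq(lambda s: _lognormal_skewness(s) - skew, 1e-9, 5.0))


# ---------------------------------------------------------------------------
# generator


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-hospital generator.

    Defaults emulate three hospitals of 27 general medical/surgical units
    each (81 units), censuses averaging ~22.9 occupied beds per unit-day,
    and per-unit daily required-hours distributions whose cross-unit median
    skewness is ~0.6 and median excess kurtosis ~0.7.
    """

    n_hospitals: int = 3
    units_per_hospital: int = 27
    groups_per_hospital: int = 3
    beds_range: tuple[int, int] = (22, 30)
    occupancy_mean: float = 0.88
    occupancy_sd: float = 0.05
    occupancy_bounds: tuple[float, float] = (0.65, 0.97)
    base_acuity_mix: tuple[float, ...] = (0.36, 0.27, 0.18, 0.12, 0.07)
    acuity_concentration: float = 60.0
    mix_high: tuple[float, ...] = (0.0, 0.0, 0.0, 0.25, 0.75)
    tail_mix_prob: float = 0.028  # share of high-variability days
    tail_mix_scale: float = 3.5  # log-scale widening on those days
    rn_mix_mean: float = 0.51
    rn_mix_sd: float = 0.05
    rn_mix_bounds: tuple[float, float] = (0.35, 0.70)
    shift_weight_base: tuple[float, float, float] = (0.40, 0.35, 0.25)
    shift_weight_concentration: float = 80.0
    specialing_rate_range: tuple[float, float] = (0.0, 0.4)
    skew_median: float = 0.6  # cross-unit median of per-unit skewness targets
    skew_log_sd: float = 0.514  # puts ~16% of units above skewness 1
    level_hours: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CARE_HOURS))
    shape_inflation: float = SHAPE_INFLATION

    def __post_init__(self) -> None:
        if self.n_hospitals <= 0 or self.units_per_hospital <= 0:
            raise ConfigurationError("hospital and unit counts must be positive")
        if self.groups_per_hospital <= 0:
            raise ConfigurationError("groups_per_hospital must be positive")
        lo, hi = self.beds_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError("beds_range must be positive and ordered")
        mix = np.asarray(self.base_acuity_mix, dtype=float)
        if mix.shape != (len(CARE_LEVELS),) or np.any(mix < 0) or abs(mix.sum() - 1) > 1e-9:
            raise ConfigurationError("base_acuity_mix must be proportions over the care levels")
        if self.skew_median <= 0:
            raise ConfigurationError("skew_median must be positive")


_GROUP_NAMES = ("medical", "surgical", "elderly", "mixed", "stepdown", "admissions")


def generate_hospital(
    gen_config: GeneratorConfig, seed: int, hospital_index: int = 0
) -> HospitalProfile:
    """Generate one synthetic hospital, deterministic in (config, seed, index)."""
    cfg = gen_config
    rng = _rng.substream(seed, _rng.STRUCTURE, hospital_index)
    hid = f"H{hospital_index + 1}"
    n = cfg.units_per_hospital
    level_hours = np.array([cfg.level_hours[lv] for lv in CARE_LEVELS], dtype=float)
    mix_high = np.asarray(cfg.mix_high, dtype=float)
    h_hi = float(mix_high @ level_hours)
    h_lo = float(level_hours[0])

    beds = rng.integers(cfg.beds_range[0], cfg.beds_range[1] + 1, size=n)
    occ = np.clip(
        rng.normal(cfg.occupancy_mean, cfg.occupancy_sd, size=n), *cfg.occupancy_bounds
    )
    base_mix = rng.dirichlet(
        np.asarray(cfg.base_acuity_mix) * cfg.acuity_concentration, size=n
    )
    rn_mix = np.clip(rng.normal(cfg.rn_mix_mean, cfg.rn_mix_sd, size=n), *cfg.rn_mix_bounds)
    shift_w = rng.dirichlet(
        np.asarray(cfg.shift_weight_base) * cfg.shift_weight_concentration, size=n
    )
    spec_rate = rng.uniform(*cfg.specialing_rate_range, size=n)
    # Per-unit skewness targets: log-normal across units so the cross-unit
    # median sits at skew_median with a heavy enough right tail that a
    # realistic minority of units exceed 1.
    target_skew = np.exp(rng.normal(np.log(cfg.skew_median), cfg.skew_log_sd, size=n))
    target_skew = np.clip(target_skew, 0.05, 3.0)

    groups = np.array_split(np.arange(n), cfg.groups_per_hospital)
    group_of = np.empty(n, dtype=int)
    for g, idx in enumerate(groups):
        group_of[idx] = g

    units = []
    for i in range(n):
        sigma = sigma_from_skewness(float(target_skew[i])) * cfg.shape_inflation
        gname = _GROUP_NAMES[group_of[i] % len(_GROUP_NAMES)]
        acuity = DistributionSpec(
            "tilted-multinomial",
            {
                "base_mix": [float(x) for x in base_mix[i]],
                "mix_high": [float(x) for x in mix_high],
                "level_hours": [float(x) for x in level_hours],
                "sigma_log": float(sigma),
                "tail_mix_prob": float(cfg.tail_mix_prob),
                "tail_mix_scale": float(cfg.tail_mix_scale),
            },
        )
        units.append(
            UnitProfile(
                unit_id=f"{hid}-U{i + 1:02d}",
                specialty_group=f"{hid}-{gname}",
                beds=int(beds[i]),
                census_dist=DistributionSpec(
                    "binomial", {"n": int(beds[i]), "p": float(occ[i])}
                ),
                acuity_mix_dist=acuity,
                specialing_rate=float(spec_rate[i]),
                shift_weights=tuple(float(x) for x in shift_w[i]),
                rn_skill_mix=float(rn_mix[i]),
                demand_shape={
                    "target_skewness": float(target_skew[i]),
                    "target_excess_kurtosis": lognormal_excess_kurtosis(
                        sigma_from_skewness(float(target_skew[i]))
                    ),
                    "sigma_log": float(sigma),
                },
            )
        )
    return HospitalProfile(hospital_id=hid, units=units)


def generate_hospitals(gen_config: GeneratorConfig, seed: int) -> list[HospitalProfile]:
    """Generate the full synthetic system (default: 3 hospitals, 81 units)."""
    return [
        generate_hospital(gen_config, seed, h) for h in range(gen_config.n_hospitals)
    ]


# ---------------------------------------------------------------------------
# patient-mix sampling


def sample_patient_mix_block(
    unit: UnitProfile, n_days: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised patient-mix draws: (census, level_counts, specialing).

    census: (n_days,) ints; level_counts: (n_days, n_levels); specialing
    clipped at census so 1:1 patients are always real patients.
    """
    cd = unit.census_dist
    if cd.family == "degenerate":
        census = np.full(n_days, int(cd.params["value"]), dtype=np.int64)
    elif cd.family == "binomial":
        census = rng.binomial(int(cd.params["n"]), float(cd.params["p"]), size=n_days)
    elif cd.family == "negative-binomial":
        # mean mu, dispersion r (var = mu + mu^2/r); mildly right-skewed,
        # as ward censuses below capacity are; truncated at the bed count
        mu, r = float(cd.params["mu"]), float(cd.params["r"])
        census = rng.negative_binomial(r, r / (r + mu), size=n_days)
    else:
        raise ConfigurationError(f"unknown census distribution family '{cd.family}'")
    census = np.clip(census, 0, unit.beds)

    am = unit.acuity_mix_dist
    if am.family == "fixed":
        pvals = np.tile(np.asarray(am.params["mix"], dtype=float), (n_days, 1))
    elif am.family == "tilted-multinomial":
        base = np.asarray(am.params["base_mix"], dtype=float)
        mix_high = np.asarray(am.params["mix_high"], dtype=float)
        level_hours = np.asarray(am.params["level_hours"], dtype=float)
        sigma = float(am.params["sigma_log"])
        q = float(am.params.get("tail_mix_prob", 0.0))
        s = float(am.params.get("tail_mix_scale", 1.0))
        h_u = float(base @ level_hours)
        h_hi = float(mix_high @ level_hours)
        h_lo = float(level_hours[0])
        # Mean-one right-skewed day factor: log-normal bulk with a small
        # symmetric scale-mixture tail (occasional high-variability days),
        # which carries the excess kurtosis seen in observed demand.
        z = rng.normal(0.0, 1.0, size=n_days)
        if q > 0.0:
            wide = rng.random(n_days) < q
            z[wide] *= s
        mean_factor = (1.0 - q) * np.exp(0.5 * sigma**2) + q * np.exp(0.5 * (s * sigma) ** 2)
        g = np.exp(sigma * z) / mean_factor
        mu = np.clip(h_u * g, h_lo, h_hi)
        pvals = np.empty((n_days, len(base)))
        up = mu >= h_u
        t_up = np.zeros(n_days)
        if h_hi > h_u:
            t_up[up] = (mu[up] - h_u) / (h_hi - h_u)
        t_dn = np.zeros(n_days)
        if h_u > h_lo:
            t_dn[~up] = (h_u - mu[~up]) / (h_u - h_lo)
        e0 = np.zeros(len(base))
        e0[0] = 1.0
        pvals[up] = (1 - t_up[up, None]) * base + t_up[up, None] * mix_high
        pvals[~up] = (1 - t_dn[~up, None]) * base + t_dn[~up, None] * e0
    else:
        raise ConfigurationError(f"unknown acuity mix family '{am.family}'")

    counts = rng.multinomial(census, pvals)
    if unit.specialing_rate > 0:
        specialing = np.minimum(rng.poisson(unit.specialing_rate, size=n_days), census)
    else:
        specialing = np.zeros(n_days, dtype=np.int64)
    return census, counts, specialing


def sample_patient_mix(unit: UnitProfile, day: int, rng: np.random.Generator) -> PatientMix:
    """Draw one day's patient mix for a unit (census, level counts, specialing)."""
    census, counts, specialing = sample_patient_mix_block(unit, 1, rng)
    return PatientMix(int(census[0]), counts[0], int(specialing[0]))


# ---------------------------------------------------------------------------
# availability presets


def availability_preset(name: str) -> AvailabilityScenario:
    """Return one of the named temporary-staff availability scenarios."""
    if name == "none":
        return AvailabilityScenario.uniform("none", 0.0, 0.0)
    if name == "higher":
        return AvailabilityScenario.uniform("higher", 0.5, 0.5)
    if name == "unlimited":
        return AvailabilityScenario.uniform("unlimited", 0.5, 1.0)
    if name == "limited":
        with resources.files("wardsim.data").joinpath("availability_limited.csv").open() as fh:
            frame = pd.read_csv(fh, keep_default_na=False)
        return AvailabilityScenario.from_frame("limited", frame)
    raise ConfigurationError(
        f"unknown availability preset '{name}'; available: {', '.join(AVAILABILITY_PRESETS)}"
    )


# ---------------------------------------------------------------------------
# demand-shape summary


def demand_shape_summary(realisations) -> tuple[pd.DataFrame, dict]:
    """Per-unit sample skewness / excess kurtosis of daily required hours.

    ``realisations`` maps unit_id -> 1-D array of daily totals (a 2-D array
    is treated as units x days).  Skewness is the adjusted Fisher-Pearson
    sample statistic; kurtosis is excess kurtosis (normal = 0), both
    bias-corrected.  Units with fewer than 3 days or zero variance are
    excluded with a warning.
    """
    if isinstance(realisations, np.ndarray):
        realisations = {f"unit{i:03d}": row for i, row in enumerate(np.atleast_2d(realisations))}
    rows = []
    for unit_id, values in realisations.items():
        x = np.asarray(values, dtype=float)
        if x.size < 3:
            warnings.warn(
                f"unit {unit_id}: fewer than 3 observations; excluded from shape summary",
                stacklevel=2,
            )
            continue
        if np.ptp(x) == 0:
            warnings.warn(
                f"unit {unit_id}: zero variance; excluded from shape summary", stacklevel=2
            )
            continue
        rows.append(
            {
                "unit_id": unit_id,
                "n_days": int(x.size),
                "skewness": float(stats.skew(x, bias=False)),
                "excess_kurtosis": float(stats.kurtosis(x, fisher=True, bias=False)),
            }
        )
    table = pd.DataFrame(rows, columns=["unit_id", "n_days", "skewness", "excess_kurtosis"])
    if len(table):
        summary = {
            "n_units": int(len(table)),
            "median_skewness": float(table["skewness"].median()),
            "median_excess_kurtosis": float(table["excess_kurtosis"].median()),
            "frac_skewness_gt_1": float((table["skewness"] > 1).mean()),
            "frac_excess_kurtosis_gt_1": float((table["excess_kurtosis"] > 1).mean()),
        }
    else:
        summary = {
            "n_units": 0,
            "median_skewness": float("nan"),
            "median_excess_kurtosis": float("nan"),
            "frac_skewness_gt_1": float("nan"),
            "frac_excess_kurtosis_gt_1": float("nan"),
        }
    return table, summary


# ---------------------------------------------------------------------------
# round-trip IO


def units_to_csv(units: Sequence[UnitProfile], path) -> None:
    rows = []
    for u in units:
        rows.append(
            {
                "unit_id": u.unit_id,
                "specialty_group": u.specialty_group,
                "beds": u.beds,
                "census_dist": u.census_dist.to_json(),
                "acuity_mix_dist": u.acuity_mix_dist.to_json(),
                "specialing_rate": u.specialing_rate,
                "shift_weights": json.dumps(list(u.shift_weights)),
                "rn_skill_mix": u.rn_skill_mix,
                "demand_shape": json.dumps(u.demand_shape, sort_keys=True),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def units_from_csv(path) -> list[UnitProfile]:
    frame = pd.read_csv(path, keep_default_na=False)
    units = []
    for row in frame.itertuples():
        units.append(
            UnitProfile(
                unit_id=row.unit_id,
                specialty_group=row.specialty_group,
                beds=int(row.beds),
                census_dist=DistributionSpec.from_json(row.census_dist),
                acuity_mix_dist=DistributionSpec.from_json(row.acuity_mix_dist),
                specialing_rate=float(row.specialing_rate),
                shift_weights=tuple(json.loads(row.shift_weights)),
                rn_skill_mix=float(row.rn_skill_mix),
                demand_shape=json.loads(row.demand_shape),
            )
        )
    return units


def hospital_to_json(hospital: HospitalProfile, path=None) -> str:
    def unit_dict(u: UnitProfile) -> dict:
        d = dataclasses.asdict(u)
        d["census_dist"] = {"family": u.census_dist.family, "params": u.census_dist.params}
        d["acuity_mix_dist"] = {
            "family": u.acuity_mix_dist.family,
            "params": u.acuity_mix_dist.params,
        }
        d["shift_weights"] = list(u.shift_weights)
        return d

    text = json.dumps(
        {"hospital_id": hospital.hospital_id, "units": [unit_dict(u) for u in hospital.units]},
        indent=2,
        sort_keys=True,
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def hospital_from_json(source) -> HospitalProfile:
    if isinstance(source, str) and source.lstrip().startswith("{"):
        obj = json.loads(source)
    else:
        with open(source) as fh:
            obj = json.load(fh)
    units = [
        UnitProfile(
            unit_id=u["unit_id"],
            specialty_group=u["specialty_group"],
            beds=int(u["beds"]),
            census_dist=DistributionSpec(**u["census_dist"]),
            acuity_mix_dist=DistributionSpec(**u["acuity_mix_dist"]),
            specialing_rate=float(u["specialing_rate"]),
            shift_weights=tuple(u["shift_weights"]),
            rn_skill_mix=float(u["rn_skill_mix"]),
            demand_shape=u.get("demand_shape", {}),
        )
        for u in obj["units"]
    ]
    return HospitalProfile(hospital_id=obj["hospital_id"], units=units)
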