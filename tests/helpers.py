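"""Shared test helpers: compact unit-profile factories."""

from __future__ import annotations

from wardsim.synthetic_hospital import DistributionSpec, HospitalProfile, UnitProfile


def make_unit(
    unit_id: str = "U1",
    group: str = "G1",
    beds: int = 24,
    census: int | DistributionSpec = 20,
    mix: tuple = (1.0, 0.0, 0.0, 0.0, 0.0),
    specialing_rate: float = 0.0,
    shift_weights: tuple = (0.4, 0.4, 0.2),
    rn_skill_mix: float = 0.5,
) -> UnitProfile:
    """A unit with degenerate census (int) and a fixed acuity mix by default."""
    if isinstance(census, int):
        census_dist = DistributionSpec("degenerate", {"value": census})
    else:
        census_dist = census
    return UnitProfile(
        unit_id=unit_id,
        specialty_group=group,
        beds=beds,
        census_dist=census_dist,
        acuity_mix_dist=DistributionSpec("fixed", {"mix": list(mix)}),
        specialing_rate=specialing_rate,
        shift_weights=shift_weights,
        rn_skill_mix=rn_skill_mix,
    )


def make_hospital(n_units: int = 4, group: str = "G1", **kwargs) -> HospitalProfile:
    units = [make_unit(unit_id=f"U{i + 1}", group=group, **kwargs) for i in range(n_units)]
    return HospitalProfile("H1", units)
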