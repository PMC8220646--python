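"""Shared domain constants: shifts, roles, care levels, weekdays."""

SHIFTS = ("early", "late", "night")
ROLES = ("RN", "NA")
WEEKDAYS = ("mon", "tue", "wed", "thu", "fri", "sat", "sun")
WEEKEND = ("sat", "sun")
CARE_LEVELS = ("0", "1a", "1b", "2", "3")

# Illustrative care hours per patient per day for each acuity/dependency
# level.  The patient classification system itself does not publish a single
# national multiplier set; these defaults are configurable and every report
# echoes the values actually used.
DEFAULT_CARE_HOURS = {"0": 3.0, "1a": 4.5, "1b": 5.5, "2": 9.0, "3": 14.0}

# One-to-one specialing adds the patient's full daily care time.
SPECIALING_HOURS = 24.0

TEMPORARY_SOURCES = ("bank", "agency")
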