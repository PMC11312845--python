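"""The 16-way demographic stratification used for indirect standardization.

Events and populations are stratified by sex (men/women), race (white /
non-white) and four age groups covering ages 40 and above.  Every record in a
stratified count table maps to exactly one of the 2 x 2 x 4 = 16 strata.
"""

from __future__ import annotations

from .errors import ValidationError

SEXES: tuple[str, ...] = ("men", "women")
RACES: tuple[str, ...] = ("white", "non_white")
AGE_GROUPS: tuple[str, ...] = ("40-59", "60-69", "70-79", "80+")

#: All 16 (sex, race, age_group) strata in canonical order.
STRATA: tuple[tuple[str, str, str], ...] = tuple(
    (s, r, a) for s in SEXES for r in RACES for a in AGE_GROUPS
)

STRATUM_COLUMNS = ("sex", "race", "age_group")

_SEX_ALIASES = {
    "men": "men", "man": "men", "male": "men", "m": "men",
    "women": "women", "woman": "women", "female": "women", "f": "women",
}
_RACE_ALIASES = {
    "white": "white", "w": "white",
    "non_white": "non_white", "non-white": "non_white", "nonwhite": "non_white",
    "non white": "non_white",
}
_AGE_ALIASES = {
    "40-59": "40-59", "40_59": "40-59", "40–59": "40-59",
    "60-69": "60-69", "60_69": "60-69", "60–69": "60-69",
    "70-79": "70-79", "70_79": "70-79", "70–79": "70-79",
    "80+": "80+", "80plus": "80+", ">=80": "80+", "≥80": "80+", "80_plus": "80+",
}


def _normalize(label: object, aliases: dict[str, str], field: str) -> str:
    key = str(label).strip().lower()
    if key not in aliases:
        raise ValidationError(f"unresolvable {field} label: {label!r}")
    return aliases[key]


def normalize_sex(label: object) -> str:
    return _normalize(label, _SEX_ALIASES, "sex")


def normalize_race(label: object) -> str:
    return _normalize(label, _RACE_ALIASES, "race")


def normalize_age_group(label: object) -> str:
    return _normalize(label, _AGE_ALIASES, "age_group")
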