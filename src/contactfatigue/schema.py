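"""Covariate schema for contact-survey regression designs.

The survey design distinguishes three blocks of one-hot coded covariates:

* the *always-in* block — age group (14 levels, with children aged 0-5 split
  by preschool attendance), sex (2) and household size (5), 21 columns in
  total, which every model controls for;
* the *tested* block — employment status (9), COVID-like symptoms (2),
  day of week (2) and urban-rural typology (3), 16 columns, which are
  subject to Bayesian variable selection for contact intensity;
* the *fatigue* block — age group, sex, household size, employment and
  urban type, 33 = 14 + 2 + 5 + 9 + 3 columns, which are tested for
  association with reporting fatigue.

Each factor carries a reference level.  Design matrices keep one column per
category (so block widths are exactly 21 / 16 / 33) but reference-level
columns are structurally zero and excluded from estimation; their effect is
absorbed into the baseline intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

AGE_GROUPS = [
    "0-5 preschool",
    "0-5 home",
    "6-9",
    "10-14",
    "15-19",
    "20-24",
    "25-34",
    "35-44",
    "45-54",
    "55-64",
    "65-69",
    "70-74",
    "75-79",
    "80-84",
]

SEX_LEVELS = ["male", "female"]
HH_LEVELS = ["1", "2", "3", "4", "5+"]
EMPLOYMENT_LEVELS = [
    "full-time",
    "part-time",
    "self-employed",
    "student",
    "retired",
    "long-term sick",
    "unemployed seeking",
    "unemployed not seeking",
    "stay-at-home parent",
]
SYMPTOM_LEVELS = ["no", "yes"]
DAY_LEVELS = ["weekday", "weekend"]
URBAN_LEVELS = ["rural", "intermediate", "urban"]

#: child age bands used at data collection for participants under 18,
#: with inclusive integer bounds for uniform age imputation
CHILD_AGE_BANDS = {
    "0-4": (0, 4),
    "5-9": (5, 9),
    "10-14": (10, 14),
    "15-18": (15, 18),
}

# non-age-group bounds of the modelled age range
AGE_MIN, AGE_MAX = 0, 84


def age_to_group(age: int, attends_preschool: bool = True) -> str:
    """Map an integer age (0-84) to its 14-level age-group label.

    Children aged 0-5 are split by preschool attendance, which is not
    derivable from age alone.
    """
    if not (AGE_MIN <= age <= AGE_MAX):
        raise ValueError(f"age {age} outside supported range {AGE_MIN}-{AGE_MAX}")
    if age <= 5:
        return "0-5 preschool" if attends_preschool else "0-5 home"
    for lab, hi in [
        ("6-9", 9), ("10-14", 14), ("15-19", 19), ("20-24", 24),
        ("25-34", 34), ("35-44", 44), ("45-54", 54), ("55-64", 64),
        ("65-69", 69), ("70-74", 74), ("75-79", 79), ("80-84", 84),
    ]:
        if age <= hi:
            return lab
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class CovariateSchema:
    """Declared factor categories, reference levels and block membership.

    ``always_in`` factors are controlled for in every model; ``tested``
    factors undergo variable selection; ``fatigue_factors`` names the
    factors whose categories form the 33-column reporting-fatigue block.
    """

    always_in: dict[str, list[str]] = field(default_factory=lambda: {
        "age_group": list(AGE_GROUPS),
        "sex": list(SEX_LEVELS),
        "hh_size": list(HH_LEVELS),
    })
    tested: dict[str, list[str]] = field(default_factory=lambda: {
        "employment": list(EMPLOYMENT_LEVELS),
        "symptoms": list(SYMPTOM_LEVELS),
        "day_type": list(DAY_LEVELS),
        "urban_type": list(URBAN_LEVELS),
    })
    reference: dict[str, str] = field(default_factory=lambda: {
        "age_group": "25-34",
        "sex": "male",
        "hh_size": "2",
        "employment": "full-time",
        "symptoms": "no",
        "day_type": "weekday",
        "urban_type": "urban",
    })
    fatigue_factors: tuple[str, ...] = (
        "age_group", "sex", "hh_size", "employment", "urban_type",
    )

    def __post_init__(self) -> None:
        for fac, ref in self.reference.items():
            levels = self.factor_levels(fac)
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not a level of {fac!r}")

    # -- column bookkeeping -------------------------------------------------

    def factor_levels(self, factor: str) -> list[str]:
        if factor in self.always_in:
            return self.always_in[factor]
        if factor in self.tested:
            return self.tested[factor]
        raise KeyError(factor)

    def _columns(self, factors) -> list[tuple[str, str]]:
        return [(f, lev) for f in factors for lev in self.factor_levels(f)]

    @property
    def always_in_columns(self) -> list[tuple[str, str]]:
        return self._columns(self.always_in)

    @property
    def tested_columns(self) -> list[tuple[str, str]]:
        return self._columns(self.tested)

    @property
    def fatigue_columns(self) -> list[tuple[str, str]]:
        return self._columns(self.fatigue_factors)

    def column_names(self, block: str) -> list[str]:
        cols = {
            "always_in": self.always_in_columns,
            "tested": self.tested_columns,
            "fatigue": self.fatigue_columns,
        }[block]
        return [f"{f}:{lev}" for f, lev in cols]

    def estimable_mask(self, block: str) -> list[bool]:
        """True for columns whose coefficient is sampled.

        Reference levels of the always-in and tested blocks are absorbed
        into the intercept; the fatigue block measures reductions relative
        to first-time participants, so all 33 of its columns are estimable.
        """
        if block == "fatigue":
            return [True] * len(self.fatigue_columns)
        cols = {
            "always_in": self.always_in_columns,
            "tested": self.tested_columns,
        }[block]
        return [lev != self.reference[f] for f, lev in cols]


def schema_from_yaml(path) -> CovariateSchema:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    kwargs = {}
    for key in ("always_in", "tested", "reference"):
        if key in raw:
            kwargs[key] = raw[key]
    if "fatigue_factors" in raw:
        kwargs["fatigue_factors"] = tuple(raw["fatigue_factors"])
    return CovariateSchema(**kwargs)


def schema_to_yaml(schema: CovariateSchema, path) -> None:
    payload = {
        "always_in": schema.always_in,
        "tested": schema.tested,
        "reference": schema.reference,
        "fatigue_factors": list(schema.fatigue_factors),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
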