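"""Synthetic multi-wave contact-survey cohorts with known ground truth.

No public release of the COVIMOD records exists, so every downstream stage
is exercised on synthetic panels that emulate the study design: a wave
quota of participants, Bernoulli retention of the previous wave's panel
with fresh recruitment back up to quota, covariate-driven log-linear
contact intensities, a smooth calendar-time trend, multiplicative
reporting fatigue that decays with repeat count toward an asymptote, and
negative-binomial observation noise (variance lambda + lambda^2 / phi).

Default sizes mirror the longitudinal analysis window of the emulated
study: 10 waves at a quota of ~1,283 with retention 0.9, giving roughly
2,450 unique participants and 12.8k records.  The default fatigue truth is
a single Hill curve with gamma 0.88, zeta -1.55, eta 0.94 — the regime the
recovery tests target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from . import data_model
from .data_model import RECORD_COLUMNS
from .fatigue import HillParams, hill_effect
from .schema import CovariateSchema, age_to_group

# sampling weights for participant covariates, loosely matched to the
# composition of a German online panel
AGE_GROUP_WEIGHTS = {
    "0-5 preschool": 61, "0-5 home": 17, "6-9": 34, "10-14": 80,
    "15-19": 103, "20-24": 106, "25-34": 216, "35-44": 163, "45-54": 271,
    "55-64": 318, "65-69": 311, "70-74": 118, "75-79": 48, "80-84": 5,
}
AGE_GROUP_RANGES = {
    "0-5 preschool": (0, 5), "0-5 home": (0, 5), "6-9": (6, 9),
    "10-14": (10, 14), "15-19": (15, 19), "20-24": (20, 24),
    "25-34": (25, 34), "35-44": (35, 44), "45-54": (45, 54),
    "55-64": (55, 64), "65-69": (65, 69), "70-74": (70, 74),
    "75-79": (75, 79), "80-84": (80, 84),
}
HH_WEIGHTS = {"1": 0.26, "2": 0.34, "3": 0.17, "4": 0.15, "5+": 0.08}
URBAN_WEIGHTS = {"rural": 0.15, "intermediate": 0.38, "urban": 0.47}
EMPLOYMENT_BY_AGE = {
    # (lo, hi): weights over employment categories; under-15s have none
    (15, 19): {"student": 0.90, "full-time": 0.05, "part-time": 0.05},
    (20, 24): {"student": 0.35, "full-time": 0.35, "part-time": 0.10,
               "unemployed seeking": 0.10, "self-employed": 0.05,
               "unemployed not seeking": 0.05},
    (25, 64): {"full-time": 0.45, "part-time": 0.18, "self-employed": 0.08,
               "stay-at-home parent": 0.05, "long-term sick": 0.03,
               "unemployed seeking": 0.06, "unemployed not seeking": 0.03,
               "retired": 0.07, "student": 0.05},
    (65, 84): {"retired": 0.92, "part-time": 0.03, "self-employed": 0.03,
               "full-time": 0.02},
}

DEFAULT_EFFECTS = {
    "sex:female": -0.05,
    "hh_size:1": -0.15, "hh_size:3": 0.08, "hh_size:4": 0.12, "hh_size:5+": 0.18,
    "employment:student": 0.26, "employment:full-time": 0.10,
    "employment:self-employed": -0.10, "employment:retired": -0.22,
    "employment:stay-at-home parent": -0.25, "employment:long-term sick": -0.30,
    "employment:unemployed seeking": -0.15,
    "day_type:weekend": 0.15,
    "urban_type:intermediate": 0.08,
}

DEFAULT_HILL = HillParams(gamma=0.88, zeta=-1.55, eta=0.94)


def default_age_profile(age):
    """Smooth bimodal log-scale age effect: school-age and mid-life peaks."""
    a = np.asarray(age, dtype=float)
    return (0.5 * np.exp(-((a - 9.0) / 9.0) ** 2)
            + 0.3 * np.exp(-((a - 45.0) / 16.0) ** 2)
            - 0.004 * a)


def default_calendar_trend(t):
    """Sinusoid plus drift on standardized time in [0, 1]."""
    t = np.asarray(t, dtype=float)
    return 0.15 * np.sin(2.0 * np.pi * t) + 0.10 * t


@dataclass
class GeneratorConfig:
    """Ground-truth generative settings for a synthetic panel."""

    n_per_wave: int = 1283
    n_waves: int = 10
    retention: float = 0.9
    recruit_to_quota: bool = True
    beta0: float = float(np.log(2.5))
    effects: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    age_profile: Callable | None = default_age_profile
    calendar_trend: Callable | None = default_calendar_trend
    #: single HillParams applied to everyone, or a mapping from fatigue
    #: feature columns ("factor:level") to per-feature HillParams
    fatigue: HillParams | Mapping[str, HillParams] | None = DEFAULT_HILL
    phi: float = 2.0
    #: "negbin" (default) or "poisson"; the Poisson option matches the
    #: observation model of the single-wave selection analyses exactly
    observation: str = "negbin"
    truncate: bool = True
    #: optional override of the age-dependent employment composition for
    #: all participants aged 15+; e.g. uniform weights give the balanced
    #: design used in selection operating-characteristics experiments
    employment_weights: Mapping[str, float] | None = None
    #: optional override of the age-group composition (same purpose)
    age_group_weights: Mapping[str, float] | None = None
    #: optional override of the urban-rural composition (same purpose)
    urban_weights: Mapping[str, float] | None = None
    wave_window_days: int = 4
    wave_spacing_days: int = 14
    weekend_prob: float = 0.15
    symptom_prob: float = 0.2
    rng_seed: int = 0

    def __post_init__(self):
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.observation not in ("negbin", "poisson"):
            raise ValueError("observation must be 'negbin' or 'poisson'")
        if not (0.0 <= self.retention <= 1.0):
            raise ValueError("retention must be in [0, 1]")
        if self.n_waves > 1 and self.retention == 0.0 and not self.recruit_to_quota:
            raise ValueError("infeasible config: full dropout with no recruitment")
        schema = CovariateSchema()
        known = set(schema.column_names("tested") + schema.column_names("always_in"))
        unknown = set(self.effects) - known
        if unknown:
            raise ValueError(f"effect keys not in schema: {sorted(unknown)}")


@dataclass
class PopulationMargins:
    """Census cell counts over age group x sex x household size."""

    cells: pd.DataFrame  # columns: age_group, sex, hh_size, count

    def __post_init__(self):
        if (self.cells["count"] < 0).any():
            raise ValueError("margin counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.cells["count"].sum())


# ---------------------------------------------------------------------------
# panel generation


def _draw_weighted(rng, options_weights: Mapping[str, float], size=None):
    keys = list(options_weights)
    w = np.array([options_weights[k] for k in keys], dtype=float)
    w /= w.sum()
    return rng.choice(keys, size=size, p=w)


def _new_participant(rng, pid: str, employment_weights=None,
                     age_group_weights=None, urban_weights=None) -> dict:
    group = _draw_weighted(rng, age_group_weights or AGE_GROUP_WEIGHTS)
    lo, hi = AGE_GROUP_RANGES[group]
    age = int(rng.integers(lo, hi + 1))
    employment = None
    if age >= 15:
        if employment_weights is not None:
            employment = str(_draw_weighted(rng, employment_weights))
        else:
            for (a, b), weights in EMPLOYMENT_BY_AGE.items():
                if a <= age <= b:
                    employment = str(_draw_weighted(rng, weights))
                    break
    return {
        "part_id": pid,
        "age": age,
        "attends_preschool": group == "0-5 preschool",
        "sex": str(rng.choice(["male", "female"])),
        "hh_size": str(_draw_weighted(rng, HH_WEIGHTS)),
        "employment": employment,
        "urban_type": str(_draw_weighted(rng, urban_weights or URBAN_WEIGHTS)),
    }


def generate_panel(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate the multi-wave panel structure (covariates and repeat
    counts, no contact counts yet).

    Participants persist across waves under Bernoulli retention; fresh
    recruitment tops the panel back up to the wave quota.  Stable
    covariates are drawn once at recruitment; survey-day covariates
    (date, day of week, symptoms) are redrawn each wave.
    """
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    roster: list[dict] = []
    next_id = 0
    rows = []
    for w in range(1, config.n_waves + 1):
        if w == 1:
            current = []
        else:
            current = [p for p in roster if rng.random() < config.retention]
        n_new = max(config.n_per_wave - len(current), 0) if (
            config.recruit_to_quota or w == 1) else 0
        for _ in range(n_new):
            p = _new_participant(rng, f"p{next_id:06d}", config.employment_weights,
                                 config.age_group_weights, config.urban_weights)
            p["n_prior"] = 0
            next_id += 1
            current.append(p)
        day0 = (w - 1) * config.wave_spacing_days
        for p in current:
            rows.append({
                "wave": w,
                "part_id": p["part_id"],
                "repeat_count": p["n_prior"],
                "age": float(p["age"]),
                "child_age_band": None,
                "attends_preschool": p["attends_preschool"],
                "sex": p["sex"],
                "hh_size": p["hh_size"],
                "employment": p["employment"],
                "symptoms": "yes" if rng.random() < config.symptom_prob else "no",
                "day_type": "weekend" if rng.random() < config.weekend_prob else "weekday",
                "urban_type": p["urban_type"],
                "y": 0,
                "date": int(day0 + rng.integers(0, config.wave_window_days)),
            })
            p["n_prior"] += 1
        roster = current
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def generate_wave(config: GeneratorConfig, repeat_probs: Mapping[int, float],
                  n: int, seed: int, wave: int = 21) -> pd.DataFrame:
    """Generate a single-wave cross-section with a prescribed repeat-count
    mixture, emulating a late survey wave that pools fresh recruits with
    long-standing panel members."""
    rng = np.random.default_rng(seed)
    rs = np.array(sorted(repeat_probs))
    p = np.array([repeat_probs[r] for r in rs], dtype=float)
    p /= p.sum()
    day0 = (wave - 1) * config.wave_spacing_days
    rows = []
    for i in range(n):
        part = _new_participant(rng, f"w{wave}p{i:06d}", config.employment_weights,
                                config.age_group_weights, config.urban_weights)
        rows.append({
            "wave": wave, "part_id": part["part_id"],
            "repeat_count": int(rng.choice(rs, p=p)),
            "age": float(part["age"]), "child_age_band": None,
            "attends_preschool": part["attends_preschool"],
            "sex": part["sex"], "hh_size": part["hh_size"],
            "employment": part["employment"],
            "symptoms": "yes" if rng.random() < config.symptom_prob else "no",
            "day_type": "weekend" if rng.random() < config.weekend_prob else "weekday",
            "urban_type": part["urban_type"],
            "y": 0,
            "date": int(day0 + rng.integers(0, config.wave_window_days)),
        })
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


# ---------------------------------------------------------------------------
# contact simulation


def feature_indicator(records: pd.DataFrame, column: str) -> np.ndarray:
    """0/1 indicator for a "factor:level" feature column."""
    factor, level = column.split(":", 1)
    if factor == "age_group":
        vals = [age_to_group(int(a), bool(p)) for a, p in
                zip(records["age"], records["attends_preschool"])]
        return np.array([v == level for v in vals], dtype=float)
    return (records[factor] == level).to_numpy(dtype=float)


def true_log_intensity(records: pd.DataFrame, config: GeneratorConfig,
                       include_fatigue: bool = True) -> np.ndarray:
    """Ground-truth log mean contact intensity for each record."""
    eta = np.full(len(records), config.beta0)
    for col, eff in config.effects.items():
        if eff != 0.0:
            eta += eff * feature_indicator(records, col)
    if config.age_profile is not None:
        eta += config.age_profile(records["age"].to_numpy(dtype=float))
    if config.calendar_trend is not None:
        dates = records["date"].to_numpy(dtype=float)
        span = max(config.n_waves * config.wave_spacing_days - 1, 1)
        eta += config.calendar_trend(dates / span)
    if include_fatigue and config.fatigue is not None:
        r = records["repeat_count"].to_numpy(dtype=int)
        if isinstance(config.fatigue, HillParams):
            eta += hill_effect(r, config.fatigue)
        else:
            for col, params in config.fatigue.items():
                eta += feature_indicator(records, col) * hill_effect(r, params)
    return eta


def simulate_contacts(panel: pd.DataFrame, config: GeneratorConfig,
                      seed: int | None = None) -> pd.DataFrame:
    """Fill contact counts from the negative-binomial observation model."""
    rng = np.random.default_rng(config.rng_seed + 1 if seed is None else seed)
    lam = np.exp(true_log_intensity(panel, config))
    if config.observation == "poisson":
        y = rng.poisson(lam)
    else:
        p = config.phi / (config.phi + lam)
        y = rng.negative_binomial(config.phi, p)
    out = panel.copy()
    out["y"] = data_model.truncate_contacts(y) if config.truncate else y
    return out


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Panel structure plus simulated contacts in one call."""
    base = config.rng_seed if seed is None else seed
    panel = generate_panel(config, seed=base)
    return simulate_contacts(panel, config, seed=base + 1)


# ---------------------------------------------------------------------------
# population margins


def generate_margins(records: pd.DataFrame, total: float = 83_000_000,
                     skew: float = 0.0, seed: int = 0) -> PopulationMargins:
    """Population margins over age group x sex x household size.

    ``skew`` = 0 gives margins proportional to the sample composition;
    positive values multiply each cell by a log-normal factor so that
    post-stratification weighting is non-trivial.
    """
    rng = np.random.default_rng(seed)
    groups = [age_to_group(int(a), bool(p)) for a, p in
              zip(records["age"], records["attends_preschool"])]
    tab = pd.DataFrame({
        "age_group": groups,
        "sex": records["sex"],
        "hh_size": records["hh_size"],
    }).value_counts().rename("count").reset_index()
    factors = np.exp(skew * rng.standard_normal(len(tab))) if skew > 0 else 1.0
    counts = tab["count"].to_numpy(dtype=float) * factors
    tab["count"] = counts * (total / counts.sum())
    return PopulationMargins(cells=tab)


# ---------------------------------------------------------------------------
# truth bookkeeping


def write_truth(config: GeneratorConfig, path) -> None:
    """Record all generative parameters for later recovery checks."""
    payload = asdict(config)
    payload["age_profile"] = None if config.age_profile is None else "default_age_profile"
    payload["calendar_trend"] = (None if config.calendar_trend is None
                                 else "default_calendar_trend")
    if isinstance(config.fatigue, HillParams):
        payload["fatigue"] = asdict(config.fatigue)
    elif config.fatigue is not None:
        payload["fatigue"] = {k: asdict(v) for k, v in config.fatigue.items()}
    payload["effects"] = dict(config.effects)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
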