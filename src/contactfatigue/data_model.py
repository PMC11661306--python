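"""Participant records, survey-table I/O and preprocessing.

The canonical in-memory container is a pandas ``DataFrame`` with one row per
participant-wave response (columns in :data:`RECORD_COLUMNS`); the
:class:`ParticipantRecord` dataclass mirrors a single row for typed access.

Preprocessing follows the survey-analysis protocol:

1. drop responses missing sex or any age information,
2. impute exact ages for children reported in coarse age bands by a
   discrete-uniform draw within the band (seeded per participant so the
   imputation is reproducible),
3. truncate reported contact totals at 30 to blunt extreme outliers,
4. derive each response's repeat count ``r`` = number of earlier waves in
   which the same participant appears (``r = 0`` marks first-time
   participation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .schema import CHILD_AGE_BANDS, CovariateSchema, age_to_group

logger = logging.getLogger(__name__)

#: contact totals above this are truncated
CONTACT_TRUNCATION = 30

#: columns of a processed record frame
RECORD_COLUMNS = [
    "wave", "part_id", "repeat_count", "age", "child_age_band",
    "attends_preschool", "sex", "hh_size", "employment", "symptoms",
    "day_type", "urban_type", "y", "date",
]

PARTICIPANT_FILE_COLUMNS = [
    "part_id", "wave", "date", "age", "child_age_band", "attends_preschool",
    "sex", "hh_size", "employment", "symptoms", "day_type", "urban_type",
]

CONTACT_FILE_COLUMNS = ["part_id", "wave"]


class SchemaError(ValueError):
    """A mandatory column is missing or a category is undeclared."""


class IntegrityError(ValueError):
    """Duplicate or internally inconsistent survey rows."""


@dataclass
class ParticipantRecord:
    """One survey response.

    ``repeat_count`` is the number of prior waves in which the participant
    appears (0 = first-time); ``y`` is the per-day contact total after
    aggregation; ``date`` is an integer calendar-day index.
    """

    wave: int
    part_id: str
    repeat_count: int = 0
    age: float | None = None
    child_age_band: str | None = None
    attends_preschool: bool = True
    sex: str | None = None
    hh_size: str | None = None
    employment: str | None = None
    symptoms: str = "no"
    day_type: str = "weekday"
    urban_type: str = "urban"
    y: int = 0
    date: int = 0


def records_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    frame = pd.DataFrame([vars(r) for r in records])
    return frame.reindex(columns=RECORD_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[ParticipantRecord]:
    return [ParticipantRecord(**{k: (None if pd.isna(v) else v) for k, v in row.items()})
            for row in frame[RECORD_COLUMNS].to_dict("records")]


# ---------------------------------------------------------------------------
# survey-table I/O

def read_survey_tables(participant_path, contact_path) -> pd.DataFrame:
    """Read long-format participant and contact tables into a record frame.

    The contact file holds one row per itemised contact keyed by
    ``(part_id, wave)``; the participant file may additionally carry a
    ``group_contacts`` column of aggregate totals reported in bulk.  A
    participant-wave's contact count is the number of itemised rows plus
    any aggregate total.
    """
    parts = pd.read_csv(participant_path)
    missing = [c for c in ("part_id", "wave", "sex", "hh_size") if c not in parts.columns]
    if missing:
        raise SchemaError(f"participant file missing mandatory column(s): {missing}")
    dupes = parts.duplicated(subset=["part_id", "wave"])
    if dupes.any():
        bad = parts.loc[dupes, ["part_id", "wave"]].iloc[0]
        raise IntegrityError(
            f"duplicate participant rows for (wave={bad['wave']}, part_id={bad['part_id']})"
        )

    contacts = pd.read_csv(contact_path)
    if len(contacts) and any(c not in contacts.columns for c in CONTACT_FILE_COLUMNS):
        raise SchemaError(f"contact file must have columns {CONTACT_FILE_COLUMNS}")
    if len(contacts):
        itemised = contacts.groupby(["part_id", "wave"]).size()
    else:
        itemised = pd.Series(dtype=int)

    frame = parts.copy()
    key = pd.MultiIndex.from_frame(frame[["part_id", "wave"]])
    frame["y"] = itemised.reindex(key, fill_value=0).to_numpy()
    if "group_contacts" in frame.columns:
        frame["y"] = frame["y"] + frame["group_contacts"].fillna(0).astype(int)
        frame = frame.drop(columns=["group_contacts"])
    for col in RECORD_COLUMNS:
        if col not in frame.columns:
            frame[col] = np.nan if col not in ("repeat_count", "date") else 0
    frame["attends_preschool"] = frame["attends_preschool"].fillna(True).astype(bool)
    return frame[RECORD_COLUMNS].reset_index(drop=True)


def write_survey_tables(records: pd.DataFrame, participant_path, contact_path) -> None:
    """Write a record frame back out as participant + contact CSVs.

    Contact totals are emitted through the ``group_contacts`` aggregate
    column (no per-contact attributes are modelled), so reading the pair
    back reproduces the records exactly.
    """
    parts = records.copy()
    parts["group_contacts"] = parts["y"]
    parts = parts.drop(columns=["y"])
    parts.to_csv(participant_path, index=False)
    pd.DataFrame(columns=CONTACT_FILE_COLUMNS).to_csv(contact_path, index=False)


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"processed record file missing column(s): {missing}")
    frame["attends_preschool"] = frame["attends_preschool"].astype(bool)
    return frame[RECORD_COLUMNS]


# ---------------------------------------------------------------------------
# preprocessing

def filter_missing_demographics(records: pd.DataFrame) -> pd.DataFrame:
    """Drop responses without disclosed sex or any age information."""
    has_sex = records["sex"].notna()
    has_age = records["age"].notna() | records["child_age_band"].notna()
    keep = has_sex & has_age
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropping %d records with undisclosed age or sex", n_drop)
    return records.loc[keep].reset_index(drop=True)


def impute_child_age(band: str, rng_seed: int) -> int:
    """Draw an exact age uniformly from a child age band (bounds inclusive)."""
    if band not in CHILD_AGE_BANDS:
        raise ValueError(f"unknown child age band {band!r}")
    lo, hi = CHILD_AGE_BANDS[band]
    return int(np.random.default_rng(rng_seed).integers(lo, hi + 1))


def impute_ages(records: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Fill exact ages for banded children, seeded per participant id.

    The per-participant seeding keeps a child's imputed age constant
    across waves and independent of row order.
    """
    out = records.copy()
    need = out["age"].isna() & out["child_age_band"].notna()
    for idx in out.index[need]:
        pid = out.at[idx, "part_id"]
        sub = (seed + (hash(str(pid)) & 0x7FFFFFFF)) % (2**31)
        out.at[idx, "age"] = impute_child_age(out.at[idx, "child_age_band"], sub)
    out["age"] = out["age"].astype(float)
    return out


def truncate_contacts(y):
    """Truncate a contact total (scalar or array) at 30."""
    arr = np.asarray(y)
    if np.any(arr < 0):
        raise ValueError("contact counts must be non-negative")
    out = np.minimum(arr, CONTACT_TRUNCATION)
    return int(out) if np.isscalar(y) or arr.ndim == 0 else out


def compute_repeat_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Fill ``repeat_count`` = number of earlier waves containing the id."""
    out = records.sort_values(["part_id", "wave"], kind="stable").copy()
    out["repeat_count"] = out.groupby("part_id").cumcount()
    return out.sort_index().reset_index(drop=True)


def preprocess(records: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Full preprocessing chain: filter, impute, truncate, repeat counts."""
    out = filter_missing_demographics(records)
    out = impute_ages(out, seed=seed)
    out["y"] = truncate_contacts(out["y"].to_numpy())
    out = compute_repeat_counts(out)
    return out


# ---------------------------------------------------------------------------
# design matrices

@dataclass
class WaveDataset:
    """Records plus the one-hot design blocks used by the models.

    ``U`` (n x 21) always-in, ``V`` (n x 16) tested, ``W`` (n x 33)
    fatigue block; reference-level columns are identically zero.
    """

    records: pd.DataFrame
    schema: CovariateSchema
    U: np.ndarray
    V: np.ndarray
    W: np.ndarray

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def y(self) -> np.ndarray:
        return self.records["y"].to_numpy(dtype=int)

    @property
    def r(self) -> np.ndarray:
        return self.records["repeat_count"].to_numpy(dtype=int)

    @property
    def dates(self) -> np.ndarray:
        return self.records["date"].to_numpy(dtype=float)

    def metadata(self) -> dict:
        rec = self.records
        return {
            "waves": sorted(rec["wave"].unique().tolist()),
            "n_records": int(len(rec)),
            "n_first_time": int((rec["repeat_count"] == 0).sum()),
            "n_repeating": int((rec["repeat_count"] > 0).sum()),
            "date_range": (float(rec["date"].min()), float(rec["date"].max()))
            if len(rec) else (None, None),
        }


def _one_hot(records: pd.DataFrame, columns: Sequence[tuple[str, str]],
             schema: CovariateSchema, drop_reference: bool = True) -> np.ndarray:
    n = len(records)
    X = np.zeros((n, len(columns)))
    col_index = {fc: j for j, fc in enumerate(columns)}
    factors = {f for f, _ in columns}
    age_groups = None
    if "age_group" in factors:
        ages = records["age"].to_numpy()
        pres = records["attends_preschool"].to_numpy(dtype=bool)
        age_groups = [age_to_group(int(a), bool(p)) for a, p in zip(ages, pres)]
    for f in factors:
        if f == "age_group":
            values = age_groups
        else:
            values = records[f].tolist()
        levels = set(schema.factor_levels(f))
        ref = schema.reference[f]
        for i, v in enumerate(values):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue  # absent factor (e.g. employment of young children)
            if v not in levels:
                pid = records.iloc[i]["part_id"]
                raise SchemaError(
                    f"record part_id={pid!r}: category {v!r} not declared for factor {f!r}"
                )
            if drop_reference and v == ref:
                continue  # reference column stays structurally zero
            X[i, col_index[(f, v)]] = 1.0
    return X


def split_waves(records: pd.DataFrame,
                schema: CovariateSchema | None = None) -> list[WaveDataset]:
    """One :class:`WaveDataset` per wave, in ascending wave order."""
    return [build_design(records[records["wave"] == w].reset_index(drop=True), schema)
            for w in sorted(records["wave"].unique())]


def build_design(records: pd.DataFrame, schema: CovariateSchema | None = None) -> WaveDataset:
    """Build the 21 / 16 / 33-column one-hot blocks for a record frame.

    Requires preprocessed records (ages imputed).  Reference-level columns
    are present but zero; :meth:`CovariateSchema.estimable_mask` identifies
    the columns whose coefficients are sampled.
    """
    schema = schema or CovariateSchema()
    if records["age"].isna().any():
        raise ValueError("records must have imputed ages before design construction")
    U = _one_hot(records, schema.always_in_columns, schema)
    V = _one_hot(records, schema.tested_columns, schema)
    # fatigue effects are measured relative to first-time participants, not
    # to a reference category, so every fatigue column is a true indicator
    W = _one_hot(records, schema.fatigue_columns, schema, drop_reference=False)
    return WaveDataset(records=records.reset_index(drop=True), schema=schema, U=U, V=V, W=W)
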