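"""Post-stratified population-level contact-intensity estimates.

Sample-based estimates are reweighted to census margins over age group x
sex x household size: each record's weight is proportional to its cell's
population share divided by its sample share, normalized to mean one.
Population and subgroup intensities are summarised per posterior draw as
the weighted mean of the *fatigue-free* fitted intensities (the Hill term
evaluated at r = 0), which is what de-biasing means operationally: the
contact intensity the sample would have reported without reporting
fatigue.  A simple participant-level bootstrap of first-time responses
serves as the model-free comparator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .debias import record_log_intensity
from .sampling import PosteriorSummary
from .synthetic import PopulationMargins
from .schema import age_to_group

CELL_FACTORS = ["age_group", "sex", "hh_size"]


@dataclass(frozen=True)
class WeightedEstimate:
    """Point estimate (contacts/person/day) with a 95% interval."""

    point: float
    lower: float
    upper: float
    wave: int | None = None
    subgroup: str = "population"
    method: str = "adjusted"

    def __post_init__(self):
        if not (self.lower <= self.point <= self.upper):
            raise ValueError("interval bounds must bracket the point estimate")


def _cells(records: pd.DataFrame) -> pd.Series:
    groups = [age_to_group(int(a), bool(p)) for a, p in
              zip(records["age"], records["attends_preschool"])]
    return pd.Series(
        [f"{g}|{s}|{h}" for g, s, h in
         zip(groups, records["sex"], records["hh_size"])],
        index=records.index,
    )


def poststrat_weights(records: pd.DataFrame, margins: PopulationMargins) -> np.ndarray:
    """Per-record post-stratification weights, normalized to mean one.

    Every sampled cell must have a margin cell.  Cells present in the
    margins but empty in the sample cannot be represented; their mass is
    redistributed by renormalizing population shares over observed cells
    (with a warning), the simplest collapse scheme.
    """
    cell = _cells(records)
    sample_share = cell.value_counts(normalize=True)

    key = margins.cells.apply(
        lambda row: f"{row['age_group']}|{row['sex']}|{row['hh_size']}", axis=1)
    pop = pd.Series(margins.cells["count"].to_numpy(dtype=float), index=key)
    pop = pop.groupby(level=0).sum()

    missing = set(sample_share.index) - set(pop.index)
    if missing:
        raise ValueError(f"margins lack cells present in the sample: {sorted(missing)[:5]}")
    empty = set(pop.index) - set(sample_share.index)
    if empty:
        warnings.warn(
            f"{len(empty)} margin cells are empty in the sample; "
            "their population mass is redistributed over observed cells",
            stacklevel=2)
        pop = pop[pop.index.isin(sample_share.index)]
    pop_share = pop / pop.sum()

    w = (pop_share / sample_share).reindex(cell.to_numpy()).to_numpy()
    return w / w.mean()


def _summarize(draw_values: np.ndarray, **fields) -> WeightedEstimate:
    lo, med, hi = np.percentile(draw_values, [2.5, 50, 97.5])
    return WeightedEstimate(point=float(med), lower=float(lo), upper=float(hi), **fields)


def population_mean_intensity(summary: PosteriorSummary, records: pd.DataFrame,
                              weights: np.ndarray | None = None,
                              method: str = "adjusted",
                              fatigue_free: bool = True,
                              wave: int | None = None) -> WeightedEstimate:
    """Post-stratified population mean contact intensity for one wave.

    Per posterior draw, the weighted mean of fitted intensities with the
    fatigue term at its r = 0 value; summarised by the posterior median
    and central 95% interval.
    """
    if weights is None:
        weights = np.ones(len(records))
    weights = np.asarray(weights, dtype=float)
    lam = np.exp(record_log_intensity(summary, records, fatigue_free=fatigue_free))
    means = lam @ (weights / weights.sum())
    if wave is None and len(records):
        wave = int(records["wave"].iloc[0])
    return _summarize(means, wave=wave, subgroup="population", method=method)


def subgroup_estimates(summary: PosteriorSummary, records: pd.DataFrame,
                       subgroups: dict[str, dict], weights: np.ndarray | None = None,
                       method: str = "adjusted") -> list[WeightedEstimate]:
    """Post-stratified intensity estimates for record-filter subgroups.

    ``subgroups`` maps labels to covariate predicates, e.g.
    ``{"men 45-54, hh 3": {"sex": "male", "age_group": "45-54", "hh_size": "3"}}``.
    An empty predicate selects the whole population, recovering
    :func:`population_mean_intensity`.
    """
    if weights is None:
        weights = np.ones(len(records))
    weights = np.asarray(weights, dtype=float)
    lam = np.exp(record_log_intensity(summary, records))
    groups = np.array([age_to_group(int(a), bool(p)) for a, p in
                       zip(records["age"], records["attends_preschool"])])
    wave = int(records["wave"].iloc[0]) if len(records) else None
    out = []
    for label, pred in subgroups.items():
        mask = np.ones(len(records), dtype=bool)
        for factor, level in pred.items():
            if factor == "age_group":
                mask &= groups == level
            elif factor in records.columns:
                mask &= (records[factor] == level).to_numpy()
            else:
                raise ValueError(f"subgroup {label!r} references unknown factor {factor!r}")
        if not mask.any():
            raise ValueError(f"subgroup {label!r} matches no records")
        w = weights[mask]
        means = lam[:, mask] @ (w / w.sum())
        out.append(_summarize(means, wave=wave, subgroup=label, method=method))
    return out


def bootstrap_mean(records: pd.DataFrame, B: int = 1000, seed: int = 0,
                   weights: np.ndarray | None = None,
                   wave: int | None = None) -> WeightedEstimate:
    """Simple participant-level bootstrap of first-time responses.

    ``B`` resamples with replacement; the point estimate is the mean of
    the resample (weighted) means and the interval their 2.5/97.5
    percentiles.
    """
    if (records["repeat_count"] != 0).any():
        raise ValueError("bootstrap comparator uses first-time participants only")
    if B < 100:
        warnings.warn("fewer than 100 bootstrap resamples; intervals will be noisy",
                      stacklevel=2)
    y = records["y"].to_numpy(dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(y), size=(B, len(y)))
    wm = w[idx]
    means = (y[idx] * wm).sum(axis=1) / wm.sum(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    point = float(means.mean())
    if wave is None and len(records):
        wave = int(records["wave"].iloc[0])
    return WeightedEstimate(point=point, lower=min(float(lo), point),
                            upper=max(float(hi), point), wave=wave,
                            subgroup="population", method="bootstrap")


REPORT_COLUMNS = ["wave", "method", "subgroup", "point", "lower", "upper"]


def write_report(estimates: list[WeightedEstimate], path,
                 stringency: pd.DataFrame | None = None) -> pd.DataFrame:
    """Write a tidy wave x method x subgroup estimates table.

    If a stringency table (columns ``wave``, ``index``) is supplied, its
    index is merged in as an overlay column.
    """
    frame = pd.DataFrame(
        [{"wave": e.wave, "method": e.method, "subgroup": e.subgroup,
          "point": e.point, "lower": e.lower, "upper": e.upper}
         for e in estimates],
        columns=REPORT_COLUMNS,
    )
    if stringency is not None:
        frame = frame.merge(stringency.rename(columns={"index": "stringency"}),
                            on="wave", how="left")
    frame.to_csv(path, index=False)
    return frame
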