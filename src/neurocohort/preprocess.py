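"""Cohort preprocessing: exclusion rules, imputation, log-transform screen.

Order of operations mirrors the analysis design: participants with too
much missing data are dropped first, then remaining missing cells are
filled with childhood-group means (education with the group median
class), and finally each measure is screened for non-normality and
log-transformed when the screen fails.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, GROUPS

__all__ = [
    "ExclusionRecord",
    "PreprocessError",
    "apply_exclusions",
    "impute_group_means",
    "impute_education_median",
    "screen_and_transform",
    "MISSING_FRACTION_THRESHOLD",
]

log = logging.getLogger(__name__)

#: Participants missing at least this fraction of the battery are dropped.
#: With a 21-measure battery the smallest qualifying count is 4 (19.05%).
MISSING_FRACTION_THRESHOLD = 0.19

#: Missing at least this many of a domain's 3 measures also drops a
#: participant (the domain's 2-of-3 deficit rule would be undefined).
DOMAIN_MISSING_THRESHOLD = 2


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class ExclusionRecord:
    participant_id: str
    reason: str


def apply_exclusions(
    cohort: CohortTable,
) -> tuple[CohortTable, list[ExclusionRecord]]:
    """Drop participants with >=19% of measures missing or >=2 of 3
    measures missing within any single domain.

    Returns the retained cohort and one record per excluded participant
    (a participant failing both rules gets the battery-wide reason).
    Idempotent: imputation-free re-application excludes nobody new.
    """
    battery = cohort.battery
    miss = cohort.scores.isna()
    n_measures = len(battery.measure_names)
    excluded: list[ExclusionRecord] = []
    drop = np.zeros(len(cohort), dtype=bool)
    frac = miss.sum(axis=1) / n_measures
    for i in range(len(cohort)):
        pid = cohort.data["id"].iloc[i]
        if frac.iloc[i] >= MISSING_FRACTION_THRESHOLD:
            drop[i] = True
            excluded.append(ExclusionRecord(
                pid, f"≥19% of measures missing "
                     f"({int(miss.iloc[i].sum())}/{n_measures})"))
            continue
        for d in battery.domains:
            k = int(miss.iloc[i][list(d.measures)].sum())
            if k >= DOMAIN_MISSING_THRESHOLD:
                drop[i] = True
                excluded.append(ExclusionRecord(
                    pid, f"{k}/3 measures missing in domain {d.name}"))
                break
    retained = cohort.with_data(
        cohort.data.loc[~drop].reset_index(drop=True))
    return retained, excluded


def impute_group_means(cohort: CohortTable) -> CohortTable:
    """Fill each missing score with the mean of the participant's
    childhood group on that measure.

    Leaves every observed cell, ASRS, and demographics untouched; the
    per-group mean of every measure is exactly preserved.  Raises if a
    group has no observed value at all for some measure.
    """
    data = cohort.data.copy()
    names = cohort.battery.measure_names
    for g in GROUPS:
        in_g = data["group"] == g
        if not in_g.any():
            continue
        block = data.loc[in_g, names]
        means = block.mean()
        need = block.isna().any()
        dead = [m for m in names if need[m] and math.isnan(means[m])]
        if dead:
            raise PreprocessError(
                f"group {g!r}: no observed values to impute measure(s) {dead}"
            )
        data.loc[in_g, names] = block.fillna(means)
    return cohort.with_data(data)


def impute_education_median(cohort: CohortTable) -> CohortTable:
    """Fill missing education class with the within-group median class.

    A median falling between two classes (even group size) is rounded
    half up to the higher class.
    """
    data = cohort.data.copy()
    for g in GROUPS:
        in_g = data["group"] == g
        if not in_g.any():
            continue
        vals = data.loc[in_g, "education"]
        if not vals.isna().any():
            continue
        obs = vals.dropna()
        if obs.empty:
            raise PreprocessError(
                f"group {g!r}: education missing for every participant")
        med = float(np.median(obs))
        data.loc[in_g, "education"] = vals.fillna(math.floor(med + 0.5))
    return cohort.with_data(data)


def _needs_log(values: np.ndarray, groups: np.ndarray,
               alpha: float) -> bool:
    """Shapiro-Wilk on group-mean-centered values; True when it rejects."""
    resid = values.astype(float).copy()
    for g in np.unique(groups):
        m = groups == g
        resid[m] -= resid[m].mean()
    if np.ptp(resid) == 0.0:
        return False
    # scipy caps Shapiro-Wilk at n = 5000; subsample deterministically
    if resid.size > 5000:
        idx = np.linspace(0, resid.size - 1, 5000).astype(int)
        resid = np.sort(resid)[idx]
    return stats.shapiro(resid).pvalue < alpha


def screen_and_transform(
    cohort: CohortTable, alpha: float = 0.05
) -> tuple[CohortTable, list[str]]:
    """Log-transform measures whose group-centered values fail a
    Shapiro-Wilk normality screen at ``alpha``.

    The transform is log(x + c) with c = 0 when all values are positive
    and c = 1 when zeros are present; a failing measure containing
    negative values raises (no offset is chosen silently).  All-constant
    measures are skipped with a warning.  Returns the transformed cohort
    and the list of transformed measure names.
    """
    if cohort.scores.isna().any().any():
        raise PreprocessError(
            "missing scores present; run imputation before the transform "
            "screen")
    data = cohort.data.copy()
    groups = data["group"].to_numpy()
    transformed: list[str] = []
    for m in cohort.battery.measure_names:
        x = data[m].to_numpy(dtype=float)
        if np.ptp(x) == 0.0:
            log.warning("measure %s is constant; transform screen skipped", m)
            continue
        if not _needs_log(x, groups, alpha):
            continue
        if x.min() < 0:
            raise PreprocessError(
                f"measure {m!r} fails the normality screen but has negative "
                f"values; a log transform cannot be applied"
            )
        c = 0.0 if x.min() > 0 else 1.0
        data[m] = np.log(x + c)
        transformed.append(m)
    return cohort.with_data(data), transformed
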