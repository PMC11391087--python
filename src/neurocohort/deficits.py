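"""Normative deficit classification against control-group cutoffs.

A participant is deficient on a measure when their score lies strictly
beyond a cutoff derived from the reference (control) group: mean ± 1.5 SD
when the reference distribution looks normal, otherwise the empirical
10th percentile of the impaired tail.  A cognitive domain is deficient
when at least 2 of its 3 measures are; participants are then stratified
by the number of deficient domains (0 / 1 / 2 / 3+).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .battery import BatteryConfig
from .cohort import CohortTable, GROUPS

__all__ = [
    "CutoffRule",
    "DeficitMatrix",
    "DeficitError",
    "derive_cutoffs",
    "score_deficits",
    "deficit_count_table",
    "domain_deficit_rates",
    "STRATA",
]

STRATA = ("0", "1", "2", "3plus")
SD_MULTIPLIER = 1.5
TAIL_QUANTILE = 0.10
MIN_REFERENCE_N = 20
DOMAIN_RULE_MIN = 2  # deficient measures needed for a deficient domain


class DeficitError(ValueError):
    pass


@dataclass(frozen=True)
class CutoffRule:
    """Normative cutoff for one measure.

    ``method`` records how the cutoff was derived (``sd1_5`` for the
    mean ± 1.5 SD rule, ``percentile10`` for the empirical decile of the
    impaired tail); ``deficit_side`` says which side of the cutoff is
    impaired.
    """

    measure: str
    method: str
    cutoff: float
    deficit_side: str

    def __post_init__(self) -> None:
        if self.method not in ("sd1_5", "percentile10"):
            raise DeficitError(f"unknown cutoff method {self.method!r}")
        if self.deficit_side not in ("below", "above"):
            raise DeficitError(f"unknown deficit side {self.deficit_side!r}")

    def is_deficit(self, values) -> np.ndarray:
        """Strictly beyond the cutoff on the impaired side."""
        v = np.asarray(values, dtype=float)
        return v < self.cutoff if self.deficit_side == "below" \
            else v > self.cutoff


@dataclass(frozen=True)
class DeficitMatrix:
    """Boolean deficit structure for a scored cohort.

    ``measure_deficits`` and ``domain_deficits`` are participant-indexed
    boolean frames; ``deficit_count`` counts deficient domains (0-7) and
    ``stratum`` bins it into 0 / 1 / 2 / 3plus.
    """

    measure_deficits: pd.DataFrame
    domain_deficits: pd.DataFrame
    deficit_count: pd.Series
    stratum: pd.Series


def _screen_normal(values: np.ndarray, alpha: float) -> bool:
    if np.ptp(values) == 0.0:
        return True
    # Shapiro-Wilk is only calibrated up to n = 5000; thin larger samples
    # deterministically over the order statistics
    if values.size > 5000:
        idx = np.linspace(0, values.size - 1, 5000).astype(int)
        values = np.sort(values)[idx]
    return stats.shapiro(values).pvalue >= alpha


def derive_cutoffs(cohort: CohortTable, reference_group: str = "Control",
                   alpha: float = 0.05,
                   normal_override: dict[str, bool] | None = None,
                   ) -> list[CutoffRule]:
    """Derive one cutoff per battery measure from the reference group.

    For each measure: a Shapiro-Wilk screen on the reference values
    decides the rule — normal looking gives mean − 1.5 SD (mean + 1.5 SD
    for higher-worse measures), otherwise the empirical 10th percentile
    of the impaired tail (type-7 / linear-interpolation quantile).
    ``normal_override`` can pin the screen decision per measure.
    """
    if reference_group not in GROUPS:
        raise DeficitError(f"unknown reference group {reference_group!r}")
    ref = cohort.group_subset(reference_group)
    if ref.empty:
        raise DeficitError(f"reference group {reference_group!r} is empty")
    normal_override = normal_override or {}
    rules = []
    for spec in cohort.battery.measures:
        vals = ref[spec.name].dropna().to_numpy(dtype=float)
        if len(vals) < MIN_REFERENCE_N:
            raise DeficitError(
                f"reference group has only {len(vals)} values for "
                f"{spec.name!r}; need ≥ {MIN_REFERENCE_N}"
            )
        side = "below" if spec.direction == "higher_better" else "above"
        if spec.name in normal_override:
            looks_normal = normal_override[spec.name]
        else:
            looks_normal = _screen_normal(vals, alpha)
        if looks_normal:
            mu, sd = vals.mean(), vals.std(ddof=1)
            cutoff = mu - SD_MULTIPLIER * sd if side == "below" \
                else mu + SD_MULTIPLIER * sd
            method = "sd1_5"
        else:
            q = TAIL_QUANTILE if side == "below" else 1.0 - TAIL_QUANTILE
            cutoff = float(np.quantile(vals, q, method="linear"))
            method = "percentile10"
        rules.append(CutoffRule(measure=spec.name, method=method,
                                cutoff=float(cutoff), deficit_side=side))
    return rules


def score_deficits(cohort: CohortTable,
                   cutoffs: list[CutoffRule]) -> DeficitMatrix:
    """Apply cutoffs to every participant and roll up to domains/strata."""
    battery: BatteryConfig = cohort.battery
    by_measure = {r.measure: r for r in cutoffs}
    missing = [m for m in battery.measure_names if m not in by_measure]
    if missing:
        raise DeficitError(f"no cutoff rule for measure(s) {missing}")
    if cohort.scores.isna().any().any():
        raise DeficitError(
            "missing scores present; impute before deficit scoring")
    ids = cohort.data["id"]
    md = pd.DataFrame(
        {m: by_measure[m].is_deficit(cohort.data[m].to_numpy())
         for m in battery.measure_names},
        index=ids.to_numpy())
    dd = pd.DataFrame(
        {d.name: md[list(d.measures)].sum(axis=1) >= DOMAIN_RULE_MIN
         for d in battery.domains},
        index=md.index)
    count = dd.sum(axis=1).astype(int)
    stratum = pd.Series(
        np.where(count >= 3, "3plus", count.astype(str)),
        index=md.index, name="stratum")
    return DeficitMatrix(measure_deficits=md, domain_deficits=dd,
                         deficit_count=count, stratum=stratum)


def deficit_count_table(matrix: DeficitMatrix, cohort: CohortTable,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Strata x groups contingency table of deficient-domain counts.

    Returns (counts, within-group percentages); groups absent from the
    cohort are omitted.
    """
    groups = pd.Series(cohort.groups.to_numpy(),
                       index=cohort.data["id"].to_numpy())
    present = [g for g in GROUPS if (groups == g).any()]
    counts = pd.DataFrame(0, index=list(STRATA), columns=present, dtype=int)
    for g in present:
        vc = matrix.stratum[groups == g].value_counts()
        for s in STRATA:
            counts.loc[s, g] = int(vc.get(s, 0))
    pct = 100.0 * counts / counts.sum(axis=0)
    return counts, pct


def domain_deficit_rates(matrix: DeficitMatrix,
                         cohort: CohortTable) -> pd.DataFrame:
    """Proportion of each group with a deficient domain (groups x domains)."""
    groups = pd.Series(cohort.groups.to_numpy(),
                       index=cohort.data["id"].to_numpy())
    present = [g for g in GROUPS if (groups == g).any()]
    rows = {g: matrix.domain_deficits[groups == g].mean() for g in present}
    return pd.DataFrame(rows).T[cohort.battery.domain_names]


def write_cutoffs(cutoffs: list[CutoffRule], path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([asdict(r) for r in cutoffs], indent=2),
                    encoding="utf-8")
    return path


def read_cutoffs(path) -> list[CutoffRule]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return [CutoffRule(**d) for d in doc]
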