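"""End-to-end orchestration: preprocess a cohort, score deficits, and run
the full inferential battery; plus a harness that recomputes the study's
published statistics from its printed summary tables.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import printed
from .cohort import CohortTable, GROUPS, summarize_group
from .deficits import (DeficitMatrix, deficit_count_table, derive_cutoffs,
                       domain_deficit_rates, score_deficits, write_cutoffs)
from .inference import (AnovaResult, ContingencyResult, anova_from_summary,
                        chi_square_test, eta2_to_d, manova_wilks,
                        oneway_anova, pairwise_comparisons,
                        pearson_correlation)
from .preprocess import (apply_exclusions, impute_education_median,
                         impute_group_means, screen_and_transform)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline",
           "reproduce_printed"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis settings; every default matches the study design."""

    alpha: float = 0.05           # omnibus / MANOVA-gate significance level
    fdr_q: float = 0.05           # Benjamini-Hochberg false discovery rate
    reference_group: str = "Control"
    welch: bool = True            # Welch pairwise t-tests (pooled otherwise)
    cutoffs_on_transformed: bool = False  # deficit cutoffs on log scale


@dataclass
class ReportBundle:
    """All pipeline outputs.  ``write`` serializes CSV tables plus a JSON
    summary into an output directory."""

    config: PipelineConfig
    excluded: list
    transformed_measures: list[str]
    cutoffs: list
    deficit_matrix: DeficitMatrix
    deficit_counts: pd.DataFrame
    deficit_pct: pd.DataFrame
    deficit_rates: pd.DataFrame
    deficit_strata_test: ContingencyResult
    domain_deficit_tests: dict[str, ContingencyResult]
    demographics: dict[str, ContingencyResult]
    age_anova: AnovaResult | None
    asrs_anova: AnovaResult | None
    manovas: dict[str, object]
    anovas: dict[str, AnovaResult | None]  # None when MANOVA gate failed
    gated_domains: list[str]
    pairwise: list
    bh_criterion: float
    asrs_deficit_correlation: object | None
    measure_summaries: pd.DataFrame

    def summary_dict(self) -> dict:
        def enc(x):
            if dataclasses.is_dataclass(x) and not isinstance(x, type):
                return {k: enc(v) for k, v in dataclasses.asdict(x).items()}
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if isinstance(x, dict):
                return {str(k): enc(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [enc(v) for v in x]
            return x

        return {
            "config": enc(self.config),
            "n_excluded": len(self.excluded),
            "excluded": enc(self.excluded),
            "transformed_measures": list(self.transformed_measures),
            "cutoffs": enc(self.cutoffs),
            "deficit_strata_test": enc(self.deficit_strata_test),
            "domain_deficit_tests": enc(self.domain_deficit_tests),
            "demographics": enc(self.demographics),
            "age_anova": enc(self.age_anova),
            "asrs_anova": enc(self.asrs_anova),
            "manovas": enc(self.manovas),
            "anovas": enc(self.anovas),
            "gated_domains": list(self.gated_domains),
            "bh_criterion": self.bh_criterion,
            "n_pairwise": len(self.pairwise),
            "pairwise": enc(self.pairwise),
            "asrs_deficit_correlation": enc(self.asrs_deficit_correlation),
        }

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.measure_summaries.to_csv(out / "group_summaries.csv")
        self.deficit_counts.to_csv(out / "deficit_strata_counts.csv")
        self.deficit_pct.to_csv(out / "deficit_strata_pct.csv")
        self.deficit_rates.to_csv(out / "domain_deficit_rates.csv")
        self.deficit_matrix.measure_deficits.to_csv(
            out / "measure_deficits.csv")
        self.deficit_matrix.domain_deficits.to_csv(
            out / "domain_deficits.csv")
        write_cutoffs(self.cutoffs, out / "cutoffs.json")
        pd.DataFrame([{
            "measure": r.measure, "group_a": r.pair[0], "group_b": r.pair[1],
            "mean_diff": r.mean_diff, "t": r.t, "p": r.p, "d": r.d,
            "significant": r.significant,
        } for r in self.pairwise]).to_csv(out / "pairwise.csv", index=False)
        (out / "summary.json").write_text(
            json.dumps(self.summary_dict(), indent=2), encoding="utf-8")
        return out


def _demographic_tables(cohort: CohortTable) -> dict[str, np.ndarray]:
    df = cohort.data
    present = [g for g in GROUPS if (df["group"] == g).any()]
    out: dict[str, np.ndarray] = {}
    out["sex"] = pd.crosstab(df["sex"], df["group"])[present].to_numpy()
    out["ses"] = pd.crosstab(df["ses"], df["group"])[present].to_numpy()
    out["education"] = pd.crosstab(
        df["education"], df["group"])[present].to_numpy()
    risk = df[df["birth_risks"] != "none"]
    risk_groups = [g for g in present if (risk["group"] == g).any()]
    if len(risk_groups) >= 2:
        out["birth_risks"] = pd.crosstab(
            risk["birth_risks"], risk["group"])[risk_groups].to_numpy()
    return out


def run_pipeline(cohort: CohortTable,
                 config: PipelineConfig | None = None) -> ReportBundle:
    """Run the full analysis on a loaded cohort.

    Stages: exclusions -> education median imputation -> group-mean score
    imputation -> normality screen with log transforms -> control-group
    cutoffs and deficit scoring (untransformed scale by default) ->
    demographic chi-squares / ANOVAs -> per-domain MANOVA with ANOVA
    follow-ups gated on MANOVA significance -> Welch pairwise tests under
    family-wide Benjamini-Hochberg control -> deficit contingency tests
    -> ASRS vs deficit-count correlation.
    """
    config = config or PipelineConfig()
    battery = cohort.battery

    log.info("stage=exclusions n_in=%d", len(cohort))
    retained, excluded = apply_exclusions(cohort)
    retained = impute_education_median(retained)
    imputed = impute_group_means(retained)
    log.info("stage=impute n_retained=%d n_excluded=%d",
             len(imputed), len(excluded))
    analyzed, transformed = screen_and_transform(imputed, alpha=config.alpha)
    log.info("stage=transform transformed=%s", transformed)

    cutoff_basis = analyzed if config.cutoffs_on_transformed else imputed
    cutoffs = derive_cutoffs(cutoff_basis,
                             reference_group=config.reference_group,
                             alpha=config.alpha)
    matrix = score_deficits(cutoff_basis, cutoffs)
    counts, pct = deficit_count_table(matrix, cutoff_basis)
    rates = domain_deficit_rates(matrix, cutoff_basis)
    strata_test = chi_square_test(counts.to_numpy(), alpha=config.alpha)
    domain_tests = {}
    groups_present = list(counts.columns)
    gser = pd.Series(cutoff_basis.groups.to_numpy(),
                     index=cutoff_basis.data["id"].to_numpy())
    for d in battery.domain_names:
        flags = matrix.domain_deficits[d]
        tab = np.array([
            [int((flags[gser == g]).sum()) for g in groups_present],
            [int((~flags[gser == g]).sum()) for g in groups_present],
        ])
        if (tab.sum(axis=1) > 0).all() and (tab.sum(axis=0) > 0).all():
            domain_tests[d] = chi_square_test(tab, alpha=config.alpha)
    log.info("stage=deficits strata_chi2=%.3f", strata_test.chi2)

    demographics = {name: chi_square_test(tab, alpha=config.alpha)
                    for name, tab in _demographic_tables(imputed).items()}
    df = imputed.data
    age_anova = None
    if df["age"].notna().all():
        age_anova = oneway_anova(df["age"], df["group"])
    asrs_anova = None
    ok = df["asrs"].notna()
    if ok.sum() >= 8 and df.loc[ok, "group"].nunique() >= 2:
        asrs_anova = oneway_anova(df.loc[ok, "asrs"], df.loc[ok, "group"])
    log.info("stage=demographics tests=%s", sorted(demographics))

    manovas: dict[str, object] = {}
    anovas: dict[str, AnovaResult | None] = {}
    gated: list[str] = []
    for d in battery.domains:
        X = analyzed.data[list(d.measures)].to_numpy()
        res = manova_wilks(X, analyzed.groups.to_numpy())
        manovas[d.name] = res
        passed = res.p < config.alpha
        if not passed:
            gated.append(d.name)
        for m in d.measures:
            anovas[m] = (oneway_anova(analyzed.data[m], analyzed.groups)
                         if passed else None)
    log.info("stage=manova gated=%s", gated)

    pairwise, criterion = pairwise_comparisons(
        analyzed, q=config.fdr_q, welch=config.welch)
    log.info("stage=pairwise n=%d bh_criterion=%.4f",
             len(pairwise), criterion)

    corr = None
    ok = df["asrs"].notna()
    if ok.sum() >= 3:
        count = matrix.deficit_count.reindex(df["id"]).to_numpy()
        corr = pearson_correlation(df["asrs"].to_numpy()[ok.to_numpy()],
                                   count[ok.to_numpy()])

    rows = []
    for m in battery.measure_names:
        for s in summarize_group(imputed, m):
            rows.append({"measure": m, "group": s.group, "n": s.n,
                         "mean": s.mean, "sd": s.sd})
    summaries = pd.DataFrame(rows).set_index(["measure", "group"])

    return ReportBundle(
        config=config, excluded=excluded, transformed_measures=transformed,
        cutoffs=cutoffs, deficit_matrix=matrix, deficit_counts=counts,
        deficit_pct=pct, deficit_rates=rates,
        deficit_strata_test=strata_test, domain_deficit_tests=domain_tests,
        demographics=demographics, age_anova=age_anova,
        asrs_anova=asrs_anova, manovas=manovas, anovas=anovas,
        gated_domains=gated, pairwise=pairwise, bh_criterion=criterion,
        asrs_deficit_correlation=corr, measure_summaries=summaries,
    )


# --------------------------------------------------------------------------
# recomputation of published statistics from printed summary tables
# --------------------------------------------------------------------------

def _summary_anova(measure: str, fixtures: dict) -> AnovaResult:
    ns = [fixtures["group_ns"][g] for g in printed.GROUPS]
    stats_ = fixtures["measure_stats"][measure]
    means = [stats_[g][0] for g in printed.GROUPS]
    sds = [stats_[g][1] for g in printed.GROUPS]
    return anova_from_summary(ns, means, sds)


def reproduce_printed(fixtures: dict | None = None) -> pd.DataFrame:
    """Recompute the study's published statistics from its printed
    summary tables and compare each against the printed value.

    ``fixtures`` may override any input table (keys:
    ``deficit_strata_counts``, ``education_counts``, ``ses_counts``,
    ``participation_sex_counts``, ``group_ns``, ``measure_stats``);
    defaults are the packaged printed tables.  Returns a frame with one
    row per check: computed, expected, tolerance, passed.
    """
    fx = {
        "deficit_strata_counts": printed.DEFICIT_STRATA_COUNTS,
        "education_counts": printed.EDUCATION_COUNTS,
        "ses_counts": printed.SES_COUNTS,
        "participation_sex_counts": printed.participation_sex_counts(),
        "group_ns": printed.GROUP_NS,
        "measure_stats": printed.MEASURE_STATS,
    }
    if fixtures:
        unknown = set(fixtures) - set(fx)
        if unknown:
            raise KeyError(f"unknown fixture(s): {sorted(unknown)}")
        fx.update(fixtures)

    rows: list[tuple[str, float, float, float]] = []
    strata = chi_square_test(fx["deficit_strata_counts"])
    rows.append(("deficit_strata_chi2", strata.chi2, 40.56, 0.01))
    rows.append(("deficit_strata_df", strata.df, 9, 0.0))
    rows.append(("deficit_strata_cramers_v", strata.cramers_v, 0.18, 0.01))
    t = np.asarray(fx["deficit_strata_counts"])
    rows.append(("cadhd_three_plus_pct",
                 100.0 * t[3, 0] / t[:, 0].sum(), 23.1, 0.05))
    rows.append(("education_cramers_v",
                 chi_square_test(fx["education_counts"]).cramers_v,
                 0.25, 0.005))
    rows.append(("ses_cramers_v",
                 chi_square_test(fx["ses_counts"]).cramers_v, 0.15, 0.005))
    part = chi_square_test(fx["participation_sex_counts"])
    rows.append(("participation_sex_chi2", part.chi2, 7.35, 0.01))
    rows.append(("participation_sex_cramers_v", part.cramers_v, 0.09, 0.005))
    coding = _summary_anova("coding", fx)
    rows.append(("coding_anova_F", coding.F, 13.04, 0.02))
    rows.append(("coding_cohens_d", eta2_to_d(coding.eta2), 0.60, 0.01))
    rows.append(("block_design_anova_F",
                 _summary_anova("block_design", fx).F, 8.75, 0.02))
    rows.append(("matrix_reasoning_anova_F",
                 _summary_anova("matrix_reasoning", fx).F, 7.31, 0.02))
    sim = _summary_anova("similarities", fx)
    rows.append(("similarities_anova_F", sim.F, 8.19, 0.02))
    rows.append(("similarities_cohens_d", eta2_to_d(sim.eta2), 0.47, 0.01))

    out = pd.DataFrame(rows,
                       columns=["check", "computed", "expected", "tol"])
    out["passed"] = (out["computed"] - out["expected"]).abs() <= out["tol"]
    return out
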