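"""Published summary statistics of the age-40 perinatal-risk ADHD cohort.

These tables are the public face of the study this package models: group
sizes, demographic category counts, per-measure group means and SDs, and
the deficient-domain strata counts.  They serve two roles:

* default parameters for the synthetic-cohort generator (the simulated
  cohorts reproduce these group-level statistics by construction), and
* inputs to the summary-statistics analyses (chi-square on printed
  contingency tables, ANOVA from printed means/SDs) that recompute the
  study's reported test statistics without participant-level data.
"""
from __future__ import annotations

import numpy as np

GROUPS = ("cADHD", "cAP", "Non-cAP", "Control")

#: Participants analyzed per childhood group.
GROUP_NS = {"cADHD": 39, "cAP": 79, "Non-cAP": 255, "Control": 69}

#: measure -> group -> (mean, sd) of the 21 outcome measures.
MEASURE_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "similarities": {
        "cADHD": (27.44, 4.04), "cAP": (28.09, 3.76),
        "Non-cAP": (29.15, 3.09), "Control": (30.22, 3.09)},
    "vocabulary": {
        "cADHD": (14.44, 4.10), "cAP": (16.14, 4.26),
        "Non-cAP": (17.06, 3.74), "Control": (17.60, 3.28)},
    "information": {
        "cADHD": (13.92, 4.88), "cAP": (15.72, 4.47),
        "Non-cAP": (16.83, 4.33), "Control": (17.04, 4.14)},
    "block_design": {
        "cADHD": (43.38, 10.85), "cAP": (45.41, 10.20),
        "Non-cAP": (48.60, 9.63), "Control": (51.84, 8.63)},
    "matrix_reasoning": {
        "cADHD": (17.62, 4.64), "cAP": (19.53, 3.93),
        "Non-cAP": (19.99, 3.89), "Control": (21.13, 2.80)},
    "rocf_copy": {
        "cADHD": (32.96, 2.50), "cAP": (33.18, 2.54),
        "Non-cAP": (33.66, 2.74), "Control": (33.76, 2.70)},
    "logical_memory": {
        "cADHD": (24.36, 9.48), "cAP": (27.32, 7.35),
        "Non-cAP": (28.10, 7.09), "Control": (29.26, 7.60)},
    "word_list": {
        "cADHD": (29.62, 6.16), "cAP": (33.16, 5.36),
        "Non-cAP": (34.71, 5.31), "Control": (34.78, 6.08)},
    "rocf_recall": {
        "cADHD": (38.88, 10.93), "cAP": (42.43, 12.29),
        "Non-cAP": (42.94, 12.32), "Control": (45.96, 13.60)},
    "digit_span_forward": {
        "cADHD": (9.21, 2.07), "cAP": (9.38, 1.78),
        "Non-cAP": (9.61, 2.07), "Control": (9.70, 2.03)},
    "digit_span_backward": {
        "cADHD": (8.95, 2.34), "cAP": (9.08, 2.10),
        "Non-cAP": (9.48, 2.23), "Control": (9.97, 2.79)},
    "digit_span_sequencing": {
        "cADHD": (8.00, 1.82), "cAP": (8.96, 2.24),
        "Non-cAP": (9.36, 2.06), "Control": (9.32, 2.13)},
    "cpt_omissions": {
        "cADHD": (1.05, 1.36), "cAP": (0.77, 1.52),
        "Non-cAP": (0.71, 1.17), "Control": (0.49, 0.83)},
    "cpt_rt_variability": {
        "cADHD": (97.82, 31.27), "cAP": (85.59, 28.04),
        "Non-cAP": (85.97, 29.53), "Control": (87.72, 31.88)},
    "flanker_cost": {
        "cADHD": (33.84, 64.30), "cAP": (29.83, 55.20),
        "Non-cAP": (39.17, 51.79), "Control": (18.68, 58.80)},
    "cpt_commissions": {
        "cADHD": (6.87, 3.17), "cAP": (5.76, 2.92),
        "Non-cAP": (6.25, 3.32), "Control": (6.01, 2.98)},
    "stroop_interference": {
        "cADHD": (54.28, 27.37), "cAP": (43.22, 26.97),
        "Non-cAP": (42.88, 20.69), "Control": (41.36, 15.93)},
    "word_fluency": {
        "cADHD": (42.23, 10.83), "cAP": (43.87, 9.81),
        "Non-cAP": (46.00, 9.81), "Control": (48.54, 9.29)},
    "cpt_rt": {
        "cADHD": (412.90, 55.92), "cAP": (397.57, 47.02),
        "Non-cAP": (397.17, 45.29), "Control": (398.51, 46.49)},
    "coding": {
        "cADHD": (63.26, 11.69), "cAP": (68.94, 11.73),
        "Non-cAP": (73.04, 13.01), "Control": (77.55, 11.85)},
    "pegboard_time": {
        "cADHD": (12.13, 1.70), "cAP": (11.67, 1.29),
        "Non-cAP": (11.49, 1.20), "Control": (11.55, 1.27)},
}

#: Reported per-measure ANOVA F (3, 438) and Cohen's d for reference.
MEASURE_ANOVA = {
    "similarities": (8.19, 0.47), "vocabulary": (7.24, 0.44),
    "information": (6.11, 0.41), "block_design": (8.75, 0.49),
    "matrix_reasoning": (7.31, 0.44), "rocf_copy": (1.38, 0.19),
    "logical_memory": (3.90, 0.33), "word_list": (10.99, 0.55),
    "rocf_recall": (2.80, 0.28), "digit_span_forward": (0.70, 0.14),
    "digit_span_backward": (2.40, 0.26), "digit_span_sequencing": (5.11, 0.38),
    "cpt_omissions": (1.82, 0.22), "cpt_rt_variability": (2.33, 0.26),
    "flanker_cost": (2.71, 0.27), "cpt_commissions": (1.17, 0.18),
    "stroop_interference": (3.41, 0.31), "word_fluency": (4.51, 0.35),
    "cpt_rt": (1.38, 0.19), "coding": (13.04, 0.60),
    "pegboard_time": (3.93, 0.33),
}

#: Age at assessment in years: group -> (mean, sd).
AGE_STATS = {"cADHD": (42.1, 1.24), "cAP": (42.0, 1.20),
             "Non-cAP": (42.3, 1.32), "Control": (41.5, 1.29)}

#: ASRS screener total (0-24): group -> (mean, sd).
ASRS_STATS = {"cADHD": (9.62, 5.37), "cAP": (6.47, 4.43),
              "Non-cAP": (6.29, 4.18), "Control": (6.68, 3.49)}

#: Demographic category counts by group (rows: category, cols: GROUPS order).
EDUCATION_COUNTS = np.array([  # basic / secondary / tertiary
    [15, 8, 14, 2],
    [16, 44, 141, 32],
    [8, 27, 100, 35],
])
SES_COUNTS = np.array([  # childhood SES class 1 (highest) / 2 / 3
    [5, 18, 59, 29],
    [12, 16, 74, 21],
    [22, 45, 122, 19],
])
SEX_FEMALE_COUNTS = {"cADHD": 14, "cAP": 35, "Non-cAP": 137, "Control": 39}
BIRTH_RISK_COUNTS = np.array([  # one / two / three-to-five; risk groups only
    [17, 55, 161],
    [14, 17, 64],
    [8, 7, 29],
])

#: Deficient-domain strata (0 / 1 / 2 / 3+) by group.
DEFICIT_STRATA_COUNTS = np.array([
    [13, 44, 185, 52],
    [11, 21, 40, 10],
    [6, 9, 20, 3],
    [9, 5, 10, 4],
])

#: Follow-up participation: (n, proportion female) among participants and
#: among those lost to follow-up or not assessed.
PARTICIPATION = {"participants": (442, 0.509), "nonparticipants": (481, 0.420)}


def participation_sex_counts() -> np.ndarray:
    """2x2 female/male x participated/not counts reconstructed from the
    published group sizes and female percentages."""
    rows = []
    for n, pf in PARTICIPATION.values():
        f = round(n * pf)
        rows.append((f, n - f))
    (f1, m1), (f2, m2) = rows
    return np.array([[f1, f2], [m1, m2]])


def demographic_probs(group: str) -> dict[str, dict]:
    """Category probabilities for one group, normalized from the counts."""
    j = GROUPS.index(group)
    n = GROUP_NS[group]
    sex_f = SEX_FEMALE_COUNTS[group] / n
    ses = SES_COUNTS[:, j] / SES_COUNTS[:, j].sum()
    edu = EDUCATION_COUNTS[:, j] / EDUCATION_COUNTS[:, j].sum()
    if group == "Control":
        risks = {"none": 1.0}
    else:
        col = BIRTH_RISK_COUNTS[:, j]
        p = col / col.sum()
        risks = {"one": p[0], "two": p[1], "three_to_five": p[2]}
    return {
        "sex": {"female": sex_f, "male": 1.0 - sex_f},
        "ses": {1: ses[0], 2: ses[1], 3: ses[2]},
        "education": {1: edu[0], 2: edu[1], 3: edu[2]},
        "birth_risks": risks,
    }
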