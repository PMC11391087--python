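# Methods

`neurocohort` models a four-group longitudinal cohort design in which
adults assessed around age 40 are compared on a neuropsychological
battery according to their childhood status: diagnosed ADHD (cADHD),
subthreshold attention/hyperactivity problems (cAP), perinatal-risk
cohort members without attention problems (Non-cAP), and controls
without perinatal risks (Control). This note records the model, the
defaults, and the choices made where the design was open.

## The battery

The default battery has 21 outcome measures in 7 cognitive domains of
exactly 3 measures each (verbal reasoning, perceptual skills, memory,
working memory, attention, executive function, speed). Each measure
declares the direction of impairment: for most scores low is impaired
(`higher_better`), while for error counts and timing measures (CPT
omissions/commissions, CPT mean RT and RT variability, flanker conflict
cost, Stroop interference, pegboard time) high is impaired
(`higher_worse`). The direction map is fixed by each measure's
semantics, not estimated. Alternative batteries load from YAML/JSON;
validation enforces the 7 × 3 structure and unique measure–domain
assignment.

## Synthetic cohorts

No participant-level data are distributed, so the generator is the
package's test bed. It draws, per group, a latent vector of correlated
standard normals (Gaussian copula) and pushes each coordinate through a
per-measure marginal:

- **normal** — `mu + sigma·z` for pen-and-paper scores;
- **lognormal** — moment-matched to `(mu, sigma)` via
  `s² = ln(1 + (sigma/mu)²)`, `m = ln(mu) − s²/2`, used for the
  right-skewed timing measures (Stroop interference, CPT RT
  variability, flanker cost);
- **count** — `round(max(0, mu + sigma·z))` for CPT omission and
  commission errors.

The copula keeps one correlation model valid across these mixed
marginals. The default correlation is block-exchangeable: 0.5 between
measures of the same domain, 0.25 across domains — typical magnitudes
for neuropsychological batteries; the true inter-test correlations are
unpublished, so these are configuration knobs, not claims. Group sizes
(39/79/255/69), per-measure means and SDs, demographic category
frequencies, age, and ASRS screener parameters default to the published
group summary statistics. Demographics are sampled independently of
scores; the ASRS total is a normal truncated to [0, 24] and rounded.
MCAR missingness can be injected per score cell at a configurable rate.

Known departures from real data, hence limits on what passing tests
show: Pearson correlations are mildly attenuated relative to the latent
ρ under non-normal marginals (mean pairwise r ≈ 0.47 for latent 0.5 at
n = 10 000; discrete count marginals attenuate most); the count
marginal's mean is biased upward by zero-clipping when `mu/sigma` is
small (CPT omissions: population mean ≈ 0.55 for a target of 0.49);
demographics are independent of cognitive scores, so the generator
cannot exhibit education–performance confounding; missingness is MCAR
only, and attrition over follow-up waves is not modelled.

All randomness descends from one integer master seed through
deterministically spawned per-group, per-stage substreams
(`numpy.random.SeedSequence`); a fixed seed reproduces a cohort
bit-identically.

## Preprocessing

1. **Exclusions.** A participant is dropped when ≥ 19% of measures are
   missing — with 21 measures the smallest qualifying count is 4
   (4/21 = 19.05%; 3 missing = 14.3% is retained) — or when ≥ 2 of the
   3 measures of any single domain are missing (the 2-of-3 domain rule
   would be undefined). Reasons are recorded per participant. The rule
   is idempotent.
2. **Imputation.** Missing education takes the within-group median
   class, rounding half up to the higher class on ties (deterministic
   and documented; rounding down is the obvious alternative). Missing
   scores take the within-group measure mean, which preserves every
   group mean exactly and never rewrites an observed cell. ASRS is
   never imputed; analyses using it are pairwise-complete.
3. **Transform screen.** Each measure's group-mean-centered values are
   screened with Shapiro–Wilk at α = 0.05 (a standard choice at n ≈
   40–450; the screen is applied to residuals so a pure group shift is
   not mistaken for non-normality). Failing measures are replaced by
   `log(x + c)` with `c = 0` when all values are positive and `c = 1`
   when zeros occur (error counts contain zeros); a failing measure
   with negative values raises rather than silently picking an offset.
   Samples above Shapiro–Wilk's n = 5000 calibration limit are thinned
   deterministically over the order statistics. Which measures get
   transformed is an outcome of the screen on the data at hand, and is
   reported, not asserted in advance.

## Deficit classification

Cutoffs are derived from the designated reference group only (Control
by default, never pooled), one per measure: if the reference values
pass the same Shapiro–Wilk screen, the cutoff is mean − 1.5 SD (mean +
1.5 SD for higher-worse measures); otherwise it is the empirical 10th
percentile of the impaired tail (90th for higher-worse), computed with
the type-7 linear-interpolation quantile — quantile dialects differ
across software, so the definition is pinned and oracle-tested. The
screen decision is overridable per measure. A score is deficient
strictly beyond the cutoff (ties are healthy; the strict reading makes
tie handling reproducible). A domain is deficient when ≥ 2 of its 3
measures are; participants are stratified by deficient-domain count
into 0 / 1 / 2 / 3+.

Deficits are classified on the untransformed scale by default (the
percentile rule is invariant to monotone transforms, the SD rule is
not); `PipelineConfig(cutoffs_on_transformed=True)` switches.

Useful identities used as test oracles: a reference group scored
against its own decile cutoffs has per-measure deficit rate
≤ ⌈0.1·n⌉/n; for independent measures with per-measure rate p the
2-of-3 domain rate is 3p²(1−p) + p³.

## Inferential battery

Test statistics are computed from their defining formulas; scipy
supplies only the reference distributions. Independent implementations
(scipy's `chi2_contingency`/`f_oneway`, statsmodels MANOVA and
`multipletests`) appear in tests as cross-checks.

- **Contingency tables.** Pearson χ² = Σ(O−E)²/E, df = (r−1)(c−1),
  Cramér's V = √(χ²/(N·min(r−1, c−1))). Post hocs use adjusted
  standardized residuals r_ij = (O−E)/√(E(1−row/N)(1−col/N)),
  approximately N(0,1) under independence (verified by null
  calibration: ≈ 5% of cells beyond |z| = 1.96), with a Bonferroni
  threshold of α/(r·c) — the cell count as divisor is standard practice
  for residual screens. Zero marginals are an error; categories must be
  collapsed upstream (as done for the sparsest SES class).
- **ANOVA.** One-way decomposition; η² = SSb/(SSb+SSw);
  d = 2·√(η²/(1−η²)) (d = 2f). `anova_from_summary` takes per-group
  (n, mean, SD) and shares the exact floating-point formulas with the
  raw-data path, so the two agree identically — this is what lets the
  published F statistics be recomputed from printed summary tables.
- **MANOVA.** Wilks' Λ = det(E)/det(E+H) per domain with Rao's F
  approximation (the long-standing software default), Pillai not
  needed for the default pipeline. Both Rao's df1 (9 for 4 groups × 3
  measures) and the design df (3) are reported, since summary tables in
  this literature often print the design df. Multivariate
  η² = 1 − Λ^(1/s). Follow-up ANOVAs run only when the domain's MANOVA
  is significant at α = 0.05; gated domains are marked, not hidden.
- **Pairwise comparisons.** Welch t-tests by default (group sizes range
  39–255, variance homogeneity is not assumed; pooled-variance
  optional), Cohen's d always on the pooled SD. Benjamini–Hochberg at
  q = 0.05 is applied across the full family of measure × pair tests
  (126 at the full battery) jointly, and the realized criterion
  p₍k*₎ is reported.
- **Correlation.** Pearson r with t-based p, pairwise-complete.

## Problem sizes in the test suite

Stochastic checks use sizes chosen to put Monte-Carlo error well inside
each asserted band: marginal/parameter recovery at 5 000–20 000 per
group (3 standard errors), copula correlation at n = 10 000,
adjusted-residual calibration on 3 000–4 000 null multinomial tables
(MC error ≈ 0.1 percentage point against a ±0.5-point band), MANOVA
null uniformity on 1 000 simulations (KS at α = 0.01), and the 2-of-3
binomial identity at n = 20 000. Directional end-to-end checks run at
10× the published group sizes so the expected ordering of group means
is essentially deterministic.

## Limitations

The package reproduces the study's *procedures* and its
summary-statistics results exactly; results that require the raw
participant data (exact MANOVA/ANOVA p-values on real scores, the
observed pairwise significance pattern, the ASRS–deficit r = 0.19) are
covered by calibration, identity, and directional checks on synthetic
cohorts instead. Group-mean imputation understates within-group
variance (no multiple imputation, matching the modelled design); no
covariate adjustment, nonparametric fallbacks, or MNAR mechanisms are
provided.
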