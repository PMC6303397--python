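# Methods

## Study design being modeled

The analyses target a three-arm bulk-expression design — young, old
vehicle-treated, and old senolytic-treated animals, with ≥ 3 replicates per
group in each of several tissues (kidney, liver, lung, skin) — plus lifespan
cohorts and per-cell imaging-cytometry feature tables. The scientific
question is whether removing senescent cells moves the old transcriptome
back toward the young one ("rejuvenation"), extends survival, and lowers
the tissue burden of SA-β-Gal⁺/CD45⁻/HMGB1⁻ cells.

## Expression model and simulator

Counts are negative binomial with mean `m = s_j · 2^(μ_g + β_g·I[old] +
γ_g·I[treated])` and variance `m + φ m²`:

* `μ_g` — per-gene baseline log2 expression, Normal(5, 2) by default, a
  typical bulk dynamic range of roughly 1–10³ counts.
* `φ` — NB dispersion, default 0.1 (a common bulk RNA-seq magnitude); the
  mean/variance parameterization is the standard `var = m + φ m²`.
* `β_g` — aging effect, nonzero for a fraction `frac_age_affected` (default
  0.2) of genes, Normal(0, 1) in log2 units.
* `γ_g` — treatment effect, `γ = −κ·β + ε` for age-affected genes and
  exactly 0 otherwise, with `ε ~ Normal(0, 0.2)`. The reversal fraction
  κ ∈ [0, 1] is the simulator's central dial: the implied regression tilt of
  `log2(treated/young)` on `log2(vehicle/young)` over age-affected genes is
  `1 − κ`.
* `s_j` — library-size multiplier, log-normal with sd 0.2 in log2 units, to
  exercise normalization.
* SASP genes (56 by default, matching the size of curated SASP panels) are
  forced age-affected with a positive β with probability 0.8, reflecting the
  premise that the senescence secretome rises with age; this gives the
  enrichment and score analyses real signal to find.

Defaults for replicates (5/group) and tissues (4) mirror the scale of the
motivating design. All generators use numpy's PCG64 with an explicit seed;
identical configs give byte-identical tables.

What the simulator does **not** model: UMI/plate structure, batch effects,
gene–gene correlation, length/GC bias, or tissue-shared effect sizes
(effects are drawn independently per tissue). Passing tests therefore
demonstrate the statistics are correct and calibrated under a clean NB
model, not that the pipeline is robust to those real-data artifacts.

## Differential expression and fold changes

The affected-gene caller is deliberately simple and fully declared:
median-of-ratios size factors rescaled to geometric mean 1, `log2(x/s + 1)`,
per-gene Welch t on log expression, Benjamini–Hochberg at α = 0.05,
`affected = (q ≤ α) ∧ (|lfc| ≥ lfc_min)` with `lfc_min = 0` by default.
Group log-ratios are differences of per-group means of per-sample log
expression (not logs of mean counts), so the three contrast columns satisfy
`lfc_treat_vs_young − lfc_age = lfc_treat` exactly. A gene is "detected"
when its mean normalized count reaches 1 in at least one group. Degenerate
genes with zero variance in both groups get p = 1 (equal means) or p = 0
(unequal), keeping the decision rule continuous at such fixtures.

## Tilt regression

OLS with intercept, per tissue, over age-affected genes; `t = (slope − 1)/SE`
on n − 2 df, two-sided; CI at a configurable level (default 95%). Perfect
fits follow the t-test's limit: SE = 0 with slope = 1 gives p = 1, SE = 0
with slope ≠ 1 gives p = 0. A pooled fit across tissues is also reported,
since a single printed significance level may refer to either mode.

On *true* fold changes the tilt estimator is exact: the CI covers `1 − κ`
at its nominal rate and the κ = 0 type-I rate is exactly α (the errors are
normal, so the t-test is exact). On *count-estimated* fold changes two
finite-replicate effects enter: classical errors-in-variables attenuation
from noise in the x-axis, and a positive covariance term because both axes
share the young-group mean. Together `E[tilt] ≈ ((1−κ)·V_β + s) / (V_β + 2s)`
where `V_β` is the aging-effect variance and `s` the per-gene fold-change
noise variance; the net bias is proportional to `(2κ − 1)·s`, vanishes at
κ = 0.5, and shrinks as replicates grow. Calibration claims are therefore
made on true fold changes; the estimated-tilt bias is itself covered by a
monotonicity test at κ = 1.

## Overlap, SASP score, anti-correlation

Hypergeometric tests use the upper tail `P(X ≥ k)` with the universe taken
as the detected genes of the tissue (configurable). The headline overlap
fraction is reported relative to the treatment-affected set. The SASP score
is the unweighted mean of per-gene log2 ratios over detected SASP genes;
with none detected the score is explicitly undefined rather than 0. The
vehicle/treated score comparison is a paired two-sided Wilcoxon signed-rank
over per-gene ratios (a declared choice; exact null for small n without
ties). Spearman ρ uses average ranks; for n ≤ 8 the p-value is exact by
full permutation enumeration, flagged as such in the result. All logs are
base 2; tilt and ρ are invariant to the common log base, so only the SASP
score's units depend on it.

## Survival

Kaplan–Meier product-limit with events preceding censorings at tied times;
median = smallest event time with S(t) ≤ 0.5, "not reached" otherwise. The
Gehan–Breslow–Wilcoxon test is the weighted log-rank statistic with
w_j = number at risk at the j-th pooled event time, hypergeometric variance
with tie correction `d_j (n_j − d_j)/(n_j − 1)`, k-sample chi-square
`U' V⁻¹ U` over the first k − 1 groups on k − 1 df; a pairwise mode and an
unweighted (standard log-rank) mode are provided. The p-value is the
chi-square tail — an asymptotic quantity: at very small cohorts (≤ ~10
subjects per arm) it can deviate from the exact permutation distribution of
the statistic by ~0.01–0.1, an inherent property of the approximation worth
remembering when cohorts are tiny.

## Gating

Gates are config-supplied rules (≥ / ≤ / = / interval) applied in declared
stages; nothing is fitted or applied silently. The default config's
boundaries are synthetic stand-ins matched to the simulator's default
population distributions, not measured instrument gates. HMGB1-negativity
is spot count = 0 (configurable to ≤ k). A helper suggests a boundary at
the KDE valley between the two main modes of a feature, advisory only. The
senescent fraction's denominator is the CD45⁻ focused-singles population;
with the default well-separated populations the senescence-correlated gate
spillover is < 10⁻³, so recovery error is dominated by binomial sampling.

## Pipeline and reproducibility

A YAML run config (strictly validated; unknown keys rejected, all
violations listed at once) drives simulate → analyze runs. One master seed
fans out to fixed per-stage child seeds via `SeedSequence` spawn keys, so
toggling a stage never shifts another stage's stream. Reports are JSON with
sorted keys and carry the config hash, seed, and software version — and no
wall-clock values, so identical configs reproduce outputs byte-for-byte
(timestamps live only in the run log). All outputs are plain text.

## Validation problem sizes

The calibration studies run at: tilt CI coverage — 4 tissues × 10,000 genes,
5 replicates/group, φ = 0.01, 500 full-study replicates per κ ∈
{0, 0.25, 0.5, 0.75, 1}; tilt type-I — 2,000 replicates of 2,000-gene
single-tissue truth draws; anti-correlation sign — 200 count-level runs at
κ = 0.5; GBW type-I — 2,000 null cohorts of 30/group; gating — 30,000 cells
at senescent fractions 0.02/0.1/0.4. The reproduction script
(`scripts/acceptance.py`) runs the same routines at reduced replicate
counts chosen to finish in a few minutes on one CPU.

## Known limitations

* The DE procedure is a transparent Welch/BH caller, not an NB GLM with
  variance moderation; it is adequate for calibrated synthetic data but
  underpowered at 2–3 replicates compared to empirical-Bayes methods.
* Estimated tilts carry the finite-replicate bias described above;
  comparisons across designs with different replicate counts should use
  true-scale effect estimates or matched designs.
* The GBW p-value is asymptotic (see above); no exact/permutation mode is
  exposed.
* The gating engine consumes precomputed features; it does not model
  intensity compensation or spillover, and the spot count is taken as
  given, not derived from images.
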