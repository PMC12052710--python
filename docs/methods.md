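# Methods

This note documents the statistical model, the synthetic data the tests
run on, the numerical choices, and the limitations of `fibermwas`.

## Marker-based degradation rates

Fiber degradation in the rumen is estimated indirectly with
acid-insoluble ash (AIA) as an internal marker. Because AIA is not
digested, the ratio of fiber to marker can only fall as fiber is
degraded; with feed/digesta marker concentrations A and B and fiber
concentrations FA and FB (all g/kg DM), the degraded fraction is
(1 − (A/B)(FB/FA)) × 100. The formula can yield negative values under
sampling noise; these are reported with a warning and never clamped,
because clamping would distort the tails that extreme-group assignment
depends on. Unit consistency between feed and digesta is the caller's
responsibility; only positivity is enforced. ADG is the body-weight
difference over an interval divided by its length; FCR = intake/ADG,
reported as missing (not infinite) when ADG = 0.

## Compositional preprocessing

Counts are normalized by deterministic scaling to the depth of the
shallowest sample. Scaling rather than rarefaction keeps the pipeline
deterministic and preserves within-sample proportions exactly;
prevalence (fraction of samples with abundance > 0) is invariant to it.
Zeros are handled by adding a pseudocount of 0.5 (standard additive
replacement) before closing to proportions and applying the centered
log-ratio transform clr(x)ⱼ = ln(pⱼ/g(p)); rows of the CLR matrix sum to
zero by construction. Principal components are computed on the
column-centered CLR matrix of *all* genera (the covariate role is to
absorb community-level structure, so the full matrix is the natural
input); component signs are fixed by making the largest-magnitude
loading positive so scores are reproducible across SVD implementations.

## The two-part association model

Each genus is routed by prevalence: < 60% to the binary part (presence
indicator), ≥ 60% to the quantitative part (CLR column). Both parts fit
ordinary least squares y ~ 1 + PC1..PC3 + g and take the absolute
partial t of the genus term as the test statistic (the displayed
two-part equations are y = β₁b + e and y = β₂q + e; the covariates enter
both). Significance is assessed by permuting the genus predictor against
the fixed (phenotype, covariate) frame:

* when the number of distinct arrangements of the predictor is at most
  the permutation budget, the full distribution is enumerated and
  p = #{|t| ≥ |t_obs|}/total (the observed arrangement is a member, so
  p > 0);
* otherwise seeded Monte-Carlo sampling with the add-one estimator
  p = (1 + #{≥})/(1 + N), which is never zero and has resolution
  1/(1 + N).

Permuting the predictor is valid under predictor exchangeability,
matches term-wise permutation regression, and is what makes the
exhaustive small-n oracle possible; Freedman–Lane residual permutation
is available behind `scheme="freedman_lane"`. Each permutation costs
O(n·k) rather than a refit, via the identities ĝᵀŷ = g_permᵀŷ (ŷ is
already orthogonal to the covariates) and ‖ĝ‖² = ‖g‖² − ‖Qᵀg_perm‖².
Per-genus permutation streams are seeded from (seed, crc32(genus name)),
so results are independent of column order. Ties with the observed
statistic count as exceedances (a phenotype constant after adjustment
therefore gives p = 1). Constant predictors are unestimable and excluded
from the family; predictors exactly collinear with the covariates
likewise.

Bonferroni adjustment multiplies p by the number of genera tested in
*both parts combined* (the conservative family choice) and selects at
α = 0.01. Permutation resolution interacts with Bonferroni: with m
genera the smallest achievable adjusted p is m/(1 + N), so adjusted
significance at α requires N > m/α − 1 — about 29,200 permutations for
m = 292 at α = 0.01. The default is therefore N = 100,000, kept cheap by
a two-stage scheme: every genus is screened at 999 permutations and only
those with stage-1 p ≤ 0.02 are re-tested at full resolution with a
fresh stream. The escalation threshold is far above the largest stage-1
p (~2×10⁻³ + noise) that any genus capable of reaching full-resolution
significance (true p < 3.4×10⁻⁵) could plausibly show, and re-testing
with fresh permutations keeps reported p-values valid (slightly
conservative in the escalated band).

## Spearman screen

ρ is the Pearson correlation of mid-ranks (average ranks on ties). The
two-sided p uses the t approximation for n > 9 and exact permutation
enumeration for n ≤ 9, where the approximation is poor and enumeration
is cheap. Classification follows the published thresholds: moderate
(p < 0.01, |ρ| > 0.40), weak (p < 0.01, 0.20 < |ρ| ≤ 0.40). The
boundary |ρ| = 0.40 is assigned to *weak* by default so that no
significant correlation above 0.20 is silently unclassified; a strict
mode (`strict_bounds`) leaves it unclassified, matching a literal
reading of strict inequalities on both sides.

## Extreme groups and differential testing

Outlier exclusion is a single pass: mean and sample SD (ddof = 1) are
computed once and values outside mean ± 2 SD are dropped — no iterative
re-trimming, since the exclusion is described as one step. The top and
bottom 10 of the trimmed ranking form the high/low groups; ties
straddling a cut are broken by lexicographic sample ID so assignment is
deterministic. Comparisons use Student's pooled t-test by default (the
typical default of point-and-click workflows when unstated), Welch
behind a flag; traits are tested at p < 0.05 and genus-level
differential abundance at p < 0.01, each configurable separately. The
genus tests run on CLR values so the group contrast lives on the same
scale as the quantitative model part. Output tables report per-group
SEMs and a pooled-variance SEM side by side because published livestock
tables use either convention without saying which. Degenerate t-tests
are resolved explicitly: both groups constant and equal → (t, p) =
(0, 1); both constant but different → infinite t with the smallest
representable p (perfect separation is evidence, not missingness).

## Consensus

A genus is a *key genus* when it survives all three screens; the
consensus is a pure three-way intersection, hence order-invariant and
monotone (relaxing any one threshold can only grow it). Genera without
phylum annotation tally under "Unclassified" rather than being dropped.
The reported key-genus lists for NDFD (6 Firmicutes + 1 Bacteroidetes)
and ADFD (6 Firmicutes + 1 Bacteroidetes + 1 Actinobacteria) ship as
reference constants and serve as worked examples for the tally.

## Synthetic cohorts

The generator emulates the features the analysis is sensitive to, at the
scale of the emulated study (190 animals, 292 genera):

* **Abundance**: per-genus log-normal mean abundances (log-scale SD 1.5),
  per-cell log-normal noise (SD 1.0), per-genus structural zero-inflation
  with prevalence drawn uniformly from 0.2–1.0, and a per-sample
  multinomial draw at a depth uniform on 30,000–60,000. Zero-inflation is
  applied *before* the multinomial so that rare genera are genuinely
  absent — the binary model part needs structural, not sampling, zeros.
  Multinomial sampling adds further zeros for rare genera, so observed
  prevalence spans both sides of the 60% routing boundary.
* **Phenotype**: NDFD (%) = 55 + Σβⱼ·clrᵢⱼ + Σγⱼ·1[xᵢⱼ>0] + ε,
  ε ~ N(0, 3²). Causal genera are chosen *after* generation from
  prevalence strata (quantitative ≥ 0.7, binary 0.25–0.55) so their
  routing class is guaranteed; effects are computed against the observed
  CLR table, so the planted signal is exactly what the pipeline sees.
  Default calibration: each quantitative genus explains 15% of total
  phenotype variance; each binary genus shifts the phenotype by two
  residual SDs when present. ADFD tracks NDFD minus 10 points plus
  N(0, 2²) noise.
* **Feed efficiency**: FCR = 12 − 0.1·NDFD + N(0, 1), giving a monotone
  negative NDFD–FCR association of moderate strength (sample Spearman ρ
  ≈ −0.53 on average) — the simplest mechanism reproducing the observed
  direction; no mechanistic realism is claimed.
* **Marker panels and growth**: feed AIA uniform on 8–12 g/kg DM, digesta
  enrichment factor uniform on 1.5–2.5, FB solved from the degradation
  formula so the marker round trip is exact to machine precision; body
  weights grow linearly at ADG = ADFI/FCR so growth metrics also invert
  exactly. Fermentation and morphology traits are uncorrelated nuisance
  columns.

A single RNG stream per cohort is consumed in a fixed documented order;
genus-parameter arrays are drawn genus-major so enlarging the table
extends rather than reshuffles earlier columns.

What the generator does **not** emulate: phylogenetic correlation among
genera, overdispersion structure of real 16S libraries beyond the
log-normal cell noise, diet or pen effects, measurement error in the
marker chemistry, or nonlinear phenotype links. Passing recovery tests
therefore demonstrates that the pipeline detects the planted linear-CLR
and presence effects at study scale — not that real rumen data meet
those assumptions.

## Replicate sizes used by tests and the acceptance script

Chosen as the package's own balance of Monte-Carlo error against
runtime on a single core: marker round trip 1,000 panels; sampled-vs-
exhaustive 50 problems at n ≤ 7 with 10,000 samples; null calibration
200 cohorts (tests) / 60 cohorts (script) at 999 permutations; planted
recovery 20 / 10 cohorts at 99,999 permutations; FCR direction 100 / 50
cohorts. The NDFD–FCR group contrast reproduces direction, not printed
means, because the generator's FCR scale is a modeling choice.

## Known limitations

* Under the default planted-effect calibration (four quantitative genera
  at R² ≈ 0.15 each, one binary genus at prevalence 0.4 with a 2-SD
  shift), the Spearman and MWAS screens recover essentially all causal
  genera, but the differential-abundance filter — a t-test between two
  groups of 10 at p < 0.01 — has only ~0.6 per-genus power, so the
  three-method consensus recovers on average about 3 of the 5 planted
  genera with near-perfect precision. The intersection trades recall for
  precision by design; the extreme-group stage is its statistical
  bottleneck.
* The binary model part tests presence/absence only; it does not model
  abundance among present samples (no full hurdle model).
* Bonferroni across both parts combined is conservative relative to
  per-part correction.
* No mixed-model or kinship adjustment: covariate control is limited to
  the CLR principal components.
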