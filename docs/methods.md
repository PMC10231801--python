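# Methods

This note documents the statistical models and procedures implemented in
`xdp_progression`, the choices made where the design was genuinely open,
and what the synthetic-data validation does and does not demonstrate.

## Cohort and measure model

A cohort is a long-format table of observations `Y_ijt` (subject `i`,
measure `j`, visit `t`) plus subject metadata: genotype group
(symptomatic gene-positive, pre-symptomatic gene-positive, gene-negative),
reported age at onset (symptomatic subjects only), SVA repeat size
(gene-positive only), family id, initial symptom, and per-visit ages in
decimal years. Visit indices are 0-based with 0 = enrollment. Missing
values are empty fields on disk and absent records in memory — never
numeric sentinels, which would corrupt the count likelihoods.

The default catalogue is the 107-measure battery: MDS-UPDRS Part 1 (13
ordinal items, 0–4), Part 2 (13), Part 3 (33, including the 5 rigidity
and 5 rest-tremor sub-items and the bilateral item pairs), BFM disability
(6 items 0–4 plus walking with levels {0–4, 6}), BFM movement (9 items
with the product-scored level set {0,1,2,3,4,6,8,9,12,16}), EAT-10 (10
items 0–4), CPIB (10 items 0–3), lip strength (a non-negative integer
after rounding), tongue strength, maximum phonation time, 4 DDK counts
paired with 4 DDK durations (Ba, Da, Ka, AMR; each count's Poisson
exposure is its paired duration), and swallow duration. Weight, height
and BMI are carried as auxiliary measures outside the battery; keeping
weight out of the trajectory fit preserves it as an external validation
variable. Measures on which higher values mean *less* severe disease
(CPIB, the DDK measures, lip and tongue strength, MPT, height, weight,
BMI) are tagged with severity direction −1.

Two derived variable sets are used downstream: the 99 change-testing
units (the battery with the 10 CPIB items collapsed to their sum — they
are extremely strongly correlated — plus participant weight) and the 102
correlation variables (those 99 plus repeat size, reported onset and
height as subject-level constants).

## Change testing

For each unit, the analysis difference per symptomatic subject is last
minus first value, with last-observation-carried-forward at the final
visit and next-observation-carried-backward at enrollment; subjects with
fewer than two observed timepoints are excluded. The Wilcoxon signed-rank
statistic is reported as the *sum of signed ranks* `W` (it can be
negative; a negative `W` for weight means declines dominate). Zero
differences are removed (reduced-sample rule) and tied absolute
differences receive average ranks. The two-sided p-value uses the exact
null distribution — computed by a subset-sum dynamic program equivalent
to enumerating all 2ⁿ sign assignments — whenever the reduced sample is
tie-free with n ≤ 25; otherwise a normal approximation with the
tie-correct variance `Var(W) = Σ rank_i²` and *no* continuity correction,
so results are reproducible bit for bit. Benjamini–Hochberg adjustment
uses the monotone step-up form (cumulative minimum of `p·m/rank`);
untestable units carry no p-value and do not count toward `m`.

## Correlation model

Rows are symptomatic subject-visits over the 102 variables; subject-level
constants are replicated across a subject's visits. Severity-decreasing
variables are multiplied by −1, then each variable is mapped through a
rank-based inverse-normal transform (average ranks, Blom offset). The
transform is a pragmatic choice for mixing ordinal, count and continuous
scales in one Gaussian model: it is monotone-invariant and robust, at the
cost of attenuating information in heavily tied ordinal items.

The model is `x_row ~ N(μ, Σ)` i.i.d. with a flat prior on μ and a weak
inverse-Wishart prior on Σ (ν = p + 2, scale 0.5·I), which regularizes
rank-deficient scatter matrices — the 102-variable fit has barely more
rows than columns — while leaving large-sample estimates essentially
unbiased. Fitting is by Gibbs sampling with data augmentation: missing
entries are drawn from their conditional normal given the observed part
of the row (rows grouped by missingness pattern for vectorization), then
μ and Σ from their conjugate conditionals. Each retained draw of Σ is
converted to a correlation matrix; the posterior mean of those draws is
itself symmetric, PSD and unit-diagonal by convexity, so the validity
contract holds under any missingness pattern without projection.
Credible half-widths are half the 2.5–97.5% interquantile range.
Convergence is monitored by split-R̂ on a deterministic subsample of
entries; values above 1.2 raise a warning. Variable clustering uses
average-linkage agglomeration on distance 1 − r.

## Principal variables

`PVE(S) = 100 · tr(R[:,S] R[S,S]⁻¹ R[S,:]) / p` is the percent of total
(unit) variance explained by regressing every variable on the subset S;
it equals the average squared multiple correlation and is monotone in S.
A pseudo-inverse is used when `R[S,S]` is singular. Selection is greedy
forward over blocks (one or two variables; left/right analogues and each
DDK count–duration pair form natural blocks). Among candidates whose
incremental PVE ties within 1e−6, a block containing a measure with
BH-adjusted p below the FDR level wins — significance is a tie-break,
not a filter, since a battery should also cover domains that do not
change within 18 months. "PVE jointly" is the leave-one-out increment
within the final selection: it is order-free, though the per-block values
sum only approximately to the total because shared variance is not
attributed twice. The package also encodes the reference minimal battery
(15 groups, 21 measures) for comparison reports.

## Symptom trajectory model

Progression is modelled on the realigned time scale `[Age − Onset_i]+`
("entry-time realignment"): subjects show essentially no measurable signs
before onset, and age itself is a poor progression clock because
enrollees are at very different disease stages. Every measure enters
through the linear predictor

    η_ijt = α_j(+cut-points) + β_j1·Age_it + β_j2·Rate_i·[Age_it − Onset_i]+

with family-specific likelihoods: cumulative logit with K−1 strictly
increasing thresholds for ordinal items (the K-th cumulative probability
is 1 by construction), log-normal regression for positive reals, and
Poisson with mean `offset · softplus(η)` for counts (offset 1 for lip
strength, the paired duration for DDK counts). Because `Age` appears for
everyone while the rate term is active only for symptomatic subjects,
gene-negative and pre-symptomatic participants identify the
normal-ageing coefficients β_j1; pre-symptomatic gene-positive subjects
are treated as having no onset within the model (their study window
precedes onset). Missing observations are simply dropped from the
likelihood, which is exact marginalization under conditional independence
and assumes missingness at random.

Priors (all in one config object): ordered thresholds N(0, 5); β_j1
N(0, 0.1) per year; β_j2 N(0, 1); continuous intercepts N(0, 10) and
σ_j half-normal(1); count intercepts N(0, 30). `Onset_i ~ N(a + b·repeat_i, τ)`
with hyperpriors a ~ N(40, 20), b ~ N(0, 2), τ half-normal(10), and the
reported onset modelled as `Reported_i ~ N(Onset_i + lag, s)` with a
shared non-negative lag (half-normal(10)) and noise s (half-normal(5)) —
reported onset in this disease lags true onset by several years, because
symptoms take time to become noticeable. `Rate_i ~ LogNormal(0, 0.5)`
resolves the multiplicative non-identifiability between the rates and
the β_j2 coefficients by anchoring the rates' geometric mean near 1.
Ages are centred at 40 years (≈ the cohort's mean onset) inside the
sampler and de-centred on output.

Posterior computation is by coordinate slice sampling (stepping-out with
shrinkage) within Gibbs, exploiting the model's structure: measure-
parameter blocks are conditionally independent across measures given the
subject latents, and subject blocks (Onset_i, log Rate_i) are independent
across subjects given the measure parameters. Slice sampling needs only a
per-coordinate step width and always accepts, which keeps the sampler
robust across the three likelihood families. Chains are initialized from
empirical statistics (threshold inits from category frequencies,
intercepts from data means, onsets from reported minus the typical lag)
with over-dispersed jitter. Convergence is declared only when split-R̂
over chains is below 1.01 for every subject latent; otherwise a warning
is raised and recorded in the diagnostics — with two chains at a few
hundred draws the latents typically show R̂ in the 1.0–1.3 range, which
is adequate for posterior-mean point estimates but callers wanting
publication-grade intervals should increase chains and draws.

The per-subject progression summary is `Rate_i·[age − Onset_i]+`: zero
until the estimated onset, then rising linearly at the estimated rate. A
subject whose estimated onset lies beyond his observation window
contributes no realigned exposure, so his rate posterior reverts to the
prior — the package reproduces this behaviour in simulation. Descriptive
association checks (estimated rate vs repeat size, initial symptom and
family; estimated onset vs repeat size) use Pearson correlations and
Kruskal–Wallis tests, skipping degenerate groupings with a notice.

## Rate heterogeneity

Measures are partitioned into 13 symptom-domain categories — rigidity,
rest tremor, other tremor, bradykinesia, limb dystonia, axial dystonia,
speech, swallowing, gait, non-motor, motor daily living, quantitative
oromotor, and BMI as its own category (log-normal, despite being excluded
from the global fit). The default mapping is a catalogue-tagged stand-in
assembled from the scale structure and the category names used in this
field; it is fully overridable by supplying a custom `CategoryScheme`.

Per-category rates `Rate_ig` are obtained by refitting the model to each
category's measures independently with the subject onsets *frozen* at the
global-fit estimates (one common time realignment) and the measure
parameters *pinned* at the global-fit posterior means, so only the
`Rate_ig` are sampled. Pinning the measure parameters is a deliberate
design choice: refitting β_j2 per category lets the multiplicative
rate-scale anchor land differently in every category (we measured ~1.4×
systematic offsets), which destroys comparability of `Rate_ig` across
categories — exactly what the rate-profile distances and the
highest-to-lowest ordering need. The cost is that per-category intervals
ignore measure-parameter uncertainty and are therefore somewhat narrow;
categories absent from the global fit (BMI) are refit freely and their
rate scale rests on the LogNormal(0, 0.5) anchor alone. Subjects are
compared by Euclidean distance between per-category rate vectors and
organized by average-linkage clustering; the tabular ordering is highest
to lowest average rate, ties broken by subject id.

## Synthetic cohort generator

The generator emulates the study conditions: 29 symptomatic / 7
pre-symptomatic / 51 gene-negative men, four visits at 6-month spacing,
the full battery plus anthropometrics, and 9% missing completely at
random (a DDK count is additionally masked when its duration offset is
masked, and BMI follows weight). Repeat sizes are DiscreteUniform[35, 55];
true onset is N(79 − 1.1·repeat, 5) years, giving onset ≈ 32 at the
median repeat and an implied reported-onset/repeat-size correlation of
about −0.75 to −0.9; reported onset adds a lag ~ N(7.5, 3) truncated at
zero (reported onset trails true onset by roughly 5–10 years);
symptomatic enrollment occurs ~4.5 years after reported onset.
`Rate_i ~ LogNormal(0, 0.5)`. Measure parameters are drawn per measure
with the β_j2 sign set by the severity direction, and magnitudes chosen
so that progression is visible over a decade of disease but near the
detection limit within an 18-month window — which is why, like a real
18-month study, default simulations yield only a handful of significant
change tests. Left/right analogue items are coupled through a Gaussian
copula (ρ = 0.8) to reproduce the strong bilateral correlations this
disease shows. Configuration hooks exist for null effects (no progression
anywhere), effects restricted to a subset of measures, per-category rate
scatter, and planted per-subject category-rate multipliers.

What passing tests on this generator show: the estimators recover the
latents and structure of data generated *from the model family they fit*
plus the stated missingness mechanism. What they do not show: robustness
to informative missingness, rating-scale drift between raters, reporting
biases correlated with severity, or model misspecification of the
trajectory shape — none of which the generator emulates.

## Problem sizes and numerical choices

The validation suites run at deliberately reduced scales chosen to keep
the full cycle reproducible on a single CPU: trajectory recovery uses 20
measures spanning all three families, 40 subjects and 2 chains × 500
draws (onset recovery r ≈ 0.96, rate recovery r ≈ 0.95 against ground
truth); correlation recovery uses p = 20, n = 200 with 9% MCAR; the null
false-discovery check uses 200 simulated null cohorts; rate-heterogeneity
checks use a 4-category scheme over 24-subject cohorts. A note on the
correlation-recovery metric: the fraction of entries within 0.15 of the
truth has high replicate-to-replicate variance because entrywise errors
share factor realizations — even the complete-data sample correlation
ranges from ~0.79 to 1.00 across seeds at n = 200 — so the acceptance
script reports it averaged over three replicates.

Tie-breaks and degenerate inputs are deterministic throughout: greedy
selection prefers earlier blocks among near-ties (tolerance 1e−6), the
subject ordering breaks average-rate ties by id, zero-variance variables
are dropped with a warning, all-zero difference vectors are untestable
rather than errors, and a category with no observed data reverts to the
prior with a warning. Cut-point ordering is enforced by support
constraints inside the slice sampler. Cohort files are written with
`%.17g` floats and read with round-trip parsing, so write-then-read is
the identity.
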