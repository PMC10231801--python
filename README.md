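# xdp-progression

A reusable analysis pipeline for natural-history studies of X-linked
dystonia parkinsonism (XDP), a neurodegenerative movement disorder
combining dystonia and parkinsonism that affects men with a `(CCCTCT)n`
hexamer expansion in a *TAF1*-intronic SVA retrotransposon. The package
implements the statistical machinery needed to turn a small longitudinal
cohort (tens of patients, a handful of visits, ~100 clinical measures)
into quantitative statements about disease progression:

- a **measure catalogue and cohort data model** for the 107-measure
  battery (MDS-UPDRS Parts 1–3, BFM disability and movement scales,
  EAT-10, CPIB, oromotor instrumentation, DDK tasks, swallow duration)
  plus anthropometrics, with delimited-text I/O and strict validation;
- a **synthetic cohort simulator** that generates cohorts with the same
  statistical structure (repeat-size-dependent onset, under-reported age
  at onset, log-normal per-subject progression rates, ~9% missingness)
  together with the ground-truth latents, so every downstream stage is
  testable without patient data;
- **change testing**: first-versus-last Wilcoxon signed-rank tests per
  measure (LOCF/NOCB endpoint imputation, reduced-sample zeros, average
  ranks, exact null for small tie-free samples) with Benjamini–Hochberg
  FDR control;
- a **Bayesian correlation model**: a multivariate normal fit by Gibbs
  sampling that marginalizes missing entries and always returns a valid
  (symmetric, PSD, unit-diagonal) correlation matrix, after severity
  orientation and a rank-based inverse-normal transform;
- **principal-variables battery selection**: greedy subset selection of
  measure blocks maximizing the explained-variance functional
  `PVE(S) = 100 · tr(R[:,S] R[S,S]⁻¹ R[S,:]) / p`;
- the **symptom trajectory model**: a hierarchical Bayesian model with
  entry-time realignment. Measure `j` for subject `i` at visit `t` enters
  through the linear predictor
  `α_j + β_j1·Age_it + β_j2·Rate_i·[Age_it − Onset_i]+`, with a
  cumulative-logit likelihood for ordinal items, log-normal regression
  for positive reals, and Poisson regression with a softplus mean and
  exposure offset for counts. Per-subject age at onset `Onset_i` and rate
  of progression `Rate_i` are latent; onsets are informed by the reported
  onset (modelled as lagging true onset), the SVA repeat size, and all
  observed measures. Posterior means are computed by MCMC (slice sampling
  within Gibbs);
- a **rate-heterogeneity analysis**: per-category rate refits with the
  realignment frozen at the global fit, Euclidean rate-profile distances,
  and hierarchical clustering of subjects by progression pattern.

## Worked example

```python
from xdp_progression import (SimulationConfig, simulate_cohort, run_change_tests,
                             empirical_onset_repeat_correlation)

cohort, truth = simulate_cohort(SimulationConfig(seed=1))
print(f"subjects: {len(cohort.subjects)}, observations: {len(cohort.observations)}")
print(f"onset vs repeat-size correlation: {empirical_onset_repeat_correlation(cohort):.2f}")
results = run_change_tests(cohort, fdr_level=0.05)
print(f"significant at FDR 0.05: {sum(r.significant for r in results)} of {len(results)}")
for r in results[:3]:
    print(f"{r.test_unit:<22} n={r.n_subjects} mean={r.mean_difference:+.2f} "
          f"W={r.w_statistic:+.0f} p={r.p_value:.4f} p_adj={r.p_adjusted:.4f}")
```

prints

```
subjects: 87, observations: 34715
onset vs repeat-size correlation: -0.92
significant at FDR 0.05: 1 of 99
weight                 n=29 mean=-2.17 W=-353 p=0.0001 p_adj=0.0134
bfm_move_neck          n=29 mean=+1.93 W=+255 p=0.0020 p_adj=0.1010
updrs1_11              n=29 mean=+0.83 W=+111 p=0.0035 p_adj=0.1144
```

The simulated cohort has 29 symptomatic gene-positive, 7 pre-symptomatic
gene-positive and 51 gene-negative men over four six-monthly visits.
Reported onset is strongly negatively correlated with repeat size, as in
real cohorts. Over an 18-month window with default effect sizes, few of
the 99 test units clear the FDR bar — here participant weight, which
declines by about 2 kg on average (`W` is the sum of signed ranks, so a
negative value means declines dominate). `mean` is the average first-to-
last change and `p_adj` the BH-adjusted p-value.

## Command line

Every stage is also a subcommand of `xdp-progression`:

```bash
xdp-progression simulate --seed 7 --out-dir cohort/
xdp-progression test-change --cohort cohort/ --fdr 0.05 --out change.csv
xdp-progression correlate --cohort cohort/ --draws 600 --seed 3 --out corr.csv
xdp-progression select-battery --corr corr.csv --pvals change.csv --k 15 --out battery.csv
xdp-progression fit-trajectory --cohort cohort/ --seed 5 --out posterior/
xdp-progression fit-rates --cohort cohort/ --onsets posterior/latents.csv --seed 9 --out rates/
xdp-progression run-all --seed 5 --out-dir run/ --small
```

`run-all` wires the stages end to end on a simulated cohort and writes a
manifest with per-stage seeds and output hashes.

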