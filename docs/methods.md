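# Methods

This note records the statistical model behind `mrmediate`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions a user auditing results should know.

## Causal model and estimators

All analyses operate on two-sample summary data: per-variant effect estimates
(β̂, se) for an exposure from one GWAS cohort and for an outcome from another,
non-overlapping cohort. The instrumental-variable assumptions are the usual
three: relevance (variants associate with the exposure), exchangeability (no
confounding of the variant–outcome relation) and exclusion restriction
(variants affect the outcome only through the exposure).

**Instrument selection.** Variants pass a p-value threshold (default 1×10⁻⁵
for exposures, the customary relaxation for traits with few genome-wide hits;
5×10⁻⁸ when the outcome itself is instrumented for reverse MR) and are then
greedily clumped: survivors are ordered by ascending p, the best is kept, and
any other survivor on the same chromosome within 10,000 kb whose r² with it
is ≥ 0.001 is removed. If no LD lookup is supplied, every in-window pair is
treated as correlated (pure distance pruning) — conservative, and exact for
the generator's default no-LD worlds. The package never computes LD from
genotypes and ships no reference panel; a user-supplied pairwise r² lookup
(mapping or callable) restores panel-based behaviour. Instrument strength is
flagged with the single-variant F = (β/se)²; an alternative
F = (n−2)·R²/(1−R²) with R² = 2·eaf·(1−eaf)·β² is available via
`SelectionConfig(f_formula="r2")` since the literature uses both and neither
is universally reported.

**Harmonization.** The outcome's alleles are aligned to the exposure's effect
allele: matching pairs pass through, swapped pairs negate the outcome beta
(and reflect eaf), incompatible pairs are dropped. Palindromic variants (A/T,
C/G) are oriented by allele frequency when both eafs are available and at
least 0.08 from 0.5, and dropped otherwise — the conservative standard
default; the window is configurable. Every decision is recorded in a
per-variant audit table.

**Estimators.** IVW is the weighted regression of outcome betas on exposure
betas through the origin with weights 1/se_out²; by default its SE is
multiplied by max(1, √(Q/(k−1))) (multiplicative random effects with the
inflation floored at 1, the mainstream two-sample MR default), with a
fixed-effect option. MR-Egger re-orients instruments to β_exp ≥ 0, adds an
intercept (average directional pleiotropy under the InSIDE assumption), floors
the residual dispersion at 1 the same way, and uses t(k−2) p-values because
the intercept test's small-k behaviour matters. The weighted median
interpolates the inverse-variance-weighted CDF of per-variant ratios at 0.5
and is consistent while ≥50% of weight is on valid instruments. The mode
estimators place a Gaussian kernel density over the ratios with bandwidth
0.9·min(sd, 1.4826·mad)·k^(−1/5) (falling back to whichever spread measure is
nonzero), evaluate it on a 2048-point grid spanning [min−3h, max+3h], and
break density ties toward the weighted median so the result is deterministic.
Weighted-median and mode SEs come from a parametric bootstrap (default 1000
draws, seeded; inputs are canonically sorted by variant id first so results
are reproducible across platforms).

A deliberate consequence of the two flooring conventions: under a perfectly
homogeneous world the random-effects IVW and Egger tests are conservative
(measured IVW CI coverage ≈ 97%, Egger size ≈ 0.03 at nominal 0.05). The
calibration tests therefore use the fixed-effect model, which is the matched
estimator when heterogeneity is structurally absent; real analyses should
keep the conservative default. The bootstrap-SE estimators are also
conservative (empirical size ≈ 0.01): resampling the exposure betas makes the
bootstrap ratio distribution heavy-tailed, which inflates its SD relative to
the sampling spread of the estimator itself. This is a property of the
bootstrap-plus-normal-p construction, not a defect; these estimators control
type-I error but sacrifice power.

**Sensitivity suite.** Cochran's Q uses first-order ratio weights
(β_exp²/se_out²) against the fixed-effect pooled ratio, df = k−1, with
I² = max(0, (Q−df)/Q) reported alongside. MR-PRESSO follows the published
algorithm's structure: each variant's outcome beta is predicted from the
leave-one-out IVW slope; the observed weighted RSS is compared against
parametric replicates drawn under the no-pleiotropy model (default 1000,
seeded); empirical p-values use +1 smoothing so the floor is 1/(n_sim+1);
per-variant outlier p-values are Bonferroni-compared to 0.05/k; when outliers
are flagged, IVW is recomputed without them and the raw-minus-corrected
difference is tested against differences from simulated outlier-free sets
with equally many random removals. The distortion p is reported but never
used for automatic exclusion. Leave-one-out re-runs IVW with each variant
dropped. Diagnostics are exported as plain tables (scatter with per-method
fitted lines, funnel of ratio vs precision) with optional matplotlib
rendering.

## Mediation

The two-step design estimates β_all (exposure→outcome), β₁ (exposure→
mediator) and β₂ (mediator→outcome) as three univariable MR analyses, each
with its own instruments; β₂ is the mediator's *total* effect on the outcome,
which is what two-sample summary data supports — no multivariable adjustment
for the exposure is attempted, a documented limitation. The mediated
proportion (β₁·β₂)/β_all is reported exactly as computed, including negative
values and values above 1. Its SE is a first-order delta method treating the
three estimates as independent (they come from non-overlapping cohorts),
computed in the expanded form var(indirect)/β_all² + indirect²·se_all²/β_all⁴
so the β₁ = 0 or β₂ = 0 limits need no special-casing. The source analyses
report only point proportions; the SE/CI are an extension and labelled as
such. With a rare-disease outcome the total-effect leg dominates the
uncertainty: its relative SE is bounded by the requirement that individual
forward loci stay below genome-wide significance in the outcome, so
per-replicate proportion estimates carry an SD of roughly 0.06 under the
validation scenarios and a small positive ratio-estimator bias (≈ +0.015,
second-order in 1/z of the total effect) that the recovery tests account for.

## Pipeline

The forward screen runs every exposure and candidate mediator against the
outcome (IVW primary, all complementary estimators and the sensitivity suite
alongside); a trait is selected when its IVW p < α (default 0.05, nominal —
the design this package reimplements screens at nominal significance, and
Benjamini–Hochberg columns are reported alongside, never substituted).
Exposures with no usable instruments are reported as skipped, not errors.
"Positive in reverse MR" is interpreted as reverse IVW p < α using
genome-wide-significant outcome instruments; when the outcome has none, all
exposures are retained with a flag. Note the filter's own alpha: ~5% of
truly forward-causal exposures are dropped by chance, which is inherent to
the design. Mediator classes excluded before linkage are metabolite ratios
and unknown metabolites (substring rules "ratio"/"unknown" plus the X-
identifier prefix convention, configurable). Every stochastic step derives
its seed from the run seed and the analysis labels (CRC32-based, < 2³¹), so
pipeline outputs are a pure function of inputs, config and seed; reruns are
byte-identical. Outputs are TSV tables (estimates mirroring forest-plot
columns, reverse-MR table, mediation table, screen summary, harmonization
audit), per-analysis sensitivity JSONs, and a provenance log with config and
library versions.

## Synthetic-data generator

`simulate_sumstats` generates summary statistics at the summary level: true
per-variant marginal effects are computed from the structural model

- exposure: γ_j (instruments scaled so Σ 2·maf(1−maf)·γ² equals h²_x),
- mediator: β₁·γ_j + δ_j (δ the mediator's own instruments, scaled to h²_m),
- outcome (log-odds): (θ + β₁β₂)·γ_j + β₂·δ_j + η_j + α_j,

where η are outcome-specific susceptibility loci (what reverse MR instruments
on) and α per-variant direct (pleiotropic) effects; observed betas add
N(0, se) noise with the analytic GWAS SE — 1/√(2·maf(1−maf)·n) for
continuous traits and 1/√(2·maf(1−maf)·n·prev(1−prev)) for the case-control
outcome (an effective-sample-size approximation to a logistic GWAS). Three
independent noise streams model non-overlapping cohorts; a single seed drives
all streams through SeedSequence spawning, so output is bit-reproducible.
Default cohort sizes encode the study setting the package targets: a
case-control outcome of 6435 cases/446,419 controls, an 8299-sample
metabolite GWAS, and a 50,000-sample exposure GWAS. Variants sit on one
chromosome spaced beyond the 10,000 kb clump window (no LD); an optional
block-LD mode places blocks of variants 1 kb apart and emits the pairwise r²
lookup that `select_instruments` consumes. A `beta_reverse` switch generates
a reverse-causation world in which the variants instrument the outcome
liability and the exposure is downstream.

Pleiotropy scenarios draw exposure effects with all-positive orientation:
with random instrument orientation a constant-mean direct effect cancels
after Egger's reorientation and biases nothing, so directional-pleiotropy
scenarios are only meaningful with oriented instruments. In the
`directional_pleiotropy` preset 30% of instruments carry N(0.05, 0.01) direct
effects; the mean direct effect over all instruments (0.015) is what the
Egger intercept estimates and is recorded in `SimTruth.pleiotropy_mean`.

What the generator does **not** emulate — and hence what passing tests do not
establish about real data: linkage disequilibrium beyond the optional
constant-r² blocks, allele-frequency and effect-size architecture of real
traits, sample overlap between cohorts, winner's-curse in instrument
discovery, population stratification, strand-mislabelled or multi-allelic
variants, and logistic-regression finite-sample effects in the case-control
outcome. Validation on this generator demonstrates correctness of the
estimators and workflow under the stated model, not robustness to those
real-data complications.

## Validation scenario sizes

The test suite's statistical checks use 100–500 replicates per claim
(rejection-rate and coverage bands are matched to the binomial error at those
sizes), MR-PRESSO with 1000 simulations, and bootstrap sizes of 150–1000
depending on the role of the test; these sizes were chosen so the whole suite
documents the package's statistical behaviour while remaining routinely
runnable. The acceptance script's two checks are closed-form arithmetic on
published odds ratios and run in milliseconds.

## Known limitations

- β₂ is a total, not exposure-adjusted, mediator effect; overlapping
  pathways will double-count shared components.
- The delta-method proportion CI treats the three legs as independent and
  normal; with weak total effects the ratio distribution is skewed and the
  CI becomes conservative.
- Distance-only clumping without an LD panel can over-prune dense regions
  and under-prune long-range LD.
- The reverse-MR exclusion is a nominal-α filter, with the false-drop rate
  that implies.
- No Steiger directionality filtering, MR-RAPS, correlated-instrument IVW,
  or Radial-MR; these are outside the reimplemented design.
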