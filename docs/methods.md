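# Methods

This note documents the models and procedures `cytoilc` implements, the
defaults and why they were chosen, what the synthetic cohort does and does
not emulate, and the numerical choices that matter for reproducibility.

## Logicle scale and automatic parameters

The analysis scale is the logicle (biexponential) display scale: linear
around zero over `W` decades, logarithmic at high signal, `M` total decades,
raw top-of-scale `T`, and `A` extra negative decades. The forward map is the
analytic biexponential `B(y)`; the transform `logicle(x)` is its numerical
inverse, computed by bracketed bisection on `y ∈ [−A−1, M+A+3]` to an
absolute tolerance of 1e-8 decades (vectorized; ~34 bisection sweeps). The
shape constant `p₀` solves `W = 2·p₀·log10(p₀)/(p₀+1)` by Brent's method;
`W < 1e-9` is treated as `W = 0` (`p₀ = 1`), where the bracket degenerates.

Automatic per-channel parameters follow the standard automatic-logicle
recipe: `T` = channel maximum, `M = 4.5`, `A = 0`, and
`W = (M − log10(T/|r|))/2` with `r` the 5th percentile of the channel's
strictly negative events, clamped to `[0, M/2]`. Mass-cytometry dual counts
are non-negative, so channels typically have no negatives and fall back to
`W = 0.25`, which keeps a visible linear region. All four parameters and the
quantile are overridable. Parameters are estimated on the *pooled* events of
all samples (merge-then-transform), so positivity calls are comparable
across samples; per-sample estimation is available for the pre-gating step
only (below).

The fixed positivity threshold — ≥ 1 decade is positive, < 1 negative,
inclusive at exactly 1 — is defined on this transformed scale and drives the
pre-gate, the hierarchical gate, and co-expression fractions.

## Pre-gating and subsampling

The acquisition-time gates (live, singlet, CD45+) are replaced by explicit
threshold rules so the selection is deterministic and testable: CD45 ≥ 1
decade, optionally a viability-channel maximum and a DNA-channel minimum.
Because pre-gating precedes the cohort-wide transform, rule channels of
raw-scale input are viewed through a temporary per-sample automatic-logicle
transform; transformed input is thresholded directly.

Each sample is then subsampled to exactly 5000 events uniformly without
replacement (per-sample seed = master seed + sample index, so results do not
depend on cohort composition elsewhere in a run). Samples with fewer events
contribute everything with a logged warning by default (`take_all_warn`);
an `error` policy is available. Pooling concatenates samples and tags every
event with its sample and stage.

## Hierarchical ILC gate

Each CD45+ event receives exactly one label:

1. any lineage marker (CD3, CD19, CD14, ILT3) positive, or CD56 positive,
   or CD127 negative → `nonILC`;
2. else CRTH2 positive → `ILC2`;
3. else c-Kit positive → `ILC3`, split by NKp44 into `ILC3_NKp44pos` /
   `ILC3_NKp44neg`;
4. else → `ILC1`.

The CRTH2 branch must precede c-Kit: the ILC2 definition does not condition
on c-Kit, while ILC3 requires CRTH2 negativity, so a CRTH2+c-Kit+ event is
an ILC2. NKp44 is consulted only inside the ILC3 branch; NKp44+ events
elsewhere are not specially labeled. The test suite checks the vectorized
gate against an independent set-definition oracle over all 2⁹ positivity
patterns of the nine gating markers. All subset percentages use CD45+
events as the denominator.

## Group statistics

*t-test.* The unpaired two-sample t-test defaults to the pooled-variance
(Student) form, `df = n_a + n_b − 2`; Welch–Satterthwaite is available by
flag. Two identical constant samples return `t = 0, p = 1` by convention;
zero combined variance with unequal means is an error. One-way ANOVA
supplies `MSE` and `df_error` for the range test.

*Duncan's multiple range test.* Group means are ordered; a stretch of `p`
adjacent ordered means is tested against
`R_p = q(α_p, p, df_e) · sqrt(MSE/n_h)` at the protection level
`α_p = 1 − (1−α)^{p−1}` (default `α = 0.05`), where `q` is the upper-tail
studentized-range quantile and `n_h` is the harmonic mean of the two
compared group sizes (Kramer adjustment — cell-level groups are unequal by
construction). Testing is step-down: once a stretch is declared
homogeneous, every pair inside it is non-significant. Reported homogeneous
subsets are the maximal intervals of ordered means containing no
significant pair. Consequence worth knowing: under a complete null the
*adjacent*-pair rejection rate is well below α (an adjacent pair is only
reachable when the enclosing stretch rejects); the quantities with exact
nominal levels — the single pair at k = 2 (rate α) and the extreme pair at
k = 3 (rate α₃ = 0.0975) — are what the calibration tests check. Duncan
significance is reported as a range-based flag at the protected level, not
as per-pair p-values, and no additional correction across markers is
applied.

Studentized-range quantiles use scipy's distribution for finite `df`; for
`df > 1e5` the df→∞ limit is computed directly by numerical integration of
the k-normal range distribution and Brent inversion (tolerance 1e-6), since
the finite-df routine is unreliable at extreme `df`.

## Embedding and model-based clustering

t-SNE (perplexity 30, 1000 iterations, PCA initialization, fixed seed) embeds
the ILC events on ten markers: the gate's identification set less CD45
(CD127, CRTH2, c-Kit, NKp44, CD56) plus five regulatory/activation receptors
(CD161, NKp46, NKp30, CD69, CCR6). The marker list is configurable — which
ten markers the original analysis used is not itemized, so this default is a
documented choice, not a fact.

The 2-D coordinates are fitted by EM with six Gaussian-mixture covariance
families (spherical/diagonal/full × equal/varying across components: EII,
VII, EEI, VVI, EEE, VVV — the 2-D-relevant subset of the classical
model-based-clustering taxonomy). Initialization is k-means++-style center
seeding with hard assignment; convergence at log-likelihood change < 1e-6
or 500 sweeps; a covariance floor of 1e-8 times the mean coordinate
variance guards against collapse, and degenerate fits restart with up to 5
derived seeds. The log-likelihood is asserted non-decreasing at every EM
step. Model selection maximizes `BIC = 2·loglik − k·log n` over G = 1..9 ×
6 families, breaking ties toward smaller G, then the simpler family.
Clustering operates on the t-SNE coordinates deliberately — that is the
analysis path being reproduced — despite the known caveat that t-SNE
distorts densities; a marker-space mode can be had by fitting
`gmm_fit` to marker columns directly.

Capping the search at G = 9 mirrors the reference tool's default search
range. On the synthetic cohort the ILC pool contains nine planted templates
with internal subtype substructure, so the embedded data contain at least
nine separated modes and BIC selects the cap in most replicates; the
recovery test requires a majority of 5 seeded replicates.

## Synthetic cohort

The generator emulates the *statistical shape* of a 21-sample CyTOF study:

- **Cohort**: 21 samples × 6000 CD45+ events (subsampled to 5000 in the
  pipeline), stages 12 × T2, 6 × T3, 3 × T4.
- **Subsets**: per-event multinomial draws at ILC1 0.78%, ILC2 0.54%,
  NKp44+ILC3 0.10%, NKp44−ILC3 0.09% of CD45+ cells; the remaining ~98.5%
  is filled by four background templates (CD3+ T, CD19+ B, CD14+ILT3+
  myeloid, CD56+CD127− NK) that exercise every exclusion branch of the gate.
- **Stage effect**: the ≥T3 : T2 ILC1 frequency ratio (default 2.4) is
  applied with the cohort-level mean pinned at 0.78%
  (`f_T2 = f·21/(12 + 2.4·9)`), so pooled-frequency recovery and the stage
  association hold simultaneously. Only ILC1 carries a stage effect.
- **Clusters**: nine ILC templates fix the non-defining embedding markers,
  the functional program (Th17 program in clusters 1/3/4/5, Th1 program in
  2/8, exhaustion markers in 7/9, CD103/CD69 co-expression in 5/8) and a
  subtype mix (ILC1 in all nine clusters, ILC2 in 2/4/8/9, NKp44+ILC3 in 5,
  NKp44−ILC3 in 7/8); the defining markers CRTH2/c-Kit/NKp44 follow each
  event's drawn subtype.
- **Signal model**: positive markers ~ lognormal(median 500 counts,
  sdlog 0.5); negative markers ~ zero-inflated exponential (90% exact
  zeros, scale 0.3 counts). Every template must pass a closed-form
  calibration check at construction: under a reference channel scale
  (T = 5000, W = 0.25) positives exceed the 1-decade threshold and
  negatives stay below it with probability ≥ 0.95 each. The background
  scale is deliberately small: with `W = 0.25` and realistic channel
  maxima the raw threshold sits near 0.8–1.8 counts, and a heavier
  background tail would push negative-marker false-positive rates past the
  calibration bound and visibly bias the recovered subset frequencies.
- **Dispersion**: per-sample subset frequencies are multinomial at the
  stage-conditional rates by default. True inter-patient dispersion is
  unknown; an optional `between_sample_concentration` activates a
  Dirichlet perturbation of the per-sample category probabilities for
  sensitivity analyses, at the cost of widening the pooled-frequency
  sampling band beyond the binomial default the recovery tests assume.
- **Determinism**: all randomness derives from the single spec seed via
  per-sample generators seeded with (seed, sample index).

What it does **not** emulate: mass-channel spillover, bead-drift or
acquisition-time effects, doublets, debris, batch differences between
samples, and continuous (rather than template-quantized) phenotype
variation. Passing tests therefore demonstrate that the *pipeline* is
correct and calibrated under its assumptions, not that the gate or the
cluster count would behave identically on real bladder-tumor data.

## Problem sizes and defaults in tests

The default study-scale conditions (21 × 5000 pooled events, G search to 9)
are used for the recovery tests; orchestration/determinism tests use a
6-sample, 1000-event configuration with perplexity 8 and G ≤ 3, which is the
smallest cohort on which every stage (including the cluster-level Duncan
contrasts) is well posed. Monte-Carlo calibration checks use 2000 replicates
(null rejection rates, p-uniformity) and 2×10⁶ draws (studentized-range
quantile oracle).

## Known limitations

- FCS support covers list-mode float data (the subset modern instruments
  and this pipeline exchange); integer-mode and multi-dataset files are out
  of scope, and CSV is the primary interchange format.
- The staining panel lists 36 antibody targets while the study abstract
  counts 35 parameters; the shipped default panel carries the 36 explicit
  names, and the discrepancy is inherited from the source description.
- Duncan's test is reported as significance flags at the protected level;
  exact per-pair p-values are not defined for the range-based procedure.
- Survival analysis and NK-cell (CD56+) subset analysis are explicitly out
  of scope.
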