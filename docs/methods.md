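# Methods

This note documents the models, conventions, numerical choices and known
limitations of the `rsmeta` pipeline, stage by stage.

## Data model and preprocessing

The pipeline operates on per-cohort integer count tables (samples x
features), per-sample metadata (study, subject, and either a
baseline/endpoint timepoint or an HC/CD/UC diagnosis), and optionally a
rooted phylogeny over the features. Conventions, all overridable:

| parameter | default | role |
|---|---|---|
| minimum sample depth | 1,000 reads | samples below are excluded everywhere |
| rarefaction depth | 1,000 reads | diversity analyses only |
| prevalence filter | 10% of samples (ceil, detected = count > 0) | differential abundance and networks |
| CLR pseudocount | 1 | structural zeros |
| FDR level | 0.05 | BH across features / contrasts |
| edge retention | \|r\| >= 0.1 (inclusive) and permutation p < 0.05 (strict) | networks |
| rewiring flag | combined score > 0.12 | networks |
| permutations | 999 (PERMANOVA), 100 (network p-values) | |
| forest size | 500 trees, library defaults otherwise | ML validation |

Rarefaction is a seeded multivariate-hypergeometric draw (subsampling
without replacement); a single draw per sample is used rather than
rarefaction averaging. Raw counts feed the CLR/ΔCLR stage — rarefaction is
applied **only** to diversity analyses. CLR uses the natural log; CLR
output is base-invariant up to a positive scalar and every downstream
statistic used here (signs, z-statistics, rank-based quantities) is
invariant to that scalar. Shannon entropy is reported in bits; the paired
Hedges' g downstream is scale-invariant, so the base choice is cosmetic.
Faith's PD includes the root connection and weighted UniFrac is
unnormalized (both computed through scikit-bio, matching the common QIIME
conventions); a normalized weighted-UniFrac variant exists behind a flag
but is not used by the pipeline.

## Synthetic multi-cohort generator

The generator is logistic-normal/multinomial. For subject j in study i,
feature k, timepoint t in {0, 1}, the latent log-weight is

    eta = beta_k + u_ik + s_ijk + t * delta_k + eps,

with feature baselines beta_k ~ N(0, 1), study offsets u ~ N(0,
sigma_study^2), subject offsets s ~ N(0, sigma_subject^2) shared by the
subject's two samples, residual noise eps ~ N(0, sigma_noise^2) per
sample, and counts ~ Multinomial(depth, softmax(eta)) with depth uniform
on a configured range. Because CLR(softmax(eta)) = eta − mean(eta), the
within-subject CLR difference inherits exactly the additive structure the
random-intercept model assumes, which is what makes parameter recovery a
meaningful end-to-end check. Subject effects cancel in the difference —
the statistical reason the pipeline insists on strict pairing.

The default recovery scenario mirrors the geometry of a realistic 7-cohort
design: 7 studies x 30 subjects, 200 features, a 22-feature module
depleted at delta = −0.8, sigma_study = 0.5, sigma_subject = 1.0,
sigma_noise = 0.5, depths 5,000–20,000. The cross-sectional variant adds a
per-diagnosis enrichment (default CD +1.0, UC +0.4, HC 0) to module
features, with study offsets shared across diagnosis groups; its default
size (4 studies x 40 per group) keeps desk-scale runs fast.

**The closure effect.** Depleting a module moves every *other* feature's
true CLR by −mean(delta) (here +22·0.8/200 ≈ +0.09): compositional data
cannot deplete a subset without nudging the complement. At n = 210 subjects
the mixed model correctly detects many of these induced positive shifts.
Recovery metrics therefore concern *depletion* discoveries (q < 0.05 and
negative pooled ΔCLR): against that set, sensitivity for the planted module
is essentially 1 and the false-discovery proportion essentially 0, while
the complementary positive detections are the closure effect, not errors.
This is a real property of CLR-based differential abundance worth keeping
in mind when interpreting "enriched" features in any such analysis.

What the generator does **not** emulate: sequencing-region-specific
amplification bias, chimeras, overdispersion beyond the logistic-normal
layer, taxonomic correlation structure (features are exchangeable apart
from the module), and longitudinal drift. Passing tests show the
statistical machinery is correct and calibrated under the stated model;
they do not certify performance on real amplicon data.

## REML engines

Two places need restricted maximum likelihood and share one engine
(`rsmeta.lmm`): the per-feature ΔCLR model (intercept-only) and the
disease-module model (diagnosis fixed effects, reference-coded). The
restricted likelihood of y = Xβ + Zb + e with a single random intercept is
profiled over λ = τ²/σ²: for fixed λ, β (GLS) and σ² (REML denominator
N − p) are closed-form via per-group Woodbury blocks, leaving a 1-D
criterion scanned on {0} ∪ geomspace(1e−8, 1e6, 100) and refined by bounded
optimization (xatol 1e−10). The λ = 0 boundary is always a candidate and a
boundary fit is a legitimate result, not an error; a constant response is
reported as a degenerate fit with a warning. With a single group τ² is
unidentifiable and fixed at 0. Wald z inference (normal reference) is used
throughout rather than t with Satterthwaite degrees of freedom — the main
inferential approximation, adequate at the pooled sizes this pipeline
targets (~200+ observations, ≥4 studies) and slightly conservative at the
default geometry (null p-values are near-uniform with a mild deficit of
small values).

Meta-analytic pooling of per-study Hedges' g uses the same REML idea with
known sampling variances: τ² maximizes the restricted likelihood of
g_i ~ N(μ, v_i + τ²) (grid pre-scan + bounded refinement, boundary checked),
μ is the inverse-variance weighted mean at the optimum, and the 95% CI is
z-based with no Knapp–Hartung adjustment, matching the common
reference-implementation default. The z interval's coverage is verified at
~0.94 in the k = 20 regime; with few studies (k ≈ 5–7) and large τ²/v it
is known to undercover by a few points — a property of the method, not the
implementation.

The effect size itself is the change-score standardized mean difference:
mean(endpoint − baseline) / SD(differences) with the small-sample
correction J = 1 − 3/(4(n−1)−1) and variance 1/n + g²/2n. Alternatives
(pre/post-SD standardizers, exact variance forms) exist; the change-score
form matches the within-individual framing of the design.

## PERMANOVA

SS_total = Σ_{i<j} d²_ij / n; SS_within sums the per-group analogues;
F = (SS_between/(a−1)) / (SS_within/(n−a)). The repeated-measures scheme
permutes only within subject blocks of two samples — independent
baseline/endpoint label swaps, the only permutations preserving the
pairing — enumerating all 2^S patterns exactly when 2^S ≤ n_perm (the
p-value is then exact, counting the observed pattern among the 2^S) and
Monte-Carlo sampling with the add-one convention otherwise, so p is never
zero. Permutation F-statistics are computed vectorized over all
relabelings via quadratic forms in the squared-distance matrix. The
combined cross-cohort run blocks by subject and does not additionally
model study as a fixed term; study R² is reported separately from the
unrestricted baseline analysis.

## SparCC and rewiring

Per resample, per-sample fractions are drawn from Dirichlet(counts + 1);
the variation matrix t_ab = var(log(x_a/x_b)) is computed from the
log-fraction covariance; basis variances ω solve the linear system
(diag(d) + E) ω = t under the sparsity assumption, where E marks included
pairs; correlations r_ab = (ω_a + ω_b − t_ab) / (2 √(ω_a ω_b)) are clipped
to [−1, 1]; the most strongly correlated included pair is excluded and the
system re-solved, up to 10 iterations or until max |r| < 0.1 among
candidates (the original algorithm's conventions: 20 resamples, 10
exclusion iterations, threshold 0.1). The point estimate is the median over
resamples. Non-positive basis variances are clamped with a warning;
exclusion stops if it would leave a feature with fewer than two included
pairs. Permutation p-values shuffle every feature independently across
samples and recompute the point estimate with a single inner resample for
tractability.

The rewiring score is a deliberate, documented re-implementation choice:
node-level topology change is quantified as
|s_B − s_A| / (s_A + s_B + 1e−9), where s is the within-module absolute
edge strength (module membership from greedy modularity maximization on
the union graph's absolute weights). The score is bounded in [0, 1), zero
for identical networks, symmetric in the two networks, and combined across
cohorts by a sample-size-weighted mean; the 0.12 flag threshold is a
convention for "strongly rewired". Per-cohort networks are built on a
shared post-filter feature set per cohort so baseline and endpoint compare
like with like. The pipeline caps network inference at the top features by
abundance (default 50) — co-occurrence estimation for rare features at
desk-scale sample sizes is noise-dominated.

## Classifier validation

Random forests (500 trees, default settings, class-probability scores)
with three schemes: within-study 5-fold CV (subjects shuffled with a seed
and dealt round-robin; held-out scores pooled into one ROC per study),
cross-study validation (one fit per training study, evaluated on each
other study), and LOSO (fit on the pooled remainder). Every split is
subject-blocked and a structural leakage assertion runs on every fold.
CLR features are the default for taxa; disease-contrast models use
relative abundances, and a module-restricted model subsets features
*after* normalization so module features keep their whole-community scale
(subsetting before normalization would renormalize within the module and
erase the level signal being tested). Classes represented by a single
study are excluded from class-stratified summaries.

## Disease-module validation

The module score is the per-sample sum of module-feature relative
abundances, analyzed on the raw proportion scale (a logit flag would be a
sensitivity analysis; adjusted means are then proportions x 100). Module
members absent from a cohort's table contribute 0 with a logged warning.
Marginal means are model predictions at a zero random effect; contrasts
are Wald z with BH correction, and their estimates are invariant to the
reference-level choice. Cohorts lacking one arm of a contrast are excluded
from that contrast only.

## Problem sizes used in checks

The packaged checks run the default 7x30 recovery scenario for
differential abundance (5-seed panel), a 4-study x 15-subject ladder over
delta ∈ {0, −0.4, −0.8, −1.6} for classifier monotonicity, 1,000
small-cohort replicates for restricted-permutation type-I error, 2,000
simulated meta-analyses (k = 20) for pooled-CI coverage, and 600 simulated
cross-sectional datasets for contrast coverage and bias — sizes chosen so
each Monte-Carlo bound is sharp relative to its binomial noise while the
whole suite stays desk-scale.

## Known limitations

- Wald-z inference everywhere (no small-sample df corrections); mildly
  conservative per-feature nulls at the default geometry, undercoverage of
  the pooled CI for very few studies.
- Single-draw rarefaction; no rarefaction averaging or variance
  propagation.
- The rewiring score is this package's own bounded statistic, not a
  reproduction of any external tool's internals.
- No covariate adjustment (age, sex, medication) in either the paired or
  the cross-sectional models; the data model carries no such columns.
- Zero-inflation is handled only through the CLR pseudocount.
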