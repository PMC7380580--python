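# Methods

This note documents the models, the synthetic-data generator, and the
numerical and design choices behind `fermomics`.

## Differential ranking

**Model.** For sample i with covariate row x_i and library size n_i,

    counts_i ~ Multinomial(n_i, softmax(x_i B)),

with independent normal(0, `prior_sd`²) penalties on the coefficients.
B is parameterized in additive-log-ratio (ALR) coordinates against a
reference feature (by default the most prevalent one, ties by total then
ID); after fitting, coefficients are re-expressed as centered (CLR)
differentials, so each covariate's differentials sum to zero. Absolute
differentials are unidentifiable from relative data; the package's
contract is that only their *ordering* (and ratios built from it) is
interpreted.

**Likelihood weighting.** Each sample enters the loss through its count
*proportions* with equal weight, i.e. the likelihood is evaluated as if
every sample carried a fixed `nominal_depth` of multinomial draws
(default 1,000, the order of a typical post-filter library). Two
consequences, both deliberate:

* fitted differentials are *exactly* invariant to multiplying any
  sample's counts by a positive constant — the compositional claim the
  log-ratio machinery depends on becomes a theorem of the fit, not an
  approximation;
* the prior's strength relative to the data is set by `nominal_depth`
  rather than by sequencing depth, so deeply sequenced cohorts do not
  silently turn the prior off.

**Optimizer.** First-order stochastic gradient (Adam, β = 0.9/0.999)
with optional minibatching; the desk-scale default is full-batch
training (2,000 epochs, learning rate 0.05), which is deterministic
given the seed. The penalized loss in ALR coordinates is strictly
concave, so the optimum is unique; reference invariance of the *ranking*
is a tested property (Spearman ≥ 0.99 across reference choices) rather
than an assumption. `published_spec()` preserves the historical
reference configuration for this model class (5,000 epochs, batch 5,
learning rate 1e-4, a 1,000-read sample gate, 10 held-out samples); at
those settings plain fixed-rate SGD converges far too slowly at desk
scale, which is why Adam is the optimizer throughout.

**Q².** Held-out samples (chosen once by seed) are predicted as
n_i · softmax(x_i B) under the covariate model and under an
intercept-only baseline (mean training proportions). Q² = 1 − MAE_model
/ MAE_baseline: 1 for perfect prediction, ≤ 0 when covariates add
nothing. The error functional (mean absolute error on counts) is a
package choice; Q² values are comparable only within a functional.

**Extreme-rank selection.** The k largest and k smallest differentials
form the numerator and denominator sets. One consistent ordering (value
descending, ties by smaller feature ID) serves both ends, so tied
boundaries can never produce overlapping sets; at the denominator
boundary the larger ID therefore wins the tied slot.

## Log ratios and group statistics

Per sample, ln(Σ numerator counts / Σ denominator counts) in natural
log. Samples with a zero numerator or denominator sum are excluded with
a recorded reason, never imputed — pseudocounts would silently break the
scale-invariance property. Group comparisons: Welch's unequal-variance t
with Welch–Satterthwaite df; Cohen's d with the *pooled* standard
deviation (the conventional d, reported alongside the Welch t);
two-sided Mann–Whitney (exact enumeration below 20 per group when there
are no ties, otherwise the tie-corrected normal approximation without
continuity correction, so identical samples give p = 1 exactly); Pearson
chi-square without continuity correction. A Benjamini–Hochberg utility
is provided for families of tests. All tests are two-sided at α = 0.05.

## Permutation null for selected log ratios

A log ratio built from rank-selected sets separates groups by
construction; the null asks how extreme its |Welch t| is against B log
ratios of random nonoverlapping feature sets of the same sizes, drawn
uniformly from the full feature pool (features may recur across draws —
an accepted dependence of this null, most visible with small pools).
Degenerate draws (all samples excluded, or fewer than two usable samples
in a group, or a zero-variance group) are redrawn and counted in the
diagnostics. The p-value is the add-one form rank/(B+1), where rank = 1 +
#{null ≥ observed}; it can never be zero (minimum 1/(B+1)). For display
it is truncated — not rounded — to four decimals: rank 16 of B = 1,000
gives 16/1001 = 0.01598… shown as 0.0159, rank 2 gives 0.0019. The
full-precision value is retained for computation.

## Longitudinal stability

Within each subject, pairs are formed between adjacent *usable* time
points of a per-sample statistic; a sample excluded upstream leaves a
gap, and pairs bridging a gap are flagged. Pairs are pooled across
subjects into a single Spearman correlation (with an OLS fit of y on x),
matching how such panels are usually plotted; per-group stratification is
available (`stability_by_group`). Pooled correlations mix within-subject
persistence with stable between-subject (including between-group)
differences, which is why a cohort with a real group effect has a
positive pooled rho even at zero subject stability — the null-case test
therefore uses a cohort with no group effect.

## Microbe–metabolite cooccurrence

**Model.** Each microbial read is treated as emitting the sample's
metabolite profile: p(metabolite j | read of microbe m) =
softmax_j(u_m·v_j + b_j) with d-dimensional latent vectors and a
per-metabolite bias. The composite likelihood factorizes through the
weight matrix C = Xrelᵀ Yrel (per-sample relative abundances, equal
sample weights), so training is deterministic full-batch Adam on C, with
a small ridge (1e-4) on U and V for identifiability when there is no
signal. Rows of the fitted `conditional_` matrix are probability
distributions over metabolites.

**What the conditional rows mean.** The composite-likelihood optimum for
a microbe's row is an abundance-weighted average of sample metabolite
profiles, which always contains the cohort-wide metabolite marginal in
addition to the microbe-specific deviation. The *cooccurrence* content of
the model therefore lives in the column-centered log conditional matrix
(`centered_log_conditional`), which removes the shared marginal; this is
exactly the matrix the biplot SVD consumes, and it is the surface on
which recovery of planted affinities is evaluated.

**Biplot.** SVD of the centered log conditional matrix; microbe scores
U·S, metabolite loadings V, variance proportions s²/Σs², up to three
axes, each axis oriented so its largest-magnitude metabolite loading is
positive. Axis 1 can be correlated against the differentials
(`axis_vs_differentials`) to ask whether the dominant cooccurrence
gradient tracks the consumption covariate. The sign of that correlation
is only meaningful relative to an anchor; the tests anchor the axis by
the designated metabolite's loading.

## Synthetic-data generator

The generator emulates a two-group longitudinal cohort (consumer vs
nonconsumer of fermented plants) with a paired metabolite table.

**Microbial counts.** Per-sample composition is softmax(base + g·β +
subject effect + time-point noise); counts are multinomial at a
lognormal library size (defaults: log-mean 9.2 ≈ 10,000 reads, log-sd
0.5). Base logits are drawn once per simulation from normal(0, 2) to
give the heavy-tailed abundance skew rank methods face in practice. β is
the centered planted differential vector (scale `effect_scale`, default
1). Subject effects (sd 1) follow a variance-preserving AR(1),
e_t = √s·e_{t−1} + √(1−s)·fresh, so `subject_stability` s is exactly the
fraction of subject-level variance retained week to week (default 0.9).
Time-point noise (sd 1.0 by default) represents transient day-to-day
variation; at these defaults the pooled consecutive-week log-ratio
correlation of ranked sets lands around 0.6–0.8, the upper half of the
range reported for real weekly stool panels — the band was used as a
plausibility check, not a calibration target. Metadata carries subject,
week, group, a frequency answer consistent with the group, interior-
valued host covariates, and the drawn read count, so the filtering stage
runs on generator output unchanged. Presets provide 3,100-feature
(16S-like) and 153-feature (metagenome-like) pools.

**Metabolites.** The metabolite table follows the conditional model's
own forward story: each read emits from its microbe's affinity softmax
softmax_j(u_m·v_j); a sample's expected profile is the relative-
abundance-weighted mixture of emissions, multiplied by lognormal noise
(sd 0.5) and exp(planted effect · consumer indicator) for one designated
"CLA-like" metabolite, then scaled (1e5) and rounded to integer peak
heights. Design constraints, all load-bearing:

* the designated metabolite receives the *same fixed emission share*
  from every microbe, so its group association is exactly the planted
  effect (default 2 on the log scale) and nothing else — with the effect
  set to 0 its rejection rate is nominal;
* planted microbe loadings U are column-centered, the same
  identifiability convention as the differentials (the factorization
  identifies loadings only up to a per-factor shift);
* `latent_group_coupling` (default 0.7) aligns latent factor 1 with the
  planted differentials, emulating cohorts where consumption is a
  dominant axis of microbe–metabolite covariation; with coupling 0 the
  biplot axis has no systematic relation to the differentials.

**What the generator does not emulate.** Sparse presence/absence
structure beyond lognormal abundance variation, taxonomy, sequence-level
artifacts, batch effects, real mass-spectrometry peak shapes or missing-
value mechanisms, and realistic demographic covariate distributions. A
test passing on this generator shows the estimators recover the planted
statistical structure under compositional counting noise — not that they
are robust to everything real data contain.

## Problem sizes used in the test suite

Scaled-down study conditions, chosen once: differential recovery uses
100 subjects/group, one time point, 150 features (seed 7); permutation
calibration uses 200 replicates of 15-subject/group null cohorts
(B = 99) and power uses 100 replicates at 50 subjects/group, k = 20,
B = 200; cooccurrence recovery uses 150 subjects/group, two time points,
40 microbes and 100 metabolites with a single latent factor, stronger
subject-level variation (sd 3) and a flatter base (sd 0.5) — a small
retained panel is more even than a full table, and per-microbe leverage,
not sample count, limits how well conditional rows of rare microbes can
be identified from closure-confounded cooccurrence weights.

## Numerical notes and known limitations

* The filter cascade runs in a fixed order (exclusion list → read cutoff
  → abundance floor → feature totals). It is not idempotent in every
  corner case: removing low-total features lowers sample sums, so a
  second pass can newly drop a sample sitting near the read cutoff.
* Rarefaction uses `numpy`'s multivariate hypergeometric sampler
  (without replacement) under a stated seed; zeros can never become
  positive and counts never exceed the originals.
* The permutation null reuses features across draws; with small pools
  the null statistics are dependent, which the add-one p-value does not
  correct.
* Welch's t with one zero-variance group raises rather than reporting an
  effect size with an ill-defined d.
* Audit logs attribute each removed row to the first violated rule in a
  fixed order (missing field, age, BMI, height, weight, antibiotics), so
  audit counts sum exactly to rows removed.
* Q² depends on the held-out split; the split is drawn once per seed.
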