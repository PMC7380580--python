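# fermomics

Compositional multi-omics analysis of fermented-food consumer cohorts.

Sequencing-based microbiome data are compositional: only relative
abundances are observed, so "microbe X went up" is not identifiable —
only statements about ratios are. `fermomics` implements, as a tested and
reusable pipeline, the analysis pattern used to compare gut microbiomes
and metabolomes of fermented-food consumers and nonconsumers in
questionnaire-based cohorts:

1. **Cohort and table filtering** — host-covariate bounds
   (age/BMI/height/weight), antibiotic exclusion, replicate
   deduplication, read-depth cutoffs, exclusion lists (e.g. shipping
   "bloom" taxa), relative-abundance floors, and seeded rarefaction.
2. **Differential ranking** — a regularized multinomial log-linear
   regression, `counts_i ~ Multinomial(n_i, softmax(x_i B))` with a
   normal(0, σ²) prior on B, fitted in ALR coordinates and reported as
   CLR-centered *differentials* per covariate. Only the ranking of
   differentials is interpretable; model fit is scored by Q² against an
   intercept-only baseline on held-out samples.
3. **Feature-set log ratios** — for the k highest- and k lowest-ranked
   features, the per-sample statistic ln(Σ numerator / Σ denominator),
   which cancels the unknown total load; compared between groups with
   Welch's t, pooled-SD Cohen's d, rank-sum and chi-square tests.
4. **Permutation null** — the selected log ratio is validated against
   B log ratios of *random* nonoverlapping feature sets of the same
   sizes; p = rank/(B+1), displayed truncated to 4 decimals.
5. **Longitudinal stability** — Spearman correlation (plus OLS) between
   log-ratio values at consecutive time points within subjects.
6. **Microbe–metabolite cooccurrence** — a low-rank conditional model
   p(metabolite j | read of microbe m) = softmax_j(u_m·v_j + b_j),
   summarized by an SVD biplot of the centered log conditional matrix,
   ranked cooccurring-microbe lists per metabolite, and the correlation
   of biplot axis 1 with the differentials.

Because the original cohort data are not required, the package ships a
first-class synthetic-data module that generates two-group longitudinal
cohorts with planted differentials, planted microbe–metabolite affinity,
and a planted "CLA-like" group-enriched metabolite — every downstream
stage is testable against known truth.

## Worked example

```python
import fermomics as fm

cfg = fm.SimulationConfig(seed=7)          # 100 subjects, 4 weekly samples
table, meta, truth = fm.simulate_cohort(cfg)
meta = meta.assign(consumer=(meta["group"] == "consumer").astype(float))

model = fm.fit_differentials(table, meta, fm.RegressionSpec(
    covariates=("consumer",), epochs=2000, seed=0))
pair = fm.select_extreme_features(model.differentials_, "consumer", k=20)

series = fm.compute_log_ratio(table, pair, meta["group"])
res = fm.welch_t(series)
print(f"log-ratio Welch t = {res.t:.3f}, df = {res.df:.1f}, "
      f"p = {res.p:.2e}, Cohen's d = {res.cohens_d:.3f}")

perm = fm.permutation_test(table, meta["group"], pair, B=1000, seed=0)
print(f"permutation rank = {perm.rank}, displayed p = {perm.display}")

pairs = fm.consecutive_pairs(series, meta)
stab = fm.stability_correlation(pairs)
print(f"week-to-week stability: Spearman rho = {stab.spearman_rho:.2f} "
      f"over {stab.n_pairs} consecutive pairs")

mets = fm.simulate_metabolites(table, truth, cfg)
cooc = fm.CooccurrenceFactorizer(n_components=2, epochs=1500,
                                 seed=0).fit(table, mets)
top = fm.rank_cooccurring_microbes(cooc, truth.enriched_metabolite_id, 10)
print(f"mean planted differential of top-10 microbes co-occurring with "
      f"the CLA-like metabolite: {truth.beta_true[top].mean():+.2f}")
```

prints

```
log-ratio Welch t = 36.521, df = 397.9, p = 3.84e-129, Cohen's d = 3.652
permutation rank = 1, displayed p = 0.0009
week-to-week stability: Spearman rho = 0.79 over 300 consecutive pairs
mean planted differential of top-10 microbes co-occurring with the CLA-like metabolite: +1.44
```

Reading the output: the consumer-vs-nonconsumer log ratio of the 20
top-ranked over the 20 bottom-ranked features separates the groups
strongly (the cohort was simulated with a unit-scale planted effect, and
rank-selected sets are in-sample extreme by construction); the
permutation test confirms the selection is not an artifact of picking
*any* 20+20 features (rank 1 of 1,001); log ratios are stable week to
week within subjects; and the microbes that most strongly co-occur with
the planted group-enriched metabolite are themselves consumer-associated
(mean planted differential +1.44 against a cohort mean of 0).

The same pipeline is available from the shell:

```bash
fermomics simulate --preset metagenome --seed 7 --out cohort/
fermomics rank --table cohort/microbes.tsv --metadata cohort/metadata.tsv \
    --formula consumer --out diffs.tsv
fermomics permtest --table cohort/microbes.tsv --sets sets.tsv \
    --metadata cohort/metadata.tsv -b 1000 --seed 7
```

## Layout

```
src/fermomics/
  simulate.py      planted-truth cohort and metabolite generator
  filtering.py     participant/sample/feature filters, rarefaction
  ranking.py       multinomial differential regression, Q², set selection
  logratio.py      feature-set log ratios, Welch/rank-sum/chi-square, BH
  permutation.py   random feature-set permutation null
  longitudinal.py  consecutive-time-point stability
  cooccurrence.py  conditional factorization, biplot, ranked lists
  io.py, cli.py    TSV formats and the `fermomics` command group
docs/methods.md    model and generator documentation
```
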