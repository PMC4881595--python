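# Methods

## Setting and model

The pipeline analyzes k independent two-group microarray studies per
species (MCAO vs sham), each a genes × samples matrix of log2 intensities.
The working model behind both the statistics and the synthetic-data
generator: after preprocessing, a null gene's log2 expression is
Normal(baseline_g, 1) in both groups; a truly differential gene shifts its
MCAO mean in study s by a realized effect δ_gs ~ Normal(±δ, τ²), where δ is
the common standardized effect (units of the within-study SD) and τ² the
between-study heterogeneity.  Platforms measure overlapping but unequal
gene subsets, genes are represented by one or more probes, and a small
fraction of cells is missing.

## Preprocessing

Order of operations per study: log2 transform (identity if the matrix is
flagged already-log) → quantile normalization → KNN imputation → probe
collapse by the arithmetic mean → per-gene standardization → common-gene
intersection.  Rationale for the order: normalization equalizes array
distributions before distances are computed for imputation, and probes are
collapsed only once complete, so probe means never mix observed and
imputed support unevenly.

* **Quantile normalization.**  Exact sorted-row-means algorithm on complete
  matrices; ties receive the mean of the reference values over their tied
  ranks ("average ties" dialect).  Matrices with missing cells are handled
  by building the reference from per-column empirical quantiles on a common
  grid and placing observed values by rank interpolation; the complete-data
  path is unchanged and exactly multiset-identical across columns.
* **KNN imputation** (default k = 10, the classic imputation default).
  Distance between rows is Euclidean over mutually observed columns,
  rescaled by √(m/m_shared) so sparsely overlapping rows are not
  spuriously close.  Observed cells are returned bit-identical; a row with
  no observed values is an error; a candidate pool smaller than k uses all
  candidates with a warning.
* **Standardization** uses the sample variance (n−1) — it matters at n = 3.
  Fold changes are computed on the gene-level matrix *before*
  standardization: scaling each gene to unit variance destroys the
  log-ratio scale, while t statistics and standardized effect sizes are
  location-scale invariant and may use either matrix.  Constant rows are an
  error rather than silently producing 0/0.
* **Background correction** is deliberately a no-op (inputs are assumed
  summarized intensities) and the numeric quality summary is RLE only
  (per-sample median and IQR of deviations from gene-wise medians); it is
  reported, never used to auto-drop samples.

## The five meta-analytic methods

All five operate on the common-gene intersection, so k is constant across
genes; partial gene coverage is rejected by design.

1. **Fisher**: S = −2 Σ ln pᵢ over per-study two-sided t-test p-values
   (classical/pooled-variance t by default inside the meta stage: with
   normal equal-variance simulated data the per-study null p is exactly
   uniform), p from χ²(2k).  p = 0 inputs are clamped to 1e−300, never
   propagated into log.
2. **Random-effects (DerSimonian–Laird)** over Hedges' g with
   τ̂² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)) and re-weighting by
   1/(varᵢ + τ̂²).  Reduces to the fixed-effect answer whenever Q ≤ k−1.
3. **RankProduct**: per-study fold-change ranks (average ties), RP =
   (Π rᵢ)^{1/k}, separately for the up and down orientation; the null is
   built by B (default 1000) independent shuffles of each study's rank
   vector, p(g) = (1 + #{null RP ≤ RP_g})/(B·n + 1); the reported two-sided
   p doubles the smaller directional tail, capped at 1.  A Benjamini-style
   percentage-of-false-positives column (p·n/rank) is also emitted.  The
   rank-shuffle scheme (rather than full data resampling) keeps the
   permutation cost at desk scale.
4. **Weighted Z (Stouffer)** on one-sided p-values.  Default weights are
   the fixed per-study √nᵢ: weights must be independent of the per-study
   evidence for Z to be standard normal under the null.  The
   inverse-variance alternative (wᵢ = 1/var(gᵢ)) is available but
   measurably conservative (~3% rejections at α = 0.05 in the null
   simulation) because var(gᵢ) grows with gᵢ² and the weights therefore
   anti-correlate with the per-study z.
5. **Fixed-effect (Hedges–Olkin)**: inverse-variance pooling of
   unmoderated g, z = pooled/se, normal two-sided p.

**Variance moderation.**  An empirical-Bayes option shrinks per-study
pooled sample variances toward a common prior: hyperparameters (d₀, s₀²)
of the scaled inverse-χ² prior are estimated by the method of moments on
log variances (trigamma inversion by Newton iteration), and the posterior
variance is (d₀s₀² + df·s²)/(d₀ + df).  Exactly identical input variances
return the common value with d₀ = ∞.  Moderation is off by default in the
random-effects method: the pinned var(g) formula assumes the classical
denominator, and pairing it with the (much less variable) moderated
statistic overstates var(g) by ~25% and drives null rejections down to
~1.3%.

**Vote counting.**  A gene is a meta-DEG when ≥ min_methods (default 4) of
the five p-values are below α (default 0.05).  Votes use each method's
primary per-gene p (the RankProduct pfp is exported as an alternative
column but not voted on).

### Calibration, measured

Under the global-null simulation (2000 genes, k = 4, n = 5+5) the measured
rejection fractions at α = 0.05 are: Fisher ≈ 5%, RankProduct ≈ 4.6–5.4%,
Stouffer(√n) ≈ 4.5%, fixed-effect ≈ 3%, DerSimonian–Laird ≈ 2.2%; the
4-of-5 vote selects ≈ 1.5–2%.  The two effect-size poolers are
intrinsically conservative at these sizes: var(g) = (n₁+n₂)/(n₁n₂) +
g²/(2(n₁+n₂)) increases with |g|, so inverse-variance weighting shrinks
exactly the genes with the largest effects, and the τ̂² ≥ 0 truncation can
only inflate the random-effects SE.  This is a property of the estimators
at k = 4 small studies, not an implementation artifact, and it errs on the
safe (fewer false positives) side.

## Per-study differential expression and consensus

Per study: Welch t-test by default (groups of 3–24 arrays make the
equal-variance assumption fragile; Student available), Benjamini–Hochberg
adjustment always computed, calls of up/down/none from the chosen p
(raw by default) at p < 0.05 together with |log2FC| ≥ 1.5 — read literally
as a bound on the log2 difference (≈ 2.83-fold).  The default gates on the
*raw* p: gating on the BH-adjusted p at these sample sizes empties every
per-study DEG set in simulation (and could not have produced per-study DEG
counts in the hundreds-to-thousands from 3v3 designs), collapsing all
downstream stages; `use_fdr=True` switches the gate for users who want the
stricter reading.  Consensus keeps genes called in ≥ 3 of 4 studies;
direction conflicts are retained with a flag (consensus is on presence,
not direction).

## Integration, cross-species intersection, enrichment, network

The integrated set is {meta-DEGs called in ≥ 3 individual studies}; it is
by construction a subset of the meta set and of the common-gene universe.
Cross-species matching is by upper-cased symbol only — true ortholog
resolution is out of scope.  Enrichment is the hypergeometric upper tail
P(X ≥ x) with the universe equal to the per-species common-gene
intersection (a gene absent from the analyzed matrix could never have been
selected); raw p with the conventional p < 0.05 gate, BH column emitted
for reference.  The interaction network keeps edges with confidence ≥
min_score (default 0.4, the usual mid-confidence convention) among the
selected genes; "hub" is the maximum-degree node, ties broken
alphabetically — a deliberate, simple proxy for hub-ness.

## Synthetic data: what it emulates and what it does not

Defaults describe four studies per species of 5 MCAO + 5 sham arrays,
2000 genes, 5% true DEGs with δ = 2 and τ² = 0.1, 5% per-study platform
dropout, two probes per gene (probe noise SD 0.1, small relative to the
within-group SD of 1 so mean-collapse is near-lossless), and 2% missing
cells; baselines are Normal(8, 2) log2 intensities.  Values are emitted
already log2-scale by default (the pipeline operates post-log), with a
2^x raw-scale option to exercise the log2 step.  Species collections can
share the true DEG identities (independent realized effects and noise), so
the cross-species intersection has a defined truth.  The generator does
*not* emulate array-image artifacts, RNA degradation, batch effects beyond
τ², correlated genes, or real ortholog structure — so passing tests
demonstrate statistical correctness of the machinery under the stated
model, not robustness to those real-data phenomena.

Recovery rates are always quoted against *analyzable* truth — true DEGs
present in the relevant common-gene intersection(s); with 5% dropout the
4-study intersection retains ≈ 0.95⁴ ≈ 81% of genes per species.

### Sensitivity of the stages, measured at the defaults

The meta-analysis vote recovers essentially 100% of analyzable true DEGs
with a handful of false positives.  The per-study confirmation step is
intentionally high-specificity / low-sensitivity: with per-study
fold-change SD √(2/5 + τ²) ≈ 0.7 around δ = 2, a single study clears
|log2FC| ≥ 1.5 only ~78% of the time, the ≥ 3-of-4 rule ~80% per species,
and demanding it in *both* species caps cross-species recovery near 60%
before any p-gating (measured: ~40–46%).  Users wanting sensitivity should
read the meta sets; the integrated and cross-species sets trade recall for
precision, mirroring how such multi-stage filters behave on real data.

## Numerical conventions

* Missing token "NA"; all tables tab-separated UTF-8; floats written with
  10 significant digits so round trips are lossless at that precision.
* Gene symbols upper-cased at read/collapse time (mouse "Timp1" vs GMT
  "TIMP1").
* Zero within-group variance: p = 1 when means are equal, variance floored
  at 1e−12 with a warning otherwise.  p-values of exactly 0/1 are clamped
  before normal quantiles (1e−15) or logs (1e−300).
* Determinism: every stochastic component takes a seed; the pipeline
  derives per-stage seeds from one root via seed sequences, and rerunning
  the same config + seed reproduces all output files byte-identically.
* Test problem sizes (hundreds to a few thousand genes, B = 200–2000
  permutations) were chosen so the full suite exercises every stage,
  including two complete pipeline runs, in seconds while keeping
  Monte-Carlo tolerances meaningful.

## Known limitations

* No CEL-file parsing, affy-style background correction, NUSE, or visual
  QC; no GEO/ArrayExpress access — study matrices arrive as TSVs.
* No GO DAG topology (flat gene sets), no Bayesian posterior
  meta-analysis, no forest-plot rendering (the per-study g and var(g)
  columns are exported for external plotting).
* Samples at different reperfusion time points within a series are treated
  as one MCAO group; time-course structure is not modelled.
* The fixed-effect/random-effects poolers are conservative at k = 4 small
  studies (see calibration above); interpret their absolute p-values
  accordingly and lean on the vote across methods.
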