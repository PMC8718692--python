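# Methods

This note documents the models and procedures implemented in `m6ascore`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions that make results
reproducible.

## The regulator panel

The built-in registry holds the 24 m⁶A regulator genes commonly analysed in
tumor cohorts: 10 writers (CBLL1, ELAVL1, METTL3, METTL14, METTL16, KIAA1429,
RBM15, RBM15B, WTAP, ZC3H13), 2 erasers (ALKBH5, FTO) and 12 readers (YTHDC1,
YTHDC2, YTHDF1, YTHDF2, YTHDF3, FMR1, HNRNPA2B1, HNRNPC, IGF2BP1, IGF2BP2,
IGF2BP3, LRPPRC). The literature occasionally truncates WTAP to "WTA"; the
loader normalises this alias and logs it. User registries may be smaller;
they are flagged non-canonical and the 10/2/12 partition invariant is
relaxed. In multi-cohort analyses the panel actually used is the subset
present in the merged gene space — it is computed, never hard-coded, because
microarray platforms often lack several regulators.

## Preprocessing

FPKM→TPM is per-sample renormalisation, `tpm = fpkm / colsum × 10⁶`; it is
scale-invariant per sample and fails loudly on all-zero columns. The log₂
transform uses pseudocount 1 (configurable). Cross-cohort standardisation is
quantile normalisation of the merged matrix against the mean order-statistic
distribution, applied **after** merging so all samples share one reference —
tied values within a sample receive the mean of the reference values across
their rank span. No explicit batch-effect model is fitted; quantile
normalisation equalises marginal distributions only. A caveat discovered
during validation: quantile normalisation is exactly idempotent only on
tie-free data; with ties, the tie-averaging rule can adjust values again on
a second pass (the same behaviour as the standard array-normalisation
implementations).

## Consensus clustering

For each candidate k, `reps` subsamples of ⌈p_item·n⌉ samples (defaults
1000 and 0.8) are clustered by average-linkage hierarchical clustering on
1 − Pearson correlation distance between samples (k-means/Euclidean
optional). The consensus entry for a sample pair is the fraction of
co-clusterings among draws where both were sampled; pairs never co-sampled
(only possible at very small `reps`) are set to 0 with a warning. Final
labels at each k come from hierarchical clustering of the consensus
dissimilarity, not from any single repetition. Each (k, rep) draw uses a
counter-derived child seed (`SeedSequence(seed, spawn_key=(k, rep))`), so
results are bit-reproducible regardless of execution order.

Diagnostics per k: the area under the empirical CDF of off-diagonal
consensus entries (computed by the closed form ∫CDF = 1 − mean), its
relative increase over the previous k (delta area), and PAC, the fraction of
entries in (0.1, 0.9]. The default k-selection rule is the conventional
elbow: the largest k whose relative CDF-area increase exceeds 0.1; the PAC
argmin rule (ties to smaller k) is available, and any chosen k with
PAC > 0.5 is flagged low-confidence. On well-separated 3-cluster synthetic
data the delta-area profile is unambiguous (≈0.5 at k=3 vs ≈0.01 at k=4).

## Single-sample enrichment

The ssGSEA engine is the sum-of-differences variant. Genes are ordered by
descending expression within a sample, ties broken lexicographically by gene
id (deterministic). With rank values n…1 along that ordering, in-set genes
get weights rank^α (α = 0.25 by default) and

ES = Σ over positions of (weighted in-set ECDF − unweighted out-set ECDF).

Both ECDFs terminate at 1 (asserted per call). The score depends only on
ranks, hence is exactly invariant under strictly monotone per-sample
transforms. Collection scoring optionally rescales all scores by the global
(min, max) into [0, 1]. The engine is validated against an exhaustive
position-by-position evaluation written independently of it.

Two deliberate divergences from the popular R tooling: pathway activity is
computed with this rank-based engine rather than a Gaussian-kernel density
variant, and immune/stromal scores are plain ssGSEA scores of the two
signatures without any affine "purity" transform — both therefore support
relative (group-level) comparisons, which is how they are used, but not
absolute interpretation.

## Moderated t differential expression

Per gene, a two-group comparison on log-scale expression yields the mean
difference and pooled variance s²_g on d_g = n₁+n₂−2 df. Variances are
shrunk toward an inverse-chi-square prior, s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g),
with (d₀, s₀²) estimated by the method of moments on log s²_g via the
digamma/trigamma closed forms; trigamma is inverted by Newton iteration.
When the observed dispersion of log-variances does not exceed its sampling
noise, d₀ = ∞ and every posterior variance equals s₀² (normal reference
distribution). Zero-variance genes are excluded from the moment fit (log 0
undefined) and receive the prior-shrunk posterior d₀s₀²/(d₀+d_g). Setting
d₀ = 0 recovers the ordinary t-test exactly. The implementation is checked
against the reference empirical-Bayes implementation (hyperparameters and
moderated t to ≤1e-4 relative error) and calibrated on null simulations.

Subtype DEGs use raw p < 0.001 (BH-adjusted filtering available behind a
flag); the phenotype signature is the intersection of the three pairwise
contrast lists — the centre of the 3-set Venn diagram. No log-fold-change
threshold is applied.

## Survival analysis

Kaplan–Meier curves, the multi-group log-rank test and univariate Cox
regression delegate to lifelines; ties are handled by Efron's method and
Wald inference comes from the observed information. Perfect separation is
flagged non-converged and refit with a tiny ridge penalty for a usable
(capped) estimate. The brute-force Efron partial-likelihood oracle in the
test suite confirms the fits to ~1e-7 on tiny instances with ties. One
nuance: duplicating every subject (which creates systematic ties) shifts
the Efron estimate slightly — the approximation is close but not exact under
duplication; the tests assert oracle equality and approximate preservation.

The maximally-selected cutpoint scans all midpoints of sorted distinct score
values leaving both groups ≥ ⌈minprop·n⌉ (default minprop 0.1), computes the
standardized two-group log-rank statistic |O−E|/√V at each, and returns the
argmax (ties to the lower cut). The selection-bias-adjusted p-value is *not*
computed: downstream tests report the ordinary log-rank p of the resulting
groups, which should be read as descriptive given the optimised split; the
standardized statistic is stored for transparency. The prognostic gene
filter applies univariate Cox per signature gene at Wald p < 0.05
(configurable).

## The m⁶A score

Signature genes are z-scored across training samples (zero-variance genes
dropped with a warning); the SVD of the samples × genes matrix gives the
first two principal components, and each sample's score is the sum of its
projections onto PC1 and PC2. Signs are fixed so each component's loading
sum is ≥ 0 (tie → first nonzero loading positive), making scores
reproducible across linear-algebra backends. A sample at the training means
scores exactly 0. The model (means, SDs, loadings, explained variance) is
serialisable to versioned JSON, so scores for validation cohorts are
computed against the frozen training standardisation.

TMB is the raw nonsilent mutation count per sample (silent records excluded;
per-megabase normalisation optional, off by default). The TMB high/low split
reuses the maximally-selected cutpoint machinery unless a fixed threshold is
supplied. Score × TMB strata (H/H, H/L, L/H, L/L) are compared by a global
4-group log-rank plus BH-adjusted pairwise contrasts; empty strata are
dropped with a warning.

## Synthetic-data generator

The generator produces the structure the pipeline assumes, with ground truth
exposed:

- **Expression**: baseline 8 (log₂-like units), Gaussian noise SD 1. The 24
  regulators carry random three-level cluster offsets (±effect or 0;
  effect = 2 SD by default) over three clusters of 100 samples each. Of 80
  signature genes, 50 pan-cluster markers differ between all three clusters
  as two anti-correlated programs — 70% "protective" (high in the
  good-prognosis cluster B, low in the bad-prognosis cluster A) and 30%
  "risk" oriented — mirroring the coherent prognostic programs real DEG
  signatures carry; this also pins the orientation of the fitted PCA score
  (positive-loading-sum convention → high score ≈ B-like). Fifteen further
  genes shift in a single random cluster; the rest plus 200 background genes
  are null. 23 disjoint 20-gene immune signatures are included, of which 8
  (plus a stromal signature) are upshifted by 1 SD in cluster C.
- **Survival**: exponential per cluster at monthly rates 0.020 (A, worst),
  0.008 (B, best), 0.012 (C), censored by Uniform(0, 120) months of
  administrative follow-up (~40% censoring). Median survival ln2/rate is
  verified at n = 1000 per cluster.
- **Mutations**: a latent per-sample score (cluster base −1/+1/0 for A/B/C
  plus N(0, 0.5)) splits samples at the median; nonsilent counts are
  negative binomial with mean 8 (low half) vs 4 (high half), dispersion 2,
  plus Poisson(1) silent records, scattered over the regulators and 50
  background genes. Samples may legitimately have zero records.
- **CNV**: independent per-cell gains/losses at rate 0.1 each over the
  regulator panel, 10% of hits amplified to ±2.

What the generator does **not** emulate: real marginal expression
distributions, gene–gene correlation beyond the block structure, batch
effects, platform differences, non-proportional hazards, or mutation
hotspots. Passing tests therefore demonstrate correctness of the machinery
and its statistical calibration under the assumed model, not performance on
real cohorts.

## Problem sizes and numerical conventions

Validation suites use cohorts of 300 samples (150 for orchestration checks),
100 consensus repetitions across k = 2…6 for recovery runs (1000 remains the
production default), 20 generator seeds for cluster recovery, 20 × 1000-gene
null replicates for moderated-t calibration, 500 null log-rank replicates,
200 Cox recovery replicates at n = 500, and 10 end-to-end score-pipeline
seeds — sizes chosen so the whole battery runs in a few minutes on one core
while leaving the pass criteria statistically comfortable margins.

Other conventions: Newton convergence for the trigamma inverse at 1e-10
relative; cutpoint ties resolved to the lower cut; consensus ties in
hierarchical clustering resolved by scipy's deterministic ordering;
correlation distance of zero-variance samples treated as maximal; all
stochastic components consume `numpy.random.Generator` seeds derived from a
single user seed. Pipeline outputs are content-hashed (SHA-256 of the
rounded TSV) so reproducibility is checkable at the artifact level.

## Known limitations

- The Cox engine is univariate by design (signature filtering and HR
  reporting); multivariate adjustment, time-varying effects and competing
  risks are out of scope.
- The cutpoint's log-rank p is not adjusted for the maximal selection.
- ssGSEA normalisation (global range) makes scores comparable within one
  matrix, not across independently scored matrices.
- `run_all` assumes a three-cluster solution for the pairwise-DEG stage;
  other k values degrade to a two-group or skipped DEG step with a warning.
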