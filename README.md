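# m6ascore

Molecular subtyping and prognostic scoring of bulk expression cohorts on the
N6-methyladenosine (m⁶A) regulator panel.

m⁶A is the most abundant reversible mRNA base modification, deposited by
*writer* methyltransferases (METTL3/14/16, WTAP, KIAA1429, RBM15/15B, ZC3H13,
CBLL1, ELAVL1), removed by *eraser* demethylases (FTO, ALKBH5) and interpreted
by *reader* proteins (YTHDF1–3, YTHDC1/2, IGF2BP1–3, HNRNPC, HNRNPA2B1, FMR1,
LRPPRC). In lung adenocarcinoma and other tumors, the joint expression pattern
of these 24 regulators defines modification subtypes that differ in prognosis
and immune infiltration. This package implements the full analysis chain used
to characterise such subtypes, built for tumor-transcriptomics analysts who
want a tested, reproducible version of the workflow:

1. **Preprocessing** — FPKM→TPM conversion (`tpm_gs = fpkm_gs / Σ_g fpkm_gs ×
   10⁶`), log₂ transform, quantile normalisation, and multi-cohort merging on
   the common gene space.
2. **Consensus clustering** of samples on the regulator panel (Monti-style
   subsample resampling: `M_ij = #co-clustered / #co-sampled` over 1000
   draws of 80% of samples; average-linkage hierarchical clustering on
   1 − Pearson distance), with CDF-area, delta-area and PAC diagnostics for
   choosing k.
3. **Single-sample enrichment (ssGSEA)** for immune-cell infiltration and
   pathway activity: per sample, `ES = Σ_pos [P_in(pos) − P_out(pos)]` with
   rank-weighted in-set ECDF (weights rank^α, α = 0.25).
4. **Differential expression** between subtypes with the empirical-Bayes
   moderated t: gene variances shrunk as `s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)`
   with (d₀, s₀²) from the method of moments on log s²_g; the intersection of
   all pairwise DEG lists (raw p < 0.001) defines the phenotype signature.
5. **Survival engine** — Kaplan–Meier, multi-group log-rank, univariate Cox
   (Efron ties), and maximally-selected rank-statistic cutpoints
   (argmax over midpoints of the standardized two-group log-rank statistic).
6. **The m⁶A score** — prognostic signature genes are z-scored, PCA is run on
   the samples × genes matrix, and each sample scores
   `score_s = proj_PC1(s) + proj_PC2(s)`; samples are stratified at the
   survival-optimal cutpoint and crossed with tumor mutation burden
   (nonsilent mutation count) into four prognostic strata.
7. **A synthetic-cohort generator** that emulates the assumed statistical
   structure (3 latent clusters, cluster-linked hazards, TMB tied to a latent
   score, immune signature blocks) with exposed ground truth, so every stage
   is validated by parameter recovery rather than by eye.

## Worked example

```python
import m6ascore as m

bundle = m.generate(m.GeneratorConfig(seed=7))   # 804 genes x 300 samples
config = m.RunConfig(
    expression=bundle.expression, clinical=bundle.clinical,
    mutations=bundle.mutations, gene_sets=bundle.gene_sets,
    reps=100, outdir="demo_run", seed=7,
)
report = m.run_all(config)
for stage in report.stages:
    print(stage["stage"], {k: v for k, v in stage["outputs"].items()
                           if not k.endswith("sha256")})
```

prints

```
preprocess         {'n_genes': 804, 'n_samples': 300}
consensus_cluster  {'chosen_k': 3, 'n_regulators': 24}
enrichment         {'n_sets': 25}
diffexp            {'n_overlap_degs': 54}
prognostic_filter  {'n_prognostic': 53}
gene_cluster       {'gene_cluster_k': 3}
scoring            {'n_signature': 53, 'cutpoint': -4.466747557526133,
                    'n_high': 200, 'n_low': 100,
                    'logrank_p_high_vs_low': 0.00011195138237609112,
                    'strata_logrank_p': 4.254819585007396e-05}
survival           {'cluster_logrank_chi2': 18.113264278776157,
                    'cluster_logrank_p': 0.00011661505923972239}
```

Reading the output: consensus clustering on the 24-gene regulator panel finds
the three generated subtypes (`chosen_k: 3`); 54 genes are differentially
expressed in *every* pairwise subtype contrast at raw p < 0.001, of which 53
are prognostic by univariate Cox (p < 0.05) and form the score signature. The
maximally-selected cutpoint splits 300 patients into 200 high-score /
100 low-score; the two groups separate in survival (log-rank p ≈ 1.1e-4), as
do the three regulator subtypes themselves (p ≈ 1.2e-4) and the four
score × TMB strata (p ≈ 4.3e-5).

The same workflow runs from the shell:

```
m6a simulate --seed 7 --outdir sim/
m6a run --config run.yaml          # paths to expression/clinical/... + parameters
m6a cluster --matrix sim/expression.tsv --reps 1000 --seed 7 --out clusters/
```

Real cohorts enter through the same `RunConfig`, loaded with
`read_expression`, `read_clinical`, `read_mutations`, `read_cnv` and
`read_gmt` (TSV/CSV matrices, MAF-lite mutation tables, GMT gene sets).

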