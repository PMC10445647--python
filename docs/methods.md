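# Methods

This note documents the statistical models, defaults and design choices in
`finecoloc`, and what the synthetic-data experiments do and do not show.

## Fine-mapping model

Inputs are per-locus summary statistics (β, SE, per-variant sample size n,
minor-allele frequency) and the signed LD correlation matrix R aligned to
the variant order. Writing z = β/SE, the model for a causal configuration
γ (a set of variant indices) is the standard multivariate approximate
Bayes-factor formulation on z-scores:

- null: z ~ N(0, R′) with R′ = R + λI (ridge λ = `ld_ridge`, default 1e-3,
  which keeps R′ positive definite under perfect proxies and rank-deficient
  sample LD);
- alternative: z ~ N(0, R′ + R′ᵧ W R′ᵧᵀ), where R′ᵧ are the columns of R′
  at γ and W = diag(nᵢ·w₀²) is the prior variance of the standardized
  effects, w₀ = `prior_effect_sd` = 0.2.

Because R′ᵧ = R′E_γ, the matrix determinant lemma and the Woodbury identity
reduce the log Bayes factor to a closed form in the |γ|×|γ| submatrix
R′_γγ and z_γ:

    log BF(γ) = −½ log det(I + R′_γγ W) + ½ z_γᵀ (W⁻¹ + R′_γγ)⁻¹ z_γ .

At |γ| = 1 with no LD this is exactly the Wakefield single-variant
approximate Bayes factor; the test suite verifies both this identity and
agreement with direct full-covariance multivariate-normal densities.

Priors are independent Bernoulli inclusion with probability p = 1/m per
variant (overridable globally or per variant, e.g. to consume externally
computed functional priors). Configurations of size ≤ 2 are enumerated
exhaustively (valid for loci up to 1,000 variants); sizes 3..`max_signals`
(default 5) are explored by greedily expanding the `expand_parents` = 100
top-scoring smaller configurations per size, keeping at most `beam_size` =
10,000 configurations. For loci of ≤ 12 variants with `max_signals` = 2
this is provably identical to full enumeration, which the tests assert to
1e-10. Posteriors are normalized over the enumerated set including the
null configuration; PIP_v sums the posteriors of configurations containing
v.

### Signals and credible sets

Variants with PIP ≥ 0.01 are clustered greedily: the highest-PIP
unassigned variant seeds a cluster, and a variant joins when (i) its
squared correlation with the seed is ≥ `cluster_r2_min` = 0.25 and (ii) it
does not co-occur with the seed in any *informative* configuration with
posterior > 0.01. A configuration is informative about distinctness only
when its log BF exceeds the best singleton log BF among its members:
redundant perfect-proxy pairs retain near-singleton Bayes factors (they
add no fit, only a prior penalty) yet can keep posterior above 0.01 at
small m, and must not split one signal in two; genuinely independent
causal pairs fit far better jointly and do. At most `max_signals` clusters
are formed; if no variant reaches PIP 0.01 the locus yields no credible
set, which is a legitimate outcome, not an error.

Each cluster is reported as a credible set: members sorted by PIP
descending (ties by variant ID for order independence), cut at the
smallest prefix whose within-cluster normalized PIP sum reaches
`coverage` = 0.95. Reported per-variant PIPs stay on the raw emitted
scale; only the coverage computation normalizes.

Degenerate inputs: variants with missing or non-positive SE are dropped
with a logged warning rather than failing the locus — sparse meta-analysis
summary statistics are a fact of life. A helper flags ref/alt swaps
between paired studies and can flip β, z, LD signs and alleles.

## Colocalization

For a GWAS credible set and a QTL credible set sharing K variants:

- CLPP = 1 − ∏ᵢ (1 − PIP₁ᵢ·PIP₂ᵢ), computed in log space
  (`log1p`/`expm1`) for accuracy;
- the regional proxy is Σᵢ PIP₁ᵢ·PIP₂ᵢ. It equals CLPP at K = 1 and
  bounds it from above (union bound); maxᵢ PIP₁ᵢPIP₂ᵢ bounds it from
  below. The proxy deliberately omits the hierarchical enrichment
  re-weighting of full regional colocalization methods, which requires
  genome-wide enrichment estimation out of scope here; empirically the
  two statistics are nearly collinear on synthetic colocalizing pairs
  (Pearson r > 0.99 in the benchmark).

Quality filters precede tier assignment: the QTL-side FDR must be ≤ 0.05
(required for molecular QTLs, skipped for disease-disease comparisons),
and the shared variants must retain ≥ 50% of the PIP mass of *both*
signals. Statistics are always reported for filtered pairs — they are
flagged, not dropped. Tiers follow the union rule: *credible* when
CLPP ≥ 0.01 or proxy ≥ 0.1, *strong* at 0.1 / 0.5. The 50% predicate is
exposed as `same_signal` and reused to decide whether credible sets from
independent method runs describe one signal; `consensus_table` collates
calls across labeled method runs with that verdict and a low-confidence
flag for pairs failing the 50% criterion.

## Annotation conventions

- Coordinates are 1-based inclusive internally (GTF dialect); BED input is
  converted on read (a BED record [s, e) becomes 1-based span s+1..e, or
  the half-open interval [s+1, e+1) for open-chromatin membership).
- Nearest-gene distances follow the closest-features dialect: 0 inside the
  span, negative when the gene lies left (upstream in coordinate order) of
  the variant, positive to the right; ties break by smaller gene start,
  then lexical gene ID. `coding_only` restricts candidates to
  protein-coding models.
- Splice-junction windows default to 25 bp around each intron boundary.
  Donor is the intron start and acceptor the end on the + orientation,
  swapped on −; when strand is unknown + is assumed with a logged caveat
  (the side labels, not the hits, depend on it). Variants on the first or
  last two intronic bases are flagged canonical-dinucleotide.
- Splicing concordance consumes precomputed predicted splice-change scores
  (e.g. from a trained splicing model) as a table; the predictor itself is
  never reimplemented. Both predicted and observed effects are expressed
  for the alt allele before comparing signs; score 0 is *indeterminate*,
  a missing score *unscored*.
- Open-chromatin membership is half-open: a variant at the interval start
  is inside, at the end coordinate outside.

## Cell-type enrichment

Specificity of gene g in cell type c is mean_expr(g,c) / Σ_c′
mean_expr(g,c′), after dropping genes whose summed mean expression falls
below `floor` = 0.1 (lowly expressed genes would otherwise look spuriously
specific; the exact floor is this package's choice and configurable).

The bootstrap test compares the observed mean specificity of the target
genes in each cell type against `reps` = 10,000 equally sized gene sets
sampled without replacement from the retained gene list (default seed 1).
The empirical one-sided p uses the +1 correction, so p ∈ (0, 1]; BH
correction runs across cell types within one target set, and significance
is q ≤ 0.05. The test is one-sided for enrichment; depletion shows as
negative z but is not tested. The bootstrap statistic is computed on the
specificity metric (consistent with the metric's definition) rather than
raw expression.

Conditional enrichment matches the null sets to the target's specificity
profile in a controlled cell type: retained genes are split into `bins`
(default 10) rank-based quantile bins of controlled-type specificity, and
each null set draws per bin as many genes as the target holds there.
Matching granularity matters: with extreme planted markers the default 10
bins only partially absorb the controlled type's signal (the top decile
mixes markers with mid-specificity genes), while finer bins that isolate
the marker group absorb it fully; `bins` is therefore exposed, and the
conditional z in the controlled type is guaranteed in tests to never
exceed the unconditional z. The infeasible-bin error (a bin with fewer
candidates than required) is defensive — targets drawn from the atlas
always occupy their own bins.

A presentation helper draws an average-linkage, correlation-distance
clustered expression heatmap; it is excluded from all quantitative checks.

## Synthetic data: what it emulates, and what it does not

The haplotype panel uses blockwise copy-with-mutation chains: within a
block, each variant's column copies the previous one, resampling each
haplotype to Bernoulli(block MAF) with probability 1 − `within_block_decay`.
This produces geometrically decaying LD inside blocks, exact independence
across blocks, and a stationary allele frequency equal to the block's
target MAF (drawn once per block from `maf_range`). One MAF per block is a
deliberate simplification that makes the frequency invariant exact; it is
not a model of real site-frequency spectra. Phenotypes are additive with
Gaussian noise and no covariates; effect sizes are parameterized by the
fraction of variance explained, making power explicit and sample-size
free. Diploid genotypes pair haplotypes uniformly (Hardy–Weinberg, no
inbreeding). The atlas draws per-entry multiplicative lognormal noise
(σ = 0.2) around flat expectations with planted marker folds.

Consequences: passing calibration/discrimination benchmarks on these data
shows the estimators are correct under a well-specified additive model
with block LD. It does not certify behavior under coalescent LD
structure, case-control ascertainment, mismatched LD reference panels,
cross-cohort missingness, or rank-transformed phenotypes — the trait
transformation is deliberately not modeled.

## Benchmark conditions

The repository's reproduction script and acceptance tests use: 500 loci of
50 variants (n = 5,000; one or two causals at 0.5–2% variance explained
each) for PIP calibration and 95%-CS coverage; 100 paired-study replicates
per arm (n = 10,000, 1% variance explained) for colocalization
discrimination; 200 random 60-gene targets at 1,000 bootstrap reps on a
400-gene null atlas for enrichment calibration; 1,000 variants × 200 genes
for nearest-gene exactness; and the 2-locus demo config for end-to-end
determinism. These sizes were chosen as the smallest that make the
binomial error bars meaningfully tighter than the thresholds they check.

## Known limitations

- The greedy beam beyond configuration size 2 is exact only at small loci;
  at large loci with > 2 strong interacting signals it is an approximation
  (as is any non-exhaustive search).
- The signal-clustering rule is this package's definition; different
  fine-mappers delimit signals differently, and consensus across tools
  should use `same_signal` rather than assuming identical cluster
  boundaries.
- The regional colocalization proxy is enrichment-free by design and
  should not be read as a calibrated posterior probability.
- Conditional enrichment inherits the granularity caveat above; report
  `bins` alongside results.
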