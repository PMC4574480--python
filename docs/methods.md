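# Methods

## Statistical model

### Allelic association

Association between a SNP and case status is tested on allele counts: each
of n genotyped individuals contributes two alleles, giving the 2×2 table

|          | minor | major |
|----------|-------|-------|
| cases    | a     | b     |
| controls | c     | d     |

The statistic is the uncorrected Pearson chi-square with 1 df in its
determinant form, χ² = N(ad − bc)²/(r₁r₂c₁c₂) with N = a+b+c+d and
r, c the margins; the p-value is the upper tail of χ²₁ and the effect is
the allele-count odds ratio (a/b)/(c/d). No Yates continuity correction is
applied: the uncorrected statistic reproduces every published p-value in
the association table at printed precision, while the corrected one
drifts. No multiple-testing correction is applied by default (the study
reports raw p-values); ranking, not thresholding, drives downstream
stages. Treating 2n alleles as independent assumes Hardy–Weinberg
equilibrium within each group — which the simulator enforces and real
panels should be screened for.

A zero margin makes the test undefined (error); a zero cell with positive
margins yields OR 0 or +∞ while χ² stays defined. MAF is always computed
over non-missing alleles only.

### Inverting printed summaries

Published tables report per-cohort MAF to four decimals and cohort size n.
Allele counts are recovered as minor = round(2·n·MAF) (half away from
zero) and major = 2n − minor. For the cohort sizes involved (14–1907) this
inversion is exact — no reconstructed cell lands on .5 — so the published
ORs (2 decimals) and p-values (3 significant figures) are reproduced
digit-for-digit by `reproduce_table1`. One published cell (the smaller
cohort's second SNP, p printed 1.10×10⁻³) does not follow from its own
printed MAFs (the reconstruction gives 1.07×10⁻³ and the printed value
equals the neighboring column's computation); `reproduce_table1` reports
that cell with its recomputed value and a failed-match flag rather than
forcing agreement.

### Genomic control

λ = median(χ²)/0.4549364231, the 1-df chi-square median. λ ≈ 1 indicates
no stratification confounding. The estimator is a sample median, so with
m SNPs its Monte-Carlo standard error is ≈ 1.9/√m in λ units (about 0.013
at m = 20,000); calibration checks use a [0.95, 1.05] band.

### Stratification PCA

Missing dosages are mean-imputed per SNP, columns centered by 2p̂ and
scaled by √(p̂(1−p̂)) (Eigenstrat standardization, p̂ = panel frequency of
the counted allele), monomorphic SNPs dropped, then SVD. Scores are U·S;
explained-variance proportions come from squared singular values over the
total squared norm. Sign indeterminacy is fixed by making each component's
largest-magnitude SNP loading positive. Sample gating is a closed
rectangle on a chosen component pair — a deliberate mirror of selecting
the co-clustered box on a PC1/PC2 plot by eye; no automatic clustering
criterion is invented.

### Proximity re-ranking

Among the top-K SNPs by p (K = 1000), `neighbor_count` is the number of
other top-K SNPs on the same chromosome within ±10 kb (inclusive). SNPs
are ordered by (neighbor_count desc, p asc, position) and assigned
1-based proximity ranks. This is the minimal deterministic rule that makes
an LD pair of strong signals outrank isolated, possibly artifactual hits.
Windows are interpreted as ±window around each SNP, not fixed genomic
tiles.

### Gene mapping

A SNP (1-based position) maps to every gene whose 0-based half-open
interval, extended by ±20 kb, contains it; the boundary is inclusive and
distances are measured to the inclusive last base of the interval (0
inside the gene body). A SNP may map to several genes; unmapped SNPs are
reported, and the unique gene list preserves first-hit order.

### Network assembly and enrichment

Edges carry a source label: `ppi_a` (unscored protein interaction),
`ppi_scored` (confidence-scored interaction, kept iff score ≥ 0.9,
inclusive — the cutoff's inclusivity is a declared choice), `tf` (directed
regulator→target), `pathway` (co-membership). Self-loops are dropped and
duplicate pairs merge with provenance union and maximum score. The
first-neighbor subnetwork is the induced subgraph on the seed genes plus
everything adjacent to them, with `tf` edges counting for adjacency in
either direction; seeds present in the network are kept even when
isolated, absent seeds are ignored with a warning.

Over-representation uses the exact one-sided hypergeometric tail
P(overlap ≥ k) with universe N, set size K, query size n — no normal or
chi-square approximation. Regulator enrichment replays this per regulator
against its target set, with Benjamini–Hochberg q-values. This open ORA
replaces the proprietary enrichment engine used in the original chain;
its published enrichment p-values depend on a closed knowledge base and
are not comparable numbers.

### Molecular statistics

The eQTL statistic is the Pearson correlation of allele dosage (0/1/2)
with expression, two-sided p from t = r√((n−2)/(1−r²)) on n−2 df, missing
dosages dropped pairwise, n ≥ 3 and non-constant inputs required.

qPCR fold changes follow the Livak 2^(−ΔΔCt) method: ΔCt = Ct(target) −
Ct(reference) per replicate, ΔΔCt = mean ΔCt(treated) − mean ΔCt(control),
fold = 2^(−ΔΔCt). Per-replicate folds (each treated replicate against the
control mean ΔCt) provide the SEM across independent experiments. Folds
are invariant to any constant shift of all Ct values, and a gene
normalized against itself gives exactly 1. Amplification-efficiency
correction and multi-reference normalization are out of scope.

### Phenotype statistics

Cluster-class percentages are per cell: a cluster of 5 contributes 5 cells
to the "≥4" class, pooled across larvae of a group (sums to 100 within
1e-9). Because pooling vs per-larva averaging is a genuine ambiguity in
how such figures are computed, a `per_larva=True` variant that weights
larvae equally is provided behind a flag. Length summaries are mean ± SEM
(sd/√n, n−1 denominator). Group comparisons use the equal-variance
unpaired two-tailed t-test (pooled variance, df = n₁+n₂−2) with a
significance flag at α = 0.05; both pooled-measurement and per-larva-mean
usage are possible since the unit-of-analysis question is left to the
caller. Categorical scoring schemes (severity: normal/intermediate/severe;
biliary dye accumulation: absent/small_faint/normal) are tabulated as
per-group percentages with n.

## Synthetic data: what it emulates and what it does not

The genotype generator draws a case-control panel with three ingredients:

1. **Null SNPs** under a Balding–Nichols structure model: ancestral
   frequency uniform on [0.05, 0.5]; subpopulation frequencies
   Beta(p(1−F)/F, (1−p)(1−F)/F) with differentiation parameter F (Fst);
   genotypes Binomial(2, p) within subpopulation. F = 0 gives a
   homogeneous panel. Null positions are spread uniformly over a
   22-chromosome × 130-Mb genome equivalent, so that the density of top-K
   SNPs per 10-kb window matches a genome-wide array ranking — the
   quantity that governs how often chance proximity clusters arise.
2. **A planted risk pair** at positions 49,442,285 and +2,971 bp on
   chromosome 14. Frequencies are planted exactly: each cohort receives
   round(2n·MAF) minor haplotypes (defaults 0.2857 cases / 0.1308
   controls), randomly paired into genotypes (random mating ⇒ HWE). The
   configured values are the observed cohort frequencies, so the generator
   reproduces them rather than resampling them. The two SNPs share one
   haplotype pattern — perfect LD (r² = 1), since no r² was reported; this
   is a simulator convention, as is the multiplicative (allelic) effect
   model.
3. **Missingness** completely at random at a configurable rate — only the
   call-rate filter consumes it, so no informative-missingness model is
   needed.

The annotation generator places one gene whose boundary lies exactly
8,763 bp upstream of the planted pair (the candidate-gene geometry) among
uniformly placed decoys. The network generator wires a planted module
fully to a designated seed subset through unscored edges (so it survives
any score cutoff) on top of Bernoulli background edges with random source
labels and scores. Phenotype/qPCR/expression generators draw from the
stated multinomial, normal, and linear-effect models.

Not emulated: linkage disequilibrium beyond the planted pair,
recombination maps, imputation, coalescent genealogies, genotyping-error
structure, batch effects, and realistic gene length/spacing
distributions. Passing tests therefore demonstrate the pipeline's
correctness and its behavior under idealized sampling noise — not
robustness to LD confounding or array artifacts in real panels.

## Problem sizes used in validation

Simulation-based checks run at sizes chosen to make their estimators
stable while keeping runs quick: the null-calibration panel uses 500 cases
/ 500 controls × 20,000 SNPs (at the generator's minimum MAF of 0.05 this
keeps expected minor-allele counts ≥ 50 per group, where the 1-df
approximation is accurate; smaller panels bias λ upward through count
discreteness); proximity-recovery uses the study's cohort sizes (63 cases
/ 1907 controls) with 5,000 null SNPs over 50 seeds; structure recovery
uses 200 samples × 500 SNPs at Fst 0.1. The planted frequencies, LD
distance, QC thresholds, ranking windows, and score cutoff are the study's
fixed constants throughout.

## Numerical and design choices

- Minor-allele orientation is defined on the full panel (cases +
  controls), ties at 0.5 broken toward the lexicographically smaller
  allele; internal coordinates are 0-based half-open for genes, 1-based
  for SNP positions, converted only at I/O boundaries.
- `rank_by_p` and `proximity_rank` break all ties positionally
  (chrom, pos, snp_id), making every ranking deterministic.
- PCA rank is estimated as singular values above s₁·1e-12; requesting more
  components is an error rather than returning noise.
- The t-test worked example in the test suite asserts p = 0.0710, the
  value the pooled-variance formula (and R's `t.test`) actually gives for
  those inputs.
- One global seed drives every stochastic stage of a pipeline run;
  identical config + seed gives byte-identical outputs.

## Known limitations

- The allelic test offers no covariate adjustment (no logistic
  regression) and no genotypic/trend alternatives; stratification control
  is by PCA gating only.
- The first-neighbor rule keeps isolated present seeds; whether such
  genes belong in a "neighbor" network is a modeling judgement, flagged in
  the API documentation.
- Published eQTL correlations and enrichment p-values from external data
  sources or closed engines are treated as anchors for the statistic
  definitions, not as numbers this package can recompute.
- Binary PLINK, VCF, and chip-intensity formats are out of scope; the
  text .ped/.map dialect with missing code "0" is the only genotype
  exchange format.
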