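# Methods

`hsqtl` re-implements, as a tested desk-scale pipeline, the complete
phenotype-to-QTL analysis used for outbred heterogeneous-stock (HS) rat
cohorts phenotyped for opioid-addiction-related behavior at two testing
sites: phenotype preparation, SNP heritability, leave-one-chromosome-out
(LOCO) mixed-model GWAS with a permutation significance threshold,
rule-based QTL calling with conditional mapping and LD intervals,
expression-annotation colocation, and network-based clustering of animals
into vulnerable / intermediate / resilient susceptibility phenotypes.
This note records the models, the parameters that matter, and the design
choices made where the procedure left room.

## Synthetic cohorts (`simdata`)

HS rats descend from eight inbred founder strains; each genome is a fine
founder mosaic. The generator models this in three layers.

**Founder haplotypes.** Each SNP's pool allele frequency is drawn from
`founder_maf_dist` (default Uniform(0.1, 0.5)); each founder's allele at SNP
*i* is the indicator Φ(z<sub>f,i</sub>) < p<sub>i</sub>, where z<sub>f</sub>
is a stationary AR(1) Gaussian along the chromosome with correlation
exp(−d / `founder_ld_scale_bp`) at distance *d* (default 1 Mb). The latent
process keeps the marginal frequency distribution exact while making nearby
founder columns correlated. This matters downstream: if founder alleles were
drawn independently per SNP, two SNPs in perfect cosegregation would still
show near-zero dosage correlation in the cohort, no SNP would have the
high-LD neighbors the support-SNP rule requires, and every true QTL would be
rejected as unsupported. The AR(1) scale is a modeling choice, not a
calibration to the colony's real LD decay, which is not published.

**Mosaic diploids.** Each haplotype switches to a uniformly drawn founder at
breakpoints from a Poisson process with `recomb_rate` switch points per Mb
(uniform map, no interference). The rate represents recombination
accumulated over many HS generations, not one meiosis, so the default
0.5/Mb (≈2 Mb blocks) is far above the ~0.6 cM/Mb rat meiotic map on
purpose. Dosage is the sum of the two haplotype alleles; the generator never
produces missing calls (QC paths are tested with explicitly masked data).

**Phenotypes.** For each trait,
y = site + sex + Σ<sub>k</sub> β<sub>k</sub> x<sub>k</sub> + u + e, with each
planted QTL's standardized dosage scaled so it contributes its configured
variance fraction (default 0.03 — the effect size the study design was
powered for), a polygenic term u = Zw over all non-causal standardized SNPs
with w ~ N(0, h²<sub>poly</sub>/m), and Gaussian noise filling the variance
budget. Planted positions snap to the nearest *polymorphic* SNP and the
realized SNP is recorded in the ground truth, so mapping tests have an exact
causal marker. Because u is built from the same standardized genotypes that
form the GRM, GREML on these cohorts is a true parameter-recovery test.
Site 2 gets an additive shift and an SD scale (default +0.3, ×1.2),
emulating the between-site variance difference of a two-site design; males
get an additive shift.

The progressive-ratio schedule is requirement(n) = round(5·e^(0.2n) − 5),
floored at one press, giving the canonical ladder 1, 2, 4, 6, 9, 12, 15,
20, 25, …

**Clustered cohorts.** `simulate_clustered_cohort` plants three groups
(resilient / intermediate / vulnerable). Group k receives a *profile*
(elevated by `separation` SD on its own third of the trait list) plus a
uniform severity shift 0.5·`separation`·k. The split matters: a Pearson
correlation between two animals' trait vectors centers each vector, so a
uniform shift on all traits is invisible to the similarity network; the
profile carries the clusterable signal while the uniform shift orders the
groups on the composite severity score used for labeling. The default trait
list has 12 measures because animal-animal correlations over only a handful
of traits are too noisy to cluster reliably.

What the generator does **not** emulate: real founder genomes or genetic
maps, sex chromosomes, dominance/epistasis, genotyping error and
missingness processes, litter/batch structure beyond site and sex, and the
colony's empirical LD decay. Tests passing on these cohorts show the
machinery is correct and calibrated under its own model, not that any
specific real locus would replicate.

## Genotype QC (`genoqc`)

Dosages are alternate-allele counts in {0, 1, 2} with NaN for missing.
Three conjunctive per-SNP filters, all thresholds inclusive: missingness
≤ 10%, MAF ≥ 0.5%, Hardy-Weinberg deviation p ≥ 1e-10. The HWE test is the
1-df Pearson chi-square against expected proportions from the sample allele
frequency; at a 1e-10 threshold and usable sample sizes the asymptotic vs
exact-test distinction is immaterial, and the function is swappable.
Missing dosages are excluded from MAF/HWE computation and mean-imputed only
where the GRM and association need complete columns. Positions are 1-based
(bim/VCF convention); intervals are closed. PLINK bed/bim/fam (variant-major
v1.00) and VCF 4.2 round-trip exactly; bim allele 1 is stored as the alt
allele.

## Phenotype preparation (`phenoprep`)

Per site: candidate covariates (including sex) whose *marginal* R² on the
raw trait exceeds 2% are regressed out jointly; residuals get a rank
inverse-normal transform (INT); the two sites are pooled and the pooled
vector is INT-transformed once more. Marginal screening matches the
"explains more than 2% of trait variance" criterion; joint screening is the
obvious alternative and is deliberately not used. The INT uses the Blom
offset, Φ⁻¹((r − 3/8)/(n + 1/4)), with average ranks for ties (an optional
seeded tie-break exists but is off by default). Within-site INT equalizes
the site variances — the property that justifies pooling the sites with
equal weight and, downstream, using a single permutation threshold for all
traits. Difference-score traits (time point 2 − time point 1) are computed
on raw values before preparation. Binary cluster phenotypes bypass the INT
and enter association as 0/1 with site/sex as covariates; whether the
original analysis re-transformed them is unstated, and the observed-scale
choice is recorded here as ours.

Trait correlation uses pairwise-complete Spearman rho with Bonferroni
adjustment over the distinct pairs. PCA operates on the trait correlation
matrix, retains components with eigenvalue ≥ 1, varimax-rotates retained
loadings (eigenvector × √eigenvalue), and masks |loading| ≥ 0.3. Varimax is
implemented with pairwise Jacobi planar rotations and Kaiser row
normalization (the SPSS convention); the planar form solves each two-factor
subproblem exactly and does not stall on the balanced saddle points where
gradient/SVD implementations can sit. Retention counts on null
(uncorrelated) data are unstable by design — eigenvalues hover around 1 —
and should not be interpreted.

## Relatedness and heritability (`varcomp`)

GRM: A<sub>jk</sub> = (1/m) Σ<sub>i</sub> (x<sub>ij</sub> − 2p<sub>i</sub>)
(x<sub>ik</sub> − 2p<sub>i</sub>) / (2p<sub>i</sub>(1−p<sub>i</sub>)), the
GCTA scaling; monomorphic SNPs skipped, missing dosages mean-imputed.
LOCO GRMs exclude one chromosome each; their SNP-count-weighted average
reconstructs the full GRM exactly (a tested identity).

GREML fits y = Xβ + g + e, g ~ (0, σ²g·A), e ~ (0, σ²e·I), by REML in the
eigenbasis of A: one O(n³) eigendecomposition makes every iteration O(n),
which is what lets permutation thresholds re-fit variance components
hundreds of times. Updates are Average-Information steps with an EM-flavored
first step, step-halving whenever a step would decrease the restricted
likelihood, and components clamped at zero (active set). Convergence:
|Δ log-lik| < 1e-6, max 100 iterations; non-convergence flags the result
rather than raising. h² = σ²g/(σ²g+σ²e) on the observed scale for all traits
(no liability transform, matching single-h²-per-trait reporting); its SE
comes from the delta method on the inverse AI matrix. The h² = 0 null is a
boundary test: p = ½·P(χ²₁ ≥ Λ) with p = 1 at Λ = 0. GREML uses an
intercept-only fixed design by default (covariates configurable); the
phenotype arrives pre-residualized from `phenoprep`.

## Association scan and QTL calling (`scan`)

For the SNPs of chromosome c, variance components are REML-estimated once
under the LOCO GRM for c and then held fixed across that chromosome's SNPs
(the GCTA-MLMA convention; per-SNP REML would be orders of magnitude slower
and changes nothing detectable at these scales). Each SNP's effect is a
generalized least-squares fix-effect test under
V = σ̂²g·A<sub>loco(c)</sub> + σ̂²e·I with a two-sided Wald p, computed in
the whitened eigenbasis with the covariates projected out, vectorized across
SNPs. Conditioning SNPs enter the fixed design as dosage covariates; a SNP
collinear with them (or monomorphic) is marked untestable rather than
assigned a p. With σ²g pinned to 0 the whole scan reduces to ordinary
least-squares regression with known variance — tested against a dense
brute-force GLS oracle at 1e-8.

**Permutation threshold.** The prepared phenotype is shuffled across
individuals, the full LOCO scan re-run, and the genome-wide maximum
−log₁₀ p recorded; the threshold is the empirical (1−α) quantile of the
maxima (numpy linear interpolation). Shuffling ignores relatedness — the
argument that one threshold suffices because every trait is
inverse-normal — so the threshold is exact only under exchangeability;
with strong cryptic structure it can drift, a known limitation. A cached
workspace (per-chromosome eigendecompositions + rotated genotype blocks)
makes each permutation cost one O(n²) rotation per chromosome plus an O(n)
REML, so 100 permutations take seconds at desk scale. A second, suggestive
tier (default α = 0.10) is supported.

**QTL rules.** Among SNPs above the threshold, the most significant SNP per
chromosome is a candidate peak, reported only with at least one other SNP
within 0.5 Mb (inclusive) whose −log₁₀ p is within 2 units of the peak
(inclusive); ties break toward the lower position, then the lexicographic
id. Independence of same-chromosome signals: the accepted peak's dosage
becomes a covariate and the chromosome (only) is re-scanned, repeating until
nothing passes; more than 10 rounds aborts with a collinearity diagnostic.
Interval boundaries are the outermost SNPs with r² ≥ 0.6 to the peak within
a ±10 Mb search window; contiguity of qualifying SNPs is *not* required
(loci several Mb apart can fail to be in strong LD while an isolated distal
SNP in strong LD still extends the interval) — both the non-contiguity and
the 10 Mb bound are configurable. Colocation reports every annotation SNP
(eQTL / sQTL / coding, from a local table) within ±3 Mb of a peak with its
r² and a strong-LD flag at r² ≥ 0.6. PheWAS is an exact-SNP extract across
the other traits' scans.

## Behavioral clustering (`netclust`)

Traits are z-scored within sex × site cells. Animal-animal similarity is
the Pearson correlation of standardized trait vectors over shared
non-missing traits; the binary network keeps pairs at or above the 0.8
similarity quantile (≈20% edge density). The published analysis defers the
network construction and block-model details to its cited methods; the
choices fixed here — Pearson similarity, top-quantile edge rule,
single-layer binary stochastic block model with Dirichlet(1)/Beta(1,1)
priors, Gibbs sampling, posterior-mode assignments — are documented,
configurable, and each a possible departure from the original.

The Gibbs sampler alternates conjugate draws of the block-pair edge
probabilities and mixing proportions with sequential node reassignment
(incrementally maintained neighbor counts). Chains initialize from spectral
clustering of the adjacency and run 300 sweeps with 100 burn-in by default;
post-burn-in samples are label-aligned by Hungarian matching to the first
retained sweep, the point estimate is the per-node posterior mode, and the
per-node confidence is the mode's posterior frequency. K is fixed at 3 by
the phenotype design (no model selection over K). Blocks are ranked by the
mean cohort-wide z-score of the severity traits: highest → vulnerable,
lowest → resilient; exact ties break by block size with a warning.
One-vs-rest 0/1 contrasts feed the GWAS. The allele-by-cluster test is the
plain Pearson chi-square without continuity correction on a 2×2 table of
major-allele homozygotes vs minor-allele carriers (the two displayed variant
groups; df = 1), switchable to the full three-genotype table (df = 2).

## Pipeline and reproducibility (`pipeline`)

`run_all` executes simulate/ingest → QC → preparation → heritability →
scan → threshold → QTL → colocation → clustering → contrasts from one
config. The global seed fans out per stage as CRC32(stage name) XOR seed
(mod 2³¹), so stages are independently reproducible; every artifact is a
TSV/JSON with a SHA-256 hash in the manifest, and re-running a config is
bit-identical. `n_perm = 0` skips thresholding with an explicit manifest
note. Filter counts and stage parameters are logged.

## Problem sizes used in tests

The test and acceptance workloads are sized for a single CPU: GREML
recovery uses 20 + 20 cohorts of n = 800 × m = 2000; family-wise error uses
200 trials of the full scan-plus-own-threshold procedure at n = 200 ×
m = 2000 (this averages over threshold quantile noise, which is the error
the procedure actually commits in practice); detection power uses 20
replicates at n = 850 with a 3%-variance QTL; block-model recovery uses
n = 300 planted partitions (p_in = 0.3, p_out = 0.05) across 10 seeds.

## Known limitations

- The permutation null ignores relatedness (see above).
- The REML likelihood surface is unimodal in practice here, but the solver
  only guards monotone ascent; it does not multi-start.
- Observed-scale h² for binary cluster phenotypes understates
  liability-scale heritability at unbalanced prevalence.
- The HWE filter's chi-square is asymptotic; at very low MAF an exact test
  would differ (irrelevant at the 1e-10 threshold).
- Similarity-network and SBM choices are plausible reconstructions of a
  procedure whose details live in external references; fidelity to those is
  unverifiable from the text alone.
- Annotation colocation requires the annotation SNPs to be present in the
  genotype matrix for r²; absent SNPs are reported with undefined r² rather
  than imputed.
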