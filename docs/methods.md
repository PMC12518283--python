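# Methods

This note documents the statistical models, the synthetic study design,
the numerical conventions, and the limits of what the test suite
demonstrates.

## Genotype representation and QC

The internal exchange object is an accessions × markers matrix of
alternative-allele dosage (0/1/2, NaN missing). DArT-style reports code a
call as 0 = reference homozygote, 1 = alternative homozygote,
2 = heterozygote; these map to dosages 0, 2, 1 on read. Heterozygous
dosage is always 1 internally — the source coding is presentation only.

Per-marker metrics are recomputed from the calls: alt frequency p̂ over
non-missing calls, MAF = min(p̂, 1−p̂), gene diversity 2p̂q̂ (the quantity
whose biallelic maximum is 0.5), and Botstein's PIC
1 − p̂² − q̂² − 2p̂²q̂² (maximum 0.375). Both informativeness columns are
reported because the two definitions are often conflated in applied work.
Filtering removes markers with MAF < 0.01, call rate < 0.75 or
reproducibility < 0.80; values exactly at a threshold are retained (the
rule is read as a strict "<"). Filtering is idempotent.

Missing calls are imputed by iterative truncated-SVD completion: missing
cells start at column means, and the matrix is repeatedly replaced at the
missing cells by its rank-r reconstruction until the largest change falls
below `tol` (default 1e−4) or `max_iter` (100). Observed cells are never
altered; output is clipped to [0, 2]. The default rank is 4, matching the
number of ancestral groups the structure analysis operates with; dosage
rounding is off by default because fractional dosages feed ordination
better, and analyses that need hard calls (heterozygote counts, AMOVA,
core selection) round first. No convergence rule for the original
platform implementation is published; these defaults are this package's
own.

## Diversity statistics

Within a population, per locus, unbiased gene diversity is
(2n/(2n−1))(1 − p̂² − q̂²) with n the diploid call count; Hs averages this
over loci (loci with fewer than two calls are excluded from that
population's average), and Ht applies the same formula to pooled
frequencies. F_IS defaults to the ratio-of-means form 1 − mean(Ho)/mean(Hs);
a per-locus averaging mode exists because published tables are sometimes
computed one way and printed the other. Rarefied allelic richness is the
expected number of distinct alleles in a hypergeometric draw of g gene
copies, E = 2 − C(N−n_alt, g)/C(N, g) − C(N−n_ref, g)/C(N, g), with g
defaulting to the smallest per-locus call count across populations. Note
that rarefaction is only asymptotically invariant to duplicating every
accession — drawing g copies from 2N is not the same experiment as
drawing from N — so the corresponding test asserts near-invariance.
Adjusted ("autosomal") heterozygosity multiplies Hs by
n_polymorphic/(n_polymorphic + n_invariant); the invariant-site count
cannot be derived from a SNP panel and is a required input.

F_ST is Weir–Cockerham θ with the multilocus ratio-of-sums of the a, b, c
variance components; pairwise values are computed on the two populations'
calls only, and negative multilocus estimates are reported as computed.

## AMOVA

The three-level design is zones ⊃ accessions ⊃ gene copies; each diploid
accession contributes two copies whose per-locus allele value is 0/1, so
the within-accession squared deviation is 0.5 per heterozygous call.
Sums of squares partition exactly (SS_total = SS_groups + SS_acc + SS_within,
df = G−1, n−G, n). Variance components come from the moment equations
with the unequal-size coefficient n₀ = (N − Σ N_g²/N)/(G−1) on the
among-group component (N_g = gene copies in group g) and coefficient 2 on
the among-accession component. Significance: the among-group component is
tested by permuting accessions among groups, the among-accession
component by re-pairing the two gene copies among accessions within each
group per locus; both use the add-one permutation p-value. Components can
legitimately come out negative (and percent variance slightly outside
[0, 100]) when a stratum's true variance is near zero; they are not
truncated.

## Admixture model and ΔK

Ancestry is modelled as g_ij ~ Binomial(2, π_ij), π = QF, with Q rows on
the simplex and F ∈ [1e−4, 1−1e−4]. The fit minimizes the binomial
deviance by EM (the FRAPPE-style responsibility updates), which guarantees
a non-increasing deviance — the property the ΔK criterion and the tests
rely on. Initialization is k-means on eigenvalue-scaled PCA scores with a
seed-derived random state, so replicates explore different local optima
deterministically; convergence is a relative deviance change below 1e−5
(cap 200 iterations; the best iterate is returned with a warning
otherwise). This is an explicit substitute design for MCMC-based Bayesian
clustering: it preserves the downstream contracts (Q matrices, the K grid
with replicates, membership thresholding at 0.6, ΔK) while being
deterministic per seed and desk-scale. Absolute criterion values are a
deviance, not a marginal likelihood; only differences across K matter.

ΔK(K) = |L(K+1) − 2L(K) + L(K−1)| / SD(L at K), with L the sign-flipped
mean deviance over replicates; the optimal K maximizes ΔK over interior
K. Zero replicate SD makes ΔK infinite there (flagged); an all-flat
second difference falls back to the smallest interior K with a warning.

## Tajima–Nei NJ tree

Each genotype is expanded to two base copies (a heterozygote carries one
ref and one alt base); the pair mismatch proportion p̂ averages the four
copy-pairings over loci called in both accessions (pairwise deletion).
The distance is d = −b ln(1 − p̂/b) with b = 1 − Σ q_i² + p̂²/h, base
frequencies q pooled over the pair's copies, and
h = Σ_{i<j} x_ij²/(2 q_i q_j) where x_ij is the relative frequency of the
{i, j} class among differing site-pairs. Identical heterozygotes mismatch
in two of four pairings, so only fully homozygous clones are at distance
exactly zero — an intrinsic property of the copy-pairing convention.
Saturated pairs (p̂ ≥ b) are reported missing with a warning, and NJ
refuses incomplete matrices, listing the offending pairs. Applying a
whole-sequence substitution model to a SNP panel overstates divergence in
absolute terms; the tree is used for relative grouping only and is left
unrooted. The NJ agglomeration is scikit-bio's; negative branch lengths
are floored at zero with the deficit moved to the sister branch.
Bootstrap support resamples loci with replacement and counts the fraction
of replicate trees containing each internal bipartition of the reference
tree.

## Core collection

Phase 1 is greedy maximum coverage over (locus, allele) pairs, ties
broken by higher total rarity then input order; Ny and Nz are the first
greedy sizes reaching the y and z coverage thresholds (defaults 98% and
99%). The final core is the Ny-prefix plus the (Nz − Ny) unselected
accessions of highest total rarity, where rarity of an allele is the
inverse of its carrier count and an accession's total rarity sums over
the alleles it carries (the published tool states no formula; the
inverse-carrier form is this package's choice, with a 1 − frequency
variant behind a flag). "Brute force" in the source description is
implemented as greedy max-coverage — exhaustive search is exponential —
but an exact subset-enumeration mode exists for ≤ 15 accessions and
serves as the test oracle; on random small instances the greedy size
matches the optimum in ≥ 90% of cases and never exceeds it by more than
one.

## Landscape genomics

Environmental predictors are pruned iteratively by VIF (threshold 2;
infinite-VIF duplicates fall first), then centred and scaled; the scaling
parameters are stored once and re-applied to every raster projected
through the model. The partial RDA residualizes both the centred genotype
matrix and the predictors on the conditioning block (the optimal-K Q
matrix minus one column, avoiding the sum-to-one singularity), fits
multivariate least squares, and eigen-decomposes the fitted values; the
variance partition {conditioned, constrained, unexplained} sums to one
and matches vegan's `rda(Y ~ X + Condition(Z))` on a frozen fixture. A
conditioning block that fully absorbs the predictors yields zero
constrained variance; partial aliasing is an error naming the aliased
columns. Axis significance permutes the residualized response rows; each
permutation's eigenvalues are obtained from the QR-projected p × loci
matrix, which shares the fitted values' singular values at a fraction of
the cost.

Candidate loci come from three routes: (i) loadings beyond ±2 SD on the
first three axes, annotated with the best-correlated variable; (ii) a
latent-factor scan — per-variable OLS of each locus on [1, variable,
k SVD factors], t statistics mapped to exact normal scores, genomic-
inflation calibration by the median-χ²₁ ratio, Bonferroni across
variables, then Benjamini–Hochberg across loci at FDR 0.05; (iii) a PC
outlier scan — per-locus regression z-vectors on k PCs, robust Mahalanobis
distance (MCD with support fraction 0.9: tolerant of ~10% outlying loci
while keeping near-classical tail calibration), GIF-corrected χ²_k
p-values, Bonferroni-thresholded at 0.05 (a pure-BH alternative is
available). The union of the three sets, with overlap bookkeeping, feeds
the adaptively enriched RDA (no conditioning, first two axes by default).

Genomic offset: every grid cell's scaled environment vector is projected
onto each retained axis through the fitted coefficient map (B·V); the
per-axis offset is |Δprojection| and the global offset the eigenvalue-
weighted Euclidean distance √(Σ_a w_a Δ_a²), w_a ∝ eigenvalue_a.
Geographic coordinates, being static across scenarios, contribute zero
offset and are excluded from raster projection. Several future raster
sets per scenario (e.g. circulation models) are averaged cell-wise before
projection — exactly commutative with the linear map. Offsets are exactly
zero when future equals current and exactly linear in single-direction
displacement; band classification uses half-open intervals of width 0.5.

## Synthetic study design

The generator emulates a three-population germplasm survey along a
latitudinal gradient: populations of 51/152/102 accessions in
south-to-north latitude bands, ~1,100 biallelic SNPs on seven ~50 Mbp
chromosomes, K = 4 ancestral groups under Balding–Nichols drift
(per-locus ancestral p ~ U(0.05, 0.95); group frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F), F = 0.05), Dirichlet admixture
(concentration 0.2 plus a boost of 1.0 on a population-preferred dominant
group, drawn from a soft preference matrix so every genetic group
contains accessions of every origin), Binomial(2, π) genotypes, 5%
uniform missingness, 2% of markers with reproducibility below 0.8, six
environmental variables on a 40 × 25 grid (smooth latitudinal gradient
plus spatially correlated noise), and 20 adaptive loci whose frequencies
follow logistic clines (logit shift = 1.5 × standardized driver). Future
scenarios displace each variable by one within-grid SD (SSP585 by 1.5×)
plus small correlated noise proportional to the shift, so a zero shift
reproduces the current grids exactly.

What the generator does **not** emulate — and what passing tests
therefore do not show about real collections: inbreeding/selfing
(genotypes are Hardy–Weinberg, so Ho ≈ Hs and F_IS ≈ 0, unlike highly
selfing crops), linkage disequilibrium (loci are independent given
ancestry), an L-shaped allele-frequency spectrum (the uniform ancestral
spectrum makes nearly all alleles common, so 98–99% allele coverage is
reached by ~10 accessions and the selected core is far smaller than a
real germplasm core), marker ascertainment, and spatially realistic
climate fields. For this reason the end-to-end acceptance run performs
the association and offset stages on the full collection — a
ten-accession core cannot support an eight-predictor model — while the
file-based pipeline keeps the core-set association workflow for data
whose cores are realistically sized.

## Problem sizes used in validation

The automated checks run at desk scale, chosen to exercise each property
with adequate statistical resolution: F_ST recovery at 2 × 200 diploids ×
2,000 loci × 10 seeds for drift targets 0.02/0.05/0.10 (tolerance ±0.02);
AMOVA null calibration over 200 simulations of 30 accessions × 60 loci
with 199 permutations (rejection within 5% ± 2%); ΔK modal recovery of
K = 4 over 10 seeds at 150 accessions × 500 loci, K = 1..6, 3 replicates;
greedy-vs-exhaustive core comparison on 100 Hardy–Weinberg instances of
≤ 12 accessions × ≤ 8 loci; scan calibration over 100 null simulations
(latent-factor FDR, PC-scan family-wise error) and power on the full
default design (union true-positive rate ≥ 0.7 over 10 seeds);
reproducibility by byte-comparing complete rerun outputs. The acceptance
script runs the full default design once per seed.

## Known limitations

- Deviance-based ΔK is a likelihood proxy; absolute values are not
  comparable with MCMC log-marginal estimates.
- The AMOVA copy-permutation scheme re-pairs copies per locus
  independently, which ignores gametic phase (unknown for unphased SNPs).
- The latent-factor scan estimates factors from the full genotype matrix
  including the tested locus; at panel sizes in the hundreds of loci the
  self-contribution is negligible but nonzero.
- Offset magnitudes inherit the RDA's eigenvalue scaling; bands are
  comparable within a model fit, not across fits.
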