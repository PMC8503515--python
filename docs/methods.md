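# Methods

## Model

`ancspec` works with a panel of M biallelic SNPs partitioned into sets
𝔊_1…𝔊_K, where every SNP in 𝔊_k is polymorphic (MAF f_km > 0) in
reference population k and monomorphic in the other K−1 reference
populations. For an individual with ancestral proportions p_n1…p_nK, each
of the two haplotypes at a SNP is assumed to originate from population k
with probability p_nk, independently of the other haplotype and of other
SNPs, and to carry the specific allele with probability f_km given that
origin. The minor-allele count at a population-k SNP is therefore
Binomial(2, p_nk f_km), with mean μ_km p_nk where μ_km = 2 f_km.
Independence across SNPs is an approximation justified by the low MAFs of
population-specific variants, which sit in weak linkage disequilibrium
with other variants.

From the mean structure, two linear unbiased estimators of p_nk follow:
the principal score a_nk = Σ X μ / Σ μ² (the projection onto the
asymptotic top right-singular vector of the reference genotype matrix,
scaled so that a population-k member's expected score is one) and the
ancestral information p̂_nk = Σ_{𝔊_k} X / Σ_{𝔊_k} μ. For rare alleles the
genotypic variance is approximately proportional to μ, and under that
variance law the equal-weight ratio is the minimum-variance linear
unbiased estimator; by the Cauchy–Schwarz inequality Var(a) ≥ Var(p̂)
with equality only for constant μ over 𝔊_k. Neither estimator constrains
Σ_k p̂_nk: totals below one indicate a missing or poorly-proxied source,
and p̂ > 1 indicates a cohort whose specific-allele frequencies exceed
the reference's. Both properties are diagnostics, not failure modes, and
values are never clipped.

The maximum-likelihood estimator treats each genotype as Bernoulli with
success probability p μ_km (the rare-allele limit of the binomial model)
and solves the score equation p Σ μ(1−X)/(1−pμ) = Σ X by Brent's method
on the bracket [0, (1−10⁻⁹)/max μ], the open upper limit being required
by 1 − pμ > 0 for every SNP; absolute tolerance 10⁻¹⁰. An individual
carrying no specific allele has MLE exactly 0 (the likelihood is
decreasing); if the score has no sign change on the bracket the upper end
is returned with a boundary flag. Since the Bernoulli likelihood is
defined only for X ∈ {0,1}, homozygous counts are truncated to 1 with a
warning — the moment estimator uses the untruncated counts, so a small
systematic MoM−MLE gap of order Σf²/Σμ remains even at small f.

## Genetic relationship matrix

Z = (1/M) X Xᵀ over the panel is exactly block-diagonal when samples are
unadmixed reference members, because specific alleles of different
populations have disjoint carriers. Its expectation has compound-symmetric
blocks with diagonal z_k = (1/M)Σ 2f and off-diagonal z_kk = (1/M)Σ 4f²,
hence closed-form eigenvalues λ_k = z_k + (N_k−1) z_kk (eigenvector
1/√N_k inside the block — the single population-informative direction)
and an (N_k−1)-fold repeated eigenvalue z_k − z_kk = (1/M)Σ σ² with
σ² = 2f(1−2f), pure within-population noise. These utilities validate the
theory and serve as diagnostics; the inference path never performs an
eigendecomposition, which is the practical point of the method.

## Panel construction

Per-population MAFs are computed with a single minor-allele designation
per SNP, made on the pooled reference sample (pooled frequency ≤ 0.5; at
exactly 0.5 the lexicographically smaller allele character is minor).
A pooled designation keeps one consistent counted allele per SNP; inside
the MAF windows used for panels (≤ 0.05) pooled and per-population
designations agree in practice. Missing calls are excluded from both the
numerator and denominator of the frequency; a population with no observed
call at a SNP has an undefined frequency there and the SNP is ineligible.
"Polymorphic" means strictly f > 0 on observed calls, so singletons count
as population specific; the MAF window then excludes them from panels.
The window is closed on both ends — the permissive reading of a range
stated without openness. Subsampling to the per-population panel size is
uniform without replacement from a seeded generator, making panel files
byte-reproducible. Defaults mirror a typical continental design: windows
[0.01, 0.05] and 50,000 SNPs per population.

## Missing data in scoring

When scoring study individuals, missing calls contribute zero copies and
the denominators are not rescaled: for rare panel alleles the
homozygous-major call is overwhelmingly likely, this choice keeps the
estimators linear, and it slightly shrinks rather than inflates
information under missingness. A per-individual call rate is emitted so
users can judge the potential bias.

## Synthetic data

The generator draws panel MAFs uniformly on a closed interval (default
[0.01, 0.05], the panel design window) or takes explicit frequency lists,
and simulates diploid genotypes as Binomial(2, p_nk f_km) — sampled
exactly as two Bernoulli haplotype draws. Diploid sampling, rather than
the 0/1 rare-allele approximation used in the theory, deliberately
produces occasional homozygotes so that the package's diploid-handling
choices are exercised; at small f the two models coincide.
`simulate_drifted_population` models two expectation-level departures of
real cohorts from their reference: deterministic frequency scaling
(drifted MAFs) and uniform random retention of a fraction of specific
sites (bottleneck loss), giving expected information scale × retention.
It is not a Wright–Fisher or coalescent simulation: there is no LD, no
site-frequency-spectrum realism, no relatedness and no genotyping error,
so passing tests demonstrate estimator correctness under the stated
model, not robustness to those real-data features.

## Numerical choices

* Projections are computed row-by-row (one matrix–vector product per
  individual), so an individual's scores are bitwise identical whatever
  batch they are computed in; a single matrix–matrix call could reorder
  summation with batch shape.
* Per-population allele counts use one blockwise summation pass when the
  panel's population blocks are contiguous (they always are for panels
  built by this package), falling back to the loading-vector projection
  otherwise.
* Genotype containers validate entries ∈ {0, 1, 2, NaN} in chunks;
  internal constructors whose output is valid by construction skip the
  scan.
* VCF matching is by CHROM+POS and unordered allele pair, not by ID
  (rsID presence drifts across call sets); when the panel's minor allele
  is the VCF REF the count is 2 − ALT dosage. Strand flips are never
  auto-corrected; palindromic A/T and C/G sites are matched literally and
  reported in a warning, since silent strand guessing corrupts
  rare-allele counts.

## Test scale

Unit tests run at panel sizes of a few hundred to a few thousand SNPs,
where all distributional checks already hold comfortably; the end-to-end
statistical tests use the design scale of 50,000 SNPs per population with
cohorts of 99–500 individuals, and the law-of-large-numbers check
contrasts panels of 10³ and 10⁴ SNPs over 10 replicates. All simulations
are seeded; statistical assertions use 3-standard-error bands (or
explicit small absolute cushions where a fixed random subset contributes
additional, analytically bounded variation).

## Known limitations

* Reference MAFs are treated as known; finite reference samples
  misclassify some shared-but-rare alleles as specific, which adds small
  spurious information components. Larger reference panels reduce this.
* The MLE inherits the 0/1 truncation and degrades for common alleles,
  where the Bernoulli approximation fails; the moment estimator remains
  valid there.
* Interpretation of information as an ancestral *proportion* requires the
  reference population to be a good proxy of the true ancestral source;
  otherwise it measures co-ancestry with the reference.
* The VCF reader handles hard-call GT fields of biallelic SNPs only;
  dosages, phased multiallelic records and BCF/PLINK formats are out of
  scope (convert upstream).
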