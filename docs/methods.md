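# Methods

## The omnibus multi-trait test

For one SNP, let *z* be the vector of association z-scores across *k*
traits and Ω the covariance of *z* at null SNPs. Assuming an
infinitesimal polygenic model, under the null hypothesis of no effect

    T = zᵀ Ω⁻¹ z  ~  χ²ₖ.

Ω differs from the identity because traits are phenotypically correlated
and studies share samples: Ωᵢⱼ = ρᵢⱼ · n_s(i,j) / √(nᵢ nⱼ), with ρᵢⱼ the
total phenotypic covariance, n_s the shared-sample count and nᵢ the
study sizes. Two limiting cases anchor intuition: disjoint cohorts give
a diagonal Ω, and fully shared cohorts give the Pearson correlation
matrix of the phenotypes (for standardized traits).

Implementation notes:

* The quadratic form is computed by Cholesky solve, never an explicit
  inverse; SNPs sharing a missingness pattern share one factorization.
* Traits masked at a SNP are dropped and the degrees of freedom reduced
  for that SNP, rather than padding zeros (zeros would deflate T).
* All p-values are carried as −log10(p) evaluated through `logsf`, so
  values far beyond 1e−300 remain representable; every threshold
  comparison (5·10⁻⁸ and its Bonferroni variants) happens in log space.

## Trans-ancestry extension

Cohorts of distinct ancestries are sample-independent, so per-ancestry
omnibus statistics add and Σₐ Tₐ ~ χ² with Σₐ kₐ degrees of freedom
(trait counts may differ per ancestry; a panel missing two traits
contributes k−2). This makes no homogeneity assumption on effects —
each ancestry may deviate from its null in a different direction. The
univariate comparator is the sample-size-weighted fixed-effect
meta-analysis Z_meta = Σ √Nₐ zₐ / √(Σ Nₐ), with weights renormalized
over the ancestries in which the SNP is present.

The sample-size downscaling transform Z_sim = Z/√N_total · √N_sim lets
a large cohort be replayed at any smaller sample size; it is exact on
the z scale because z scales with √N at fixed effect size.

## Estimating Ω by cross-trait LD-score regression

For each trait pair, zᵢ·zⱼ is regressed on the per-SNP LD score
(Σ r² within a 1000 kb window). Polygenic signal scales with the LD
score and loads on the slope; sample overlap and confounding do not,
and appear in the intercept — which is exactly Ωᵢⱼ. Diagonal entries
come from the regression of zᵢ² and are *not* forced to 1, so residual
inflation is absorbed into Ω rather than the statistic (a
`force_unit_diagonal` flag restores strict unit-variance semantics).

Weighting follows standard LD-score-regression practice: a first
unweighted pass fits the variance model var(zᵢzⱼ) ≈ (aᵢ+bᵢℓ)(aⱼ+bⱼℓ) +
(aᵢⱼ+bᵢⱼℓ)², and a second pass reweights by its inverse times the 1/ℓ
overcounting correction. SNPs with z² > 80 are excluded trait-wise:
strong single loci violate the polygenic regression model and would
otherwise drag the fit (the cap is configurable). Standard errors come
from a delete-one block jackknife over 200 contiguous SNP blocks.

Identifiability caveat: the intercept is an extrapolation to ℓ = 0. If
LD scores barely vary — as in a panel whose LD is artificially uniform —
intercept and slope are nearly collinear and the estimate is noise. The
synthetic LD generator therefore draws a different AR decay per block
(range [0.2, 0.95] by default), reproducing the order-of-magnitude
spread of real LD scores; with it, a 15×15 Ω is recovered with
entrywise MAE ≈ 0.005 at 10⁵ SNPs.

### Conditioning diagnostics

Nearly collinear traits measured on heavily overlapping samples give an
ill-conditioned Ω; the quadratic form then amplifies small estimation
errors into apparent genome-wide signal. `check_condition` reports the
eigenvalue-ratio condition number and flags values above 10⁴. The
default response to a flagged matrix is to fail loudly; `regularize`
offers explicit, logged shrinkage Ω′ = (1−λ)Ω + λI for users who accept
the trade-off. Both are surfaced in the CLI (`null-cov` refuses flagged
matrices unless `--regularize` is passed).

## Imputation of untyped SNPs

Within an LD block, z-scores are approximately jointly Gaussian with
covariance equal to the LD correlation matrix, so an untyped SNP *u* is
imputed by the conditional expectation ẑᵤ = Σᵤₜ Σₜₜ⁺ zₜ with quality
r²ᵤ = Σᵤₜ Σₜₜ⁺ Σₜᵤ (the explained variance share, clipped to [0, 1]).
Three accuracy controls, with defaults chosen for high-fidelity output:

| parameter | default | meaning |
|---|---|---|
| `r2_threshold` | 0.6 | minimum quality to keep an imputed z |
| `minimum_ld` | 5 | minimum count of typed neighbors with \|r\| > 0.2 |
| `eigen_threshold` | 0.05 | eigenvalues of Σₜₜ below this fraction of the largest are truncated from the pseudo-inverse |

`eigen_threshold` is interpreted relative to the largest eigenvalue,
and `minimum_ld` as the count of informative (|r| > 0.2) typed
neighbors. Imputed entries are flagged in the output so discovery can
distinguish imputed from typed leads. No variance re-inflation is
applied to imputed z (their variance is r²ᵤ < 1 by construction, which
the quality filter keeps near 1); the held-out accuracy harness
(`mask_and_assess`) reports per-trait correlations between masked and
re-imputed values.

## LD scores and quasi-independent blocks

The LD score of SNP *j* is Σᵢ r²ᵢⱼ over SNPs within 1000 kb, itself
included (so every score ≥ 1). Chromosomes are partitioned into
quasi-independent blocks by minimizing the sum of squared correlations
crossing block boundaries, ignoring r² < `thr_r2`, subject to block
sizes in [`min_size`, `max_size`] and at most `max_k` blocks. The
dynamic program is exact for this objective; ties resolve to fewest
blocks, then lexicographically earliest boundaries. Reference presets
for real chromosomes are thr_r2 = 0.05, min_size = 4000,
max_size = 5000, max_k = 400; the algorithm is size-agnostic and the
test suite exercises it at 6–25 SNPs, where exhaustive enumeration is
feasible as an oracle.

## Discovery and novelty

Regions whose minimum joint p passes 5·10⁻⁸ are clumped greedily
(PLINK-style): the smallest-p unassigned SNP with p ≤ p1 = 5·10⁻⁸
leads; unassigned SNPs with p ≤ p2 = 5·10⁻⁴ and r² ≥ 0.2 to the lead
join its clump (single assignment; p ties break to the leftmost
position). Clumps containing only their lead are discarded as
poor-quality signals. A lead is classified *new* when the joint test is
genome-wide significant and the minimum univariate p across traits is
not; the univariate minimum is deliberately uncorrected so that
anything any single-trait analysis would have reported counts as known
— a conservative novelty definition. An optional Bonferroni variant
re-tests at 5·10⁻⁸/#analyses. For trans-ancestry results, where LD
regions cannot be defined across populations, leads are the minimum-p
SNPs of fixed-origin 1 Mbp bins (bin = ⌊(pos−1)/10⁶⌋).

## Cross-ancestry comparison

* **Locus overlap**: a 1 Mbp bin counts as detected in an ancestry if it
  contains at least one significant association (joint or univariate);
  UpSet-style exclusive intersection counts summarize sharing, each
  subset flagged when it contains a joint-only discovery.
* **Signal similarity**: at bins occupied in two ancestries, the squared
  Pearson correlation of the two lead SNPs' z-vectors over shared
  traits. The same variant is used in both ancestries when it leads in
  both, otherwise each ancestry's own lead (both modes exposed).
  Computed on z rather than per-allele effects — the √N scale cancels
  in a correlation — and sign-insensitive, so divergence shows in the
  distribution of R², not its sign.
* **Downsampling specificity**: lead z-vectors of the largest cohort are
  shrunk by √f for f = 0…1 (step 0.01), p-values recomputed, and the
  fraction of still-detected bins that no other ancestry detects is
  traced. This separates genuinely population-specific loci from
  power artifacts.

## The synthetic-study generator

One ancestry is simulated as Z = R·Γ·diag(√N) + L_R·E·L_Ωᵀ: the mean is
the standardized effect matrix convolved through LD, the noise is
matrix-normal with row covariance R (block-diagonal AR(1) LD) and
column covariance Ω, i.e. Cov(vec Z) = Ω ⊗ R. Both factors use
Cholesky square roots; one seed gives bit-identical panels.

Default study conditions emulate a four-ancestry blood-trait design:
15 traits, per-trait sample sizes EUR 563,946 / EAS 151,807 /
AFR 15,171 / AMR 9,368; the EAS panel lacks two traits; ~10% of
variants are absent per non-EUR ancestry (masks never empty an LD
block); Ω has off-diagonals up to 0.6; 1% of SNPs are causal, each
hitting a random ~half of the traits with effects scaled so a typical
causal SNP reaches |z| ≈ 8 in the largest panel — strongly detectable
there, underpowered in the small panels, which is the regime where
multi-trait testing pays. Per-block AR decays are drawn from
[0.2, 0.95] per ancestry (LD is heterogeneous along the genome and
differs between populations). Optional per-ancestry effect perturbation
(`effect_divergence`) emulates population-specific pleiotropy.

What the generator does **not** emulate: genotype-level sampling,
coalescent/demographic realism, admixture LD, allele-frequency-
dependent effect sizes, cross-block LD, and strand/build errors in
input files. Passing tests therefore certify the statistical machinery
under the stated model, not robustness to every pathology of real
summary statistics.

## Numerical choices and degenerate inputs

* Quadratic forms and conditional expectations use Cholesky/eigh
  factorizations; singular Ω raises with a pointer to the diagnostics.
* Strand-ambiguous (A/T, C/G) records are dropped during harmonization
  rather than frequency-resolved; duplicated rsids keep the record with
  the largest n. Coordinates are 1-based as given by the panel. A
  record whose effect/other alleles are swapped relative to the panel
  orientation has its z sign flipped; the flip conserves |z| exactly
  and harmonization is idempotent.
* Sample-size harmonization masks SNPs below 70% of a trait's
  90th-percentile n (the named step's rule is a design choice of this
  package); the trait's scalar N is the median n of retained SNPs.
* Identity-LD blocks make every SNP uninformative for imputation: the
  quality filter removes everything and the assessment reports NaN
  correlations rather than failing.
* `mask_fraction = 0` yields an explicit empty assessment; infeasible
  block-splitting constraints (n > max_k·max_size, or no size
  combination tiling n) raise rather than silently relaxing.

## Problem sizes used in validation

Calibration and Ω-recovery runs use 10⁵ SNPs × 15 traits (≈ the SNP
count of a small chromosome after QC); trans-ancestry calibration uses
four such panels; power comparisons use 4,000 replicates; combinatorial
oracles use ≤ 25-SNP instances where exhaustive enumeration is exact.
These sizes were chosen so the full validation suite completes in
minutes on a single CPU while keeping Monte-Carlo error well inside the
asserted tolerances.

## Known limitations

* The LDSC-intercept route sidesteps how ρᵢⱼ·n_s/√(nᵢnⱼ) behaves when
  per-SNP N varies within a trait; the sample-size harmonization step
  reduces, but does not eliminate, that heterogeneity.
* Ω estimation for many traits needs many SNPs: at a few thousand SNPs
  a 15×15 estimate is noisy enough to lose positive definiteness (the
  conditioning diagnostics catch this; the remedy is more SNPs, fewer
  traits, or explicit shrinkage).
* Trans-ancestry addition assumes strictly disjoint cohorts; shared
  individuals across ancestry panels would inflate the combined test.
* Clumping uses the ancestry-matched LD store; cross-ancestry LD
  differences mean clump boundaries are not comparable across panels —
  hence the fixed 1 Mbp bins for all cross-ancestry accounting.
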