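# Methods

`leafgwas` reimplements, as a tested pipeline on synthetic data, a
multivariate linear-mixed-model (mvLMM) genome-wide association analysis of
leaf shape in a clonally replicated F1 tree cross. This note documents the
models, the synthetic-data generator that stands in for the field and
sequencing data, the numerical choices, and what the tests do and do not
demonstrate.

## The statistical model

Phenotypes are tree-level observations from a randomized complete block
design (RCBD): clone *j* is replicated as cuttings across blocks *i*. For
*t* traits the model is

    Y = X B + Z G + E

* `Y` (n x t): trait values of the n trees; the multivariate phenotype is a
  set of regular polar radii from the leaf centroid to its margin.
* `X` (n x p): fixed effects — intercept, block effects, and the
  genotype-class indicators of the tested SNP (reference-coded; p = 1 +
  (b-1) + (g-1) for b blocks and g genotype classes). F1 genotype classes
  are modeled as unordered levels, not dosages, because outbred segregation
  types yield 2–4 heterogeneous classes.
* `G` (c x t): clone-level polygenic effects, `Vec(G) ~ N(0, V_G ⊗ A)`
  where `A` is the additive relationship among clones. A single full-sib
  family of non-inbred parents has pairwise kinship 1/4, so `A` has unit
  diagonal and 0.5 off-diagonal; its spectrum is closed-form
  ((1+c)/2 once, 1/2 with multiplicity c-1).
* `E` (n x t): residuals, `Vec(E) ~ N(0, V_E ⊗ I_n)`.

The per-SNP hypothesis `M Vec(B) = 0` (all genotype-class coefficients,
all traits; q = (g-1)t rows) is tested with

    F = (1/q) (M Vec(B̂))' [ M ((I_t⊗X)' V⁻¹ (I_t⊗X))⁻¹ M' ]⁻¹ (M Vec(B̂))

referred to F(q, t(n-p)). Per-SNP variance explained is
`R² = 1 - RSS/RSS0` on the V⁻¹-weighted residual sums of squares of the
full vs the no-SNP fixed-effect model (same fitted V in both, which keeps
R² in [0,1] by construction). Univariate scans use the t = 1 special case;
narrow-sense heritability is `h² = σg²/(σg²+σe²)` from the no-SNP model.

Scans are P3D-style by default: (V_G, V_E) are REML-fitted once under the
no-SNP null and reused for every SNP's GLS/F test. An `exact` switch
refits per SNP; on null data the two agree closely and P3D is hundreds of
times faster. Trees whose clone genotype is missing at a SNP are dropped
for that SNP only (complete-case per test).

One modeling switch deserves note: the univariate model is often written
with `cov(g) = σg² I_c`, while the multivariate model uses `σg² A`. For a
single full-sib family these differ only through the constant 0.5
off-diagonal (half the genetic variance becomes a family-wide constant that
the intercept absorbs). The package uses `A` in both by default for
consistency (`A=None` selects the identity variant); heritability is
computed from the fitted components either way.

## REML estimation

The restricted likelihood is evaluated through a double diagonalization:

1. **Clone kernel.** K = Z A Z' has rank ≤ c; its nonzero eigenpairs come
   from the c x c matrix `A^{1/2} diag(m) A^{1/2}` (m = trees per clone),
   so no n x n eigendecomposition is ever formed. Directions orthogonal to
   the kernel have pure residual covariance.
2. **Trait basis.** With `V_E = L L'` and `L⁻¹ V_G L⁻ᵀ = Q M Q'`, the
   transform `T = Q' L⁻¹` makes all per-eigendirection covariances
   simultaneously diagonal: the rotated data decouple into t independent
   weighted regressions with weights `λ_j μ_k + 1`.

One evaluation of the restricted log-likelihood and its analytic gradient
(via `d(-2ℓ) = tr(P dV) - r'V⁻¹ dV V⁻¹ r`, which collapses onto
`T' [diag(·) - M] T` patterns in the same basis) costs O(t³ + c t + t p³).
The objective is maximized over Cholesky factors of (V_G, V_E) with
log-diagonal parameterization (bounds ±14 keep the factors finite; V_G may
reach the zero boundary) using L-BFGS-B, started from method-of-moments
values (within-clone residual covariance and clone-mean covariance). A
direct quasi-Newton maximization was chosen over EM because it converges
in tens of iterations where EM stalls near the V_G boundary, and the
per-dataset refits of the power study need the speed. Convergence:
relative change in -2ℓ below 1e-14 (effectively gradient-limited; looser
tolerances were found to leave the flat common-size direction of V_G
short of the optimum, which measurably inflates every downstream test),
2000 iterations maximum, non-convergence flagged on the result. The univariate fitter profiles the
same restricted likelihood over the variance ratio δ = σg²/σe² (grid on
log δ in [-12, 12] plus Brent refinement) and checks the σg² = 0 boundary
explicitly. At t = 1 the two fitters agree to optimizer tolerance, which
the tests assert.

Polar radii are strongly correlated (phenotypic correlations above 0.9 are
typical), so V_G/V_E are near-singular in the common-size direction; the
simultaneous diagonalization handles this without explicit regularization
beyond a 1e-10-scale jitter when Cholesky-factorizing a fitted V_E inside
the scanner.

## Scan post-processing

* **Genomic inflation.** Each p-value is converted to its 1-df chi-square
  quantile; `λ_GC = median(χ²) / 0.4549` (the χ²₁ median). The
  median-based definition is used, not mean-based.
* **Genomic control.** When λ_GC > 1 the chi-squares are divided by λ_GC
  and reconverted; deflation (λ_GC ≤ 1) is deliberately left uncorrected,
  and significance is assessed on the controlled p-values only when
  λ_GC > 1.
* **Threshold.** Bonferroni at α/m where m is always the LD-pruning
  survivor count (independent markers and LD blocks), never the raw SNP
  count. The worked example 0.05/10735 = 4.66e-6 (-log10 = 5.33) is frozen
  in the tests.
* **Regions.** Significant SNPs of a chromosome are split where the
  -log10(p) sequence switches from strictly decreasing to strictly
  increasing; ties extend the current trend. The strict-vs-non-strict
  choice at ties is isolated in one comparator.

## Genotype QC

Parental genotype configurations are classified into the five supported F1
segregation types (aa×ab, aa×bc, ab×aa, ab×cc at 1:1; ab×ab at 1:2:1).
Het × het configurations sharing exactly one allele (ab×ac, 1:1:1:1) are
treated as unclassifiable — the filter would admit a 1:1:1:1 ratio, but
the type is outside the five-type summary this package mirrors. A SNP
passes QC when its offspring counts fit the Mendelian ratio by chi-square
at p > 0.01, fewer than 10% of clone genotypes are missing, and the ratio
is admitted. LD pruning is sliding-window greedy (window 25 SNPs, step 2,
r² > 0.7): within a window, while any retained pair exceeds the threshold
the member with more missing data (ties: later position) is removed;
windows never span chromosomes. r² uses Pearson correlation of numeric
codes: two-class types 0/1, ab×ab by allele dosage 0/1/2. The survivor
count is the Bonferroni denominator.

## Synthetic data

The generator defines the study conditions everywhere downstream:

* **Cross.** 163 clones (default), 19 chromosomes, 1.5 Morgans each, SNP
  positions uniform, segregation types drawn with the observed five-type
  proportions (≈40% aa×ab, ≈58% ab×aa, the rest rare). Parental
  haplotypes are phased with random per-SNP phase; gametes recombine under
  the Haldane map function, so LD arises from physical linkage rather than
  a target r² matrix. Physical positions use a constant 16 Mb/Morgan.
  Genotype missingness is injected uniformly at random (3% default); no
  sequencing-error or calling model is simulated.
* **Trial.** 3 blocks, 6 cuttings per clone and plot; trees are removed
  independently at random with survival 0.765 (the observed
  trees-per-planted-cutting fraction); no spatial structure. Phenotypes
  are realized exactly per the model above. Default radius covariances
  use per-trait SD 20 mm, heritability 0.45, genetic correlation 0.9 and
  residual correlation 0.8 — matching the reference study's trait SDs
  (16–24 mm), heritabilities (40–50%) and inter-trait correlations
  (mostly > 0.9). Default trait means follow an ellipse radius profile
  (semi-axes 57 x 45 mm, matching the reference mean length/width).
* **Leaves.** Parametric silhouettes (circle, ellipse, rectangle, tapered
  ellipse) with continuous-geometry ground truth for boundary, centroid,
  polar radii and size traits; rasterized by scanline fill at 300 dpi.
  Real leaves differ in ways the fixtures do not model — petioles, lobing,
  serration, scanning artifacts — so passing geometry tests shows the
  measurement pipeline is exact on clean silhouettes, not that it is
  robust to field imagery.

## Study designs in `studies.py`

* **Null calibration** uses 2,000 *unlinked* null markers (one per
  simulated chromosome). This is deliberate: the reference distributions
  used to judge calibration (the exact binomial interval for the rejection
  rate, the χ²₁ median for λ_GC) presuppose independent tests. Linkage
  does not change per-test calibration, only the correlation between
  tests; with the default dense map the 2,000 statistics have a small
  effective sample size and both λ_GC and the empirical rate fluctuate far
  beyond their nominal references. With the fitted-V (P3D) scan on
  unlinked markers, λ_GC lands close to 1; using the *true* simulation V
  instead gives wider λ swings because the fitted V tracks the realized
  clone effects of each dataset — in-sample REML is the conditionally
  calibrated choice. Two residual effects remain even with unlinked
  markers. First, all 2,000 statistics share one phenotype realization
  and live in the ~150-dimensional clone space, so the per-scan rejection
  rate and median keep a conditional spread well beyond the independent-
  trial references (λ_GC itself has a sampling SE of ~0.07 from a median
  of 2,000 even under perfect calibration). Second, the mvLMM at t = 11
  is mildly conservative — measured empirical type-I error ~0.040 at
  nominal 0.05, with median inflation λ ~1.05 — because the 132-parameter
  V̂ absorbs part of the noise the tests would otherwise see and is then
  treated as known; this is inherited from the P3D construction, exactly
  as in the reference method, and a small-sample (Kenward-Roger-style)
  correction is deliberately out of scope.
* **Power** compares the multivariate 11-radius test against each
  single-radius test on 200 one-QTL datasets. The QTL shifts heterozygote
  radii by `6 mm x cos(θ)` — the leaf widens but does not lengthen, a
  realistic pleiotropic pattern spread across traits. The multivariate
  test runs at the Bonferroni threshold 0.05/10735; univariate tests at
  that threshold divided by 11 so the family-wise level is matched. The
  acceptance check is the ordering (multivariate ≥ every univariate), not
  a particular power value, so it is insensitive to the effect size.
* **Recovery** checks REML against the simulated truth: univariate
  σg² = σe² = 1 and bivariate V_G = diag(1,2), V_E = I, 150 clones,
  3 blocks, 5 cuttings, 100 replicates, agreement within 3 Monte-Carlo
  standard errors.
* **Geometry** renders 100 random leaves (alternating upright ellipses and
  tilted tapered leaves, semi-lengths 45–75 mm) and requires the pixel
  pipeline's mean relative errors in L, W, A to stay below the reference
  study's cross-software discrepancies (1.45%, 4.76%, 5.05%) and ellipse
  radii to match the closed form within 1%. In practice the pipeline is
  ~50x more accurate than those bars.

Problem sizes (2,000 SNPs, 150 clones, 100–200 replicates) are desk-scale
choices that keep every study's Monte-Carlo error far below the margins it
is judged against.

## Numerical and convention choices

* Binarization of grayscale leaf scans: Otsu's threshold; boolean inputs
  pass through.
* Angle convention: after normalization the leaf tip is at +π/2, the base
  at -π/2, angle 0 points to the leaf's right; the "right side" of the
  blade is exactly [-π/2, π/2]. Reduced radius sets RDk place k radii on
  that span, endpoints inclusive, spacing 180/(k-1) degrees — the only
  uniform rule giving integer-degree grids for k ∈ {6, 9, 11, 16, 61}.
* Radii are exact ray/boundary-edge intersections (not nearest-grid or
  angle-linear interpolation); for non-star-convex outlines the farthest
  intersection is taken and the profile flagged for audit.
* Orientation normalization uses the polygon's area moments (not vertex
  PCA); near-circular outlines (principal-moment ratio < 1.05) are
  centred, flagged, and left unrotated.
* Centroids are area-weighted (shoelace), never vertex means.
* All geometry is in mm via pixels-per-mm (300 dpi = 11.811 by default);
  genomic coordinates are 1-based (VCF convention).
* Abstract alleles a/b/c map to bases A/C/G in written VCFs; parents are
  the first two samples, phased; offspring unphased.

## Known limitations

* The P3D multivariate test at large t is slightly conservative (see
  above); a Kenward-Roger-style small-sample correction is out of scope.
* The full-sib kinship is theoretical, not marker-based; realized
  relationship estimation is out of scope.
* The LD pruner reports survivors as "independent markers and LD blocks"
  without enumerating blocks.
* Leaf fixtures carry no petiole and no margin detail; the measurement
  pipeline is untested on real scans.
* The simulator models neither genotyping error nor spatial field trends.
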