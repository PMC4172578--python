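# Methods

## Model

For a trait vector `y` over `n` individuals, the per-marker test fits

    y = X b + g a + u + e,    u ~ N(0, s2_a K),    e ~ N(0, s2_e I)

with fixed covariates `X` (always including an intercept), marker dosage
`g` in [0, 2], polygenic random effect `u` structured by a kinship matrix
`K`, and i.i.d. residual `e`. The null hypothesis is `a = 0`, tested with
an F statistic from generalized least squares under the fitted covariance
`V = s2_a K + s2_e I`.

## Kinship

`K` is the VanRaden genomic relationship matrix: with dosage matrix `G`
(n x m), column allele frequencies `p_j` estimated from the data, and
centered matrix `M` with columns `g_j - 2 p_j`,

    K = M M' / c,    c = 2 * sum_j p_j (1 - p_j).

Monomorphic markers contribute nothing (their centered column and their
`c` term are both zero). Because both `M M'` and `c` are sums over
markers, excluding a marker subset `S` is an exact downdate:

    K_new = (c K - M_S M_S') / (c - c_S)

using the retained raw crossproduct; `exclude_markers` implements this and
matches a from-scratch rebuild to machine precision. Excluding every
polymorphic marker leaves no kinship; callers receive a dedicated
exception (`EmptyKinshipError`) and the scan falls back to the
fixed-effects model.

## Variance components: spectral REML

Variance components are estimated by restricted maximum likelihood,
reduced to a one-dimensional problem in the ratio `delta = s2_e / s2_a`.
Let `Q` (n x m_r, `m_r = n - rank(X)`) be an orthonormal basis of the
orthogonal complement of col(X), obtained from an SVD of `X`. With the
eigendecomposition `Q' K Q = U diag(lambda) U'` and rotated data
`eta = U' Q' y`, the profiled restricted log-likelihood is

    LL(delta) = 0.5 * [ m_r log(m_r / 2 pi) - m_r
                        - m_r log( sum_i eta_i^2 / (lambda_i + delta) )
                        - sum_i log(lambda_i + delta) ].

This equals the textbook dense form (with its `+ log|X'X|` convention)
exactly; the test suite checks agreement with an explicit-inversion,
10,001-point grid oracle to 1e-6.

Optimization: `LL` is evaluated on a 100-point grid in
`log(delta) in [-10, 10]`; every local maximum is refined with bounded
scalar minimization (`xatol = 1e-8`) and the best refined point wins. The
projected kinship's eigenvalues are repaired for round-off: values in
`[-1e-8, 0)` are clamped to zero, anything below `-1e-8` is an error.

## Marker tests, P3D, and whitening

Following the P3D/EMMAX idea, the variance components are estimated once
under the no-marker model and held fixed for every marker's GLS F-test
(denominator degrees of freedom `n - rank(X) - 1`). Markers collinear with
the covariates (including monomorphic ones) are reported as untestable
sentinels rather than given fabricated p-values. An exact mode
(`mlm_scan(..., p3d=False)`) re-estimates the variance components with the
marker in the model; rank agreement between the two is checked in the
acceptance tests (Spearman >= 0.99 at n = 150, m = 1000).

Tests are computed in a whitened coordinate system. For a full-rank
kinship the whitening comes from the spectral decomposition of `V`. For
pseudo-QTN kinships of rank `s << n` the package instead uses the Woodbury
structure: with `V = s2_e I + (s2_a / c) M M'` and the SVD `M = U S W'`,
whitening is a rank-`s` correction to a scaled identity, costing
O(n s^2) instead of O(n^3). F statistics are quadratic forms in `V^{-1}`
and therefore independent of which square root is used; the equivalence is
tested directly. Batch testing vectorizes the Frisch–Waugh residual
regression across markers.

## The trait-specific scan

1. **Stage 1** ranks markers with a fixed-effects scan (a mixed-model
   first stage is available via `first_stage="mlm"`).
2. **Stage 2** partitions each chromosome into bins of `b` bp
   (`bin = floor((position - 1) / b)`), takes each bin's most significant
   testable marker, and keeps the top `s` as pseudo-QTNs. The pair
   `(s, b)` is chosen over a grid (defaults `s in {10, 20, 40, 80}`,
   `b in {0.5, 5, 50} Mb`) by maximizing the marker-free REML
   log-likelihood of the pool kinship. `s` is capped at the number of
   bins and at `n - rank(X) - 2`; ties prefer smaller `s`, then smaller
   `b`. Representative ties within a bin break deterministically by
   (p-value, position, marker id).
3. **Stage 3** retests every marker with the pool kinship minus pool
   members whose squared dosage correlation with the tested marker is
   `>= t` (default 0.10). Markers sharing an exclusion set share a
   whitening context, so the scan groups markers by exclusion set and
   builds one low-rank context per distinct set. A marker that excludes
   the entire pool is tested under the fixed-effects model.

The variance-component ratio is estimated once from the full pool and
reused across exclusion sets; re-estimating per set is available in an
internal exact mode and changes results negligibly while costing an
eigendecomposition per set.

Limits: `t > 1` reproduces the ordinary mixed-model scan over the pool
kinship, and `t = 0` reproduces the fixed-effects scan, both to 1e-10.

## Simulator

Genotypes follow a Balding–Nichols construction: each marker draws an
ancestral frequency from U(0.1, 0.9); each subpopulation draws its own
frequency from Beta with mean the ancestral frequency and scale set by
Fst. Local linkage disequilibrium comes from first-order haplotype
copying: with probability `ld_rho` an individual's allele at marker `j`
copies its allele at marker `j - 1`, resetting at chromosome boundaries.
Dosages are diploid 0/1/2 sums of two such haplotypes, or 0/2 under the
inbred coding. A Hudson-type Fst estimate on simulated panels recovers
the target within 0.05, and adjacent-marker r^2 responds to `ld_rho` as
expected.

Traits are additive: `n_qtn` markers drawn uniformly (optionally avoiding
a held-out chromosome), standard normal effect sizes, and residual
variance `Ve = Va (1 - h2) / h2` computed from the *realized* genetic
variance in the simulated panel, so the expected heritability matches the
target (`h2 = 0.75` gives `Ve = Va / 3` exactly; realized heritability is
within 0.03 of target on large panels). Conventions at the boundary:
`h2 = 1` is noiseless; `h2 = 0` is pure noise with variance `Va` while the
truth records (QTN positions, effects) are still populated. All random
streams are spawned from a single `SeedSequence`, so every artifact is
reproducible from one integer seed.

What the simulator does not model: genotyping error, missingness
mechanisms, dominance or epistasis, realistic recombination maps, allele
frequency spectra from real demographies, or family structure beyond the
subpopulation level.

## Evaluation harness

- **Empirical power.** Per replicate, the significance threshold is the
  `ceil(alpha * k)`-th smallest p-value among null markers (non-QTNs, or a
  held-out chromosome's markers), and power is the fraction of QTNs at or
  below it. Untestable QTNs count as misses. Studies report mean and
  standard error across replicates; replicate traits come from independent
  spawned seeds over a fixed genotype panel (regenerable per replicate on
  request).
- **Genomic control.** `lambda_GC` is the median association chi-square
  over 0.4549364 (the 1-df median). Zero p-values are clamped with a
  warning.
- **Multiple testing.** A Bonferroni threshold `alpha / m` (0.05 over
  3,117 markers gives 1.6e-5) and Benjamini–Hochberg q-values (delegated
  to statsmodels).

## Design decisions and limitations

- Kinship exclusion downdates keep the raw crossproduct in memory
  (opt-in via `keep_crossproduct=True`); without it, exclusion recomputes
  from the genotypes.
- The scan holds `s2_a / s2_e` fixed across exclusion sets (see above);
  this is the standard approximation and is what makes the scan
  O(n s^2) per distinct exclusion set.
- p-values are clamped away from exact zero (`nextafter(0, 1)`) so
  downstream log transforms are finite.
- Dosages must lie in [0, 2]; missing genotypes are NaN and must be
  imputed (mean imputation provided) before model fitting.
- The package targets desk-scale panels (up to a few thousand samples and
  tens of thousands of markers); it makes no attempt at biobank-scale
  out-of-core computation.
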