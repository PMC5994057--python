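# Methods

## Data model and notation

A multi-omic experiment measuring `p1` data (or tissue) types on `p2`
samples over `p` features is arranged as an order-3 tensor
`X ∈ R^{p1×p2×p}`.  The feature axis is treated as the axis of i.i.d.
realisations of a `p1 × p2` random matrix; decompositions act on modes 1
and 2 only.  Two primitives define everything else:

* mode contraction `(Z ⊙ₘ A)[..., iₘ, ...] = Σⱼ Z[..., j, ...] A[iₘ, j]`;
* mode covariance `(X ⊙₋ₘ X)_{uv}`, the `pₘ × pₘ` sum of outer products
  over all remaining indices.

The mode covariance is divided by the number of summed terms
(`p · p_other`) by default so its eigenvalues are on a variance scale.
This is a pure rescaling: eigenvectors, and hence every rotation and
source estimate downstream, are unchanged.  Unnormalised, the matrix
satisfies the exact identity `trace = Σ X²` used in tests.

Each `(type, sample)` variable is centered across its feature realisations
before any decomposition (flag to disable); no variance scaling is applied
at that stage, so data types keep their native scales until whitening.

## Tensorial PCA and whitening

tPCA eigendecomposes both mode covariances of the centered tensor,
`Cₘ = Ωₘ Λₘ Ωₘᵀ`, columns sorted by decreasing eigenvalue and sign-fixed
(largest-magnitude entry of each eigenvector made positive) so output is
deterministic.  Eigenvalues below `1e-12 ×` the largest are treated as
exactly zero; whitening a mode whose retained spectrum contains such an
eigenvalue raises an error naming the mode rather than dividing by ~0.

Retained dimensions `(d1, d2)` come from one of three policies:

* `full` — no reduction;
* explicit `(d1, d2)`;
* `rmt` — mode 1 (data types, always small in the intended applications)
  is kept full, and the sample-mode dimension is the **maximum of the
  per-type random-matrix estimates**, each computed on that type's
  feature × sample matrix.  The estimator standardises columns and counts
  eigenvalues of their sample correlation matrix above the
  Marchenko–Pastur upper edge `(1 + √(n_var/n_obs))²`.  No reduction is
  applied to modes of size ≤ 3.

The plain asymptotic edge is used without finite-size correction.  At
1000 × 100 the largest pure-noise eigenvalue fluctuates around the edge on
the Tracy–Widom scale, so pure noise yields a nonzero estimate in roughly
10% of datasets; planted signals of realistic amplitude are detected
essentially always.  This false-positive rate only ever costs one spare
component, which downstream kurtosis ranking then de-prioritises.

Whitening composes the reduced projection with eigenvalue rescaling,
`X ⊙ₘ Λₘ^{-1/2} Ωₘᵀ`, **sequentially**: mode 1 first, then mode 2 with
eigenvectors recomputed from the mode-1-whitened tensor.  Consequences
worth knowing:

* the mode whitened last has *exactly* identity covariance (tested at
  1e-10); a single whitened mode is likewise exact;
* joint whiteness of both modes holds approximately, to `O(1/√p)`
  (measured ~2e-4 relative off-diagonal at p = 10000).  Exact simultaneous
  two-mode whitening does not exist in general (it is the flip-flop /
  separable-covariance MLE problem); the sequential scheme is exact in the
  separable-population limit and is what the rotations assume.

The same `O(1/√p)` caveat applies to the fitted source tensor: slices of
the last-whitened mode have unit variance essentially exactly, the other
mode to ~3% at p = 10000 under the exact generative model.

## Tensorial ICA: tWFOBI and tWJADE

After whitening, one orthogonal rotation per mode remains.  Both rotations
are computed from the same whitened tensor and applied together.

**FOBI.**  For mode `m`, the rotation is the eigenvector matrix of
`Bₘ = (1/p) Σᵢ Mᵢ Mᵢᵀ Mᵢ Mᵢᵀ`, `Mᵢ` the mode-`m` flattening of
realisation `i`.  When the other mode has size 1 this is classical FOBI's
`E[‖x‖² x xᵀ]` exactly (asserted in tests).  In source coordinates `Bₘ` is
diagonal with entries `Σⱼ κ(S_aj) + const`, which gives the estimator's
**identifiability condition: per-component kurtosis sums must be
distinct.**  For i.i.d. sources (e.g. all slices Laplace) the population
eigenvalues tie exactly and the rotation is arbitrary within the tied
subspace — recovery correlations then hover around `cos` of an arbitrary
angle (~0.7) no matter how large `p` is.  The implementation warns on
(near-)tied spectra; the acceptance suite keeps the i.i.d. Laplace
recovery check for FOBI, where it fails for this structural reason, and
verifies recovery (> 0.99 median correlation) in the distinct-kurtosis
regime.

**JADE.**  For mode `m` the `d(d+1)/2` symmetrised fourth-cumulant
matrices `C^{(ij)} = mean[rᵢ rⱼ r rᵀ] − δᵢⱼI − eᵢeⱼᵀ − eⱼeᵢᵀ` are
estimated over all `p · d_other` pooled mode-`m` fibers and jointly
diagonalised by Givens sweeps (closed-form optimal angle per pair from the
principal eigenvector of the accumulated 2×2 Jacobi matrix; stop when
every rotation angle in a sweep is below 1e-8 or after 100 sweeps; the
off-diagonal mass is non-increasing by construction).  All cumulant
matrices are used — no eigen-matrix truncation — since retained dimensions
are ≤ ~40 in every intended use.  JADE has no distinct-kurtosis
requirement and separates any independent sources with at most one
Gaussian component per mode.

**Conventions.**  The per-mode unmixing maps are
`Wₘ = Uₘᵀ Λₘ^{-1/2} Ωₘᵀ` with pseudo-inverse mixing `Aₘ`; the source is
the centered tensor contracted with both.  Sign indeterminacy is resolved
per mode (only `p1 + p2` signs are free, not one per slice): mode-1 then
mode-2 component signs are chosen to make the skewness of the affected
slices, pooled over the other mode, non-negative, falling back to a
positive largest-|weight| entry when pooled |skewness| < 1e-8.  Components
in the sample mode are ranked by decreasing max-over-data-type excess
kurtosis, ties broken by index; data-type components stay in their
original order after back-projection.  Kurtosis is always *excess*
kurtosis (`m₄/m₂² − 3`, no small-sample correction).  The entire pipeline
is deterministic — there is no internal randomness to seed.

Interpretation happens after back-projecting the source onto the original
data-type axes (`S ⊙₁ A₁`, requiring mode 1 unreduced), which yields one
feature-weight vector per (data type, component) — e.g. the blood and
buccal axes of a methylation component.

## Simulation benchmark

The generator emulates a two-omic experiment as two 1000 × 100
feature × sample matrices with shared labels:

| parameter | default | meaning |
|---|---|---|
| `e` | 3 | block effect size (mean shift of signal entries) |
| `sigma` | 1–5 | noise SD; signal-to-noise ratio is `e/σ` |
| `jv_genes_per_type` | 50 | joint-variation genes per type (disjoint between types; 100 total) |
| `jv_samples` | 20 | samples shared by the joint source |
| `iv_genes`, `iv_samples` | 50, 10 | individual-variation block per type, unique to it |
| `distribution` | gaussian | or `laplace`, matched mean and SD (scale `σ/√2`) |

Joint-variation entries are drawn from `N(+e, σ)` in type 1 and `N(−e, σ)`
in type 2; individual variation from `N(+e, σ)`; everything else is
`N(0, σ)` noise.  Signal blocks *replace* background draws rather than
adding to them.  Index sets are drawn uniformly without replacement;
individual-variation sets are drawn disjoint from the joint sets (and from
each other across types) so truth labels are unambiguous — a flag allows
overlap.  Generation uses NumPy's PCG64 generator with a fixed stream
order (gene sets, sample sets, background, JV blocks, IV blocks), so a
seed reproduces a dataset bit-exactly across platforms.

The evaluation protocol fits 2 × 6 components, back-projects onto the two
data types, selects the top-50 |weight| genes per (type, component), and
scores sensitivity/specificity against the type's joint-variation gene
set, averaged over the two types; the best component is chosen by SE with
ties broken by SP then index (the per-component table is also available,
since SE- and SP-optimal components could in principle differ).  The
benchmark harness runs this over a noise grid with seed `seed + r` for run
`r`, so every method sees identical data and per-run values support the
paired one-tailed Wilcoxon signed-rank comparisons (exact null for ≤ 25
clean pairs, normal approximation with tie correction otherwise; all-zero
differences report p = 1 with a warning).  Adapters for external
decomposition methods are plain callables `tensor → (type × component ×
feature) weights`; a failing adapter is recorded as missing and excluded
pairwise.

What the simulator does *not* emulate: feature–feature correlation,
beta-value boundedness of methylation data, batch effects, or unmatched
feature sets across data types.  Passing benchmarks therefore demonstrate
correct recovery of block-structured joint variation under additive noise,
not performance on raw array data.

At desk scale the suite runs 50 Monte-Carlo runs per noise level rather
than 1000; measured mean SE for both tICA flavours is 1.00 at σ = 1,
declining monotonically to ~0.3 at σ = 5, with SP ≥ 0.96 throughout.

## Downstream inference

* **Top-`k` selection** is by decreasing |weight| with index tie-break
  (deterministic).
* **Fisher enrichment** (feature-category tests, e.g. mQTL lists) uses the
  one-tailed hypergeometric upper tail; OR = `ad/bc`, `+inf` when
  `bc = 0`, undefined (with p = 1) when the category is the whole
  universe.  **Binomial enrichment** (truth-set screening and chromosome
  tests) uses the exact upper tail `P(X ≥ x)`, `X ~ Bin(k, q)`; the
  background fraction `q` defaults to the category's share of the feature
  universe (the array-wide share can be supplied instead).  Both agree
  with big-integer enumeration oracles over an exhaustive small-table
  sweep in the test suite.
* **SE(max)/SE(all)**: per (data type, component), the top-`k` selection
  (`k` matched to the truth-set size by default) yields a sensitivity;
  SE(max) is the best single component.  A component is *enriched* when
  its binomial p-value beats `0.05 / (components tested)` (plain
  Bonferroni, components counted over both modes); SE(all) is the
  sensitivity of the union of selections over enriched components, and 0
  by convention when nothing is enriched.
* **Specificity calls** per component: a feature is *cell-type
  independent* when its |weight| is ≥ the 90th percentile (linear
  interpolation) in every data-type level; *cell-type specific* when it is
  strictly below the median in exactly one or two levels while reaching
  the top decile in at least one; everything else is reported as
  *unclassified*, never dropped.  Calls are invariant to positive
  rescaling of any level's weights.
* **Iterative kurtosis selection** removes the largest-|weight| feature
  while the remaining vector's excess kurtosis stays ≥ 1, capped at 500
  removals (inclusive cap: at most 500 features are ever returned; an
  initially sub-threshold vector selects nothing).
* **Phenotype association** of a sample-mode mixing column: OLS slope
  t-test for continuous/ordinal phenotypes, two-sided Wilcoxon rank sum
  for two groups (exact when the smaller group has ≤ 20 samples and no
  ties), with a caller-supplied Bonferroni divisor for the significance
  flag.

## Numerical and design notes

* Symmetric eigenproblems use `eigh`; covariance matrices are
  symmetrised (`(C + Cᵀ)/2`) before decomposition; eigenvalues are clipped
  at zero.
* The joint diagonaliser validates symmetry (asymmetry > 1e-8 is an
  error) and skips pairs whose optimal angle is below tolerance.
* TSV is the interchange format (features × samples, header = sample ids),
  gzip transparent, numeric output at 17 significant digits so files
  round-trip exactly.  Missing values are a hard error: the tensor methods
  require complete data and no imputation is offered.
* BED annotations use standard 0-based half-open coordinates; coordinates
  are carried as metadata and unused by the statistics.
* The CLI (`simulate`, `decompose`, `enrich`, `associate`, `benchmark`)
  exits 0/1/2 for success/data error/usage error, logs to stderr, and
  writes the resolved configuration next to its outputs.

## Known limitations

* FOBI's distinct-kurtosis-sum identifiability condition (above): for
  sources with matching fourth moments, use tWJADE.
* Sequential whitening leaves the first-whitened mode white only to
  `O(1/√p)`; applications with very few features per component should
  prefer the sample mode as the last-whitened (default) mode.
* The Marchenko–Pastur dimension rule has a ~10% one-extra-component
  false-positive rate at 1000 observations; it estimates dimension, not
  significance of individual components.
* Comparison decompositions (JIVE, PARAFAC, iCluster, CCA/sCCA) are not
  implemented; the benchmark accepts them through the adapter interface.
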