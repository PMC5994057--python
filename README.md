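# tensorica

Tensorial PCA and tensorial ICA (tWFOBI / tWJADE) for multi-omic data
tensors, with a simulation benchmark and the downstream inference used to
interpret components (kurtosis ranking, feature selection, enrichment
testing, sensitivity summaries, cell-type-specificity calls and phenotype
association).

## The problem

Modern epigenomics studies increasingly measure the *same* features on the
*same* samples across several data or tissue types — DNA methylation in
matched blood and buccal samples, methylation across purified blood-cell
subtypes, or matched copy-number / methylation / expression profiles of
tumours.  Such data form an order-3 tensor `X` of dimension
`p1 × p2 × p` (data type × sample × feature), and the scientific question
is which latent sources of variation drive it jointly across data types:
smoking exposure, methylation quantitative trait loci (mQTLs), copy-number
dosage effects.

Matrix factorisations applied to each data type separately ignore the
shared structure; PCA-style tensor factorisations only decorrelate.
Because biological sources of variation are typically non-Gaussian and
sparse (a source touches a small fraction of CpGs or genes), demanding
**statistical independence** of the sources — tensorial ICA — separates
them better and makes them easier to interpret.

## The model

The features are treated as `p` i.i.d. realisations of a `p1 × p2` random
matrix.  Tensorial PCA eigendecomposes the two mode covariance matrices

    (X ⊙₋ₘ X) = Ωₘ Λₘ Ωₘᵀ,   m = 1, 2

and writes `X = S ⊙₁ Ω₁ ⊙₂ Ω₂` with the slices of `S` uncorrelated.  The
number of components worth keeping in the sample mode is estimated by
random-matrix theory: eigenvalues of the sample correlation matrix above
the Marchenko–Pastur upper edge `(1 + √(n_var/n_obs))²` count as signal.

Tensorial ICA strengthens decorrelation to independence: the tICA model is
`X = S ⊙₁ Ω₁ ⊙₂ Ω₂` with slices `S[k1, k2, ·]` mutually independent,
zero-mean and unit-variance.  After tPCA whitening, one orthogonal
rotation per mode remains, estimated from fourth-order statistics:

* **tWFOBI** — eigendecomposition of the matricised quartic moment
  `Bₘ = mean_i [Mᵢ Mᵢᵀ Mᵢ Mᵢᵀ]` over the per-feature mode-`m` flattenings
  (the tensor generalisation of fourth-order blind identification);
* **tWJADE** — joint approximate diagonalisation (Jacobi rotations) of all
  `d(d+1)/2` fourth-cumulant matrices of the pooled mode-`m` fibers.

Components are ranked by excess kurtosis `κ = m₄/m₂² − 3`, which is 0 for
Gaussian noise and large for the sparse, heavy-tailed sources of real omic
data.  Feature weights of a component are interpreted through top-`k`
selection, Fisher / binomial enrichment against annotation categories, and
a quantile rule that calls a feature's effect cell-type independent (top
decile of |weight| in every cell type) or cell-type specific (below the
median in one or two cell types, top decile in at least one).

## Worked example

```python
import tensorica as tn

data = tn.simulate_multiomic(tn.SimulationConfig(seed=7, sigma=2.0))
model = tn.twjade(data.tensor, dims=(2, 6))
se, sp = tn.evaluate_sesp_tensorial(model, data)
print(tn.rank_components(model).head(4).to_string(index=False))
print(f"best-component SE = {se:.2f}, SP = {sp:.3f}")
```

```
 rank  component  mode1_index mode1_label  kurtosis  max_kurtosis
    1          0            0       type1  7.664537      7.664537
    1          0            1       type2  6.986609      7.664537
    2          1            0       type1  3.145312      3.145312
    2          1            1       type2  0.131132      3.145312
best-component SE = 1.00, SP = 1.000
```

The simulator plants one source of joint variation (100 genes, 50 per data
type, shared across 20 samples) and one source of individual variation per
data type inside a 2 × 100 × 1000 noise tensor at signal-to-noise 3/σ.
tWJADE's top-ranked component (kurtosis ≈ 7.7 in both data types — far
from the Gaussian value 0) is the joint source: selecting the 50
largest-|weight| genes per data type recovers the planted drivers with
sensitivity 1.00 and specificity 1.000 at noise level σ = 2.

The same pipeline is available from the shell:

```sh
tensorica simulate --seed 7 --sigma 2 --out-dir sim/
tensorica decompose --method twjade --dims 2,6 \
    --matrix type1=sim/type1.tsv --matrix type2=sim/type2.tsv --out-dir fit/
tensorica enrich --weights fit/weights_type1.tsv --category jv_genes.txt \
    -k 50 --out enrichment.tsv
```

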