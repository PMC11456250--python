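# ziptf

Bayesian non-negative CP tensor factorization for zero-inflated count data,
with a consensus meta-analysis that stabilizes the stochastic factorization —
built for multi-sample, multi-condition single-cell RNA-seq.

## Why

Pseudobulk analysis of multi-sample scRNA-seq naturally produces a 3-way
count tensor (samples × cell types × genes).  Classical tensor factorization
assumes Gaussian noise and struggles with the excess zeros that dropout and
low capture efficiency put into single-cell counts, and any stochastic
factorization returns different factors on every run.  `ziptf` addresses
both problems:

- **Zero-inflated Poisson tensor factorization (ZIPTF).**  Each tensor entry
  is modeled as a mixture of a point mass at zero (probability *p* of
  "extra" zeros) and a Poisson whose mean is the CP reconstruction
  λ_I = Σ_r a⁽¹⁾_{i₁r} a⁽²⁾_{i₂r} ⋯ a⁽ᴺ⁾_{i_Nr}, with entrywise
  Gamma(α⁽ᵏ⁾, β⁽ᵏ⁾) priors on the non-negative factors and a logit-normal
  prior on the gate *p*.  The posterior is approximated by a fully
  factorized mean-field family (Gamma per factor entry) optimized by
  stochastic variational inference with Monte-Carlo pathwise gradients.
  Gamma-Poisson and truncated-Gaussian observation models are available
  under the same interface, and a closed-form coordinate-ascent (CAVI)
  solver for the Gamma-Poisson model serves as a deterministic reference.
- **Consensus factorization (C-ZIPTF).**  Run the factorization M times with
  different seeds, aggregate the Frobenius-normalized factor matrices of the
  mode of interest, K-means-cluster their columns (K = R) with Local Outlier
  Factor pruning, take entrywise cluster medians, and refit with the median
  matrix as the initial guess.  Rank selection combines explained variance
  (1 − ‖X − X̃‖_F / ‖X‖_F), the cophenetic correlation of the max-loading
  gene partition across runs, and the silhouette of the column clustering.

The package also ships the surrounding pipeline: pseudobulk tensor
construction from annotated cell × gene counts (with the standard gene /
rare-group filters and per-fiber CPM normalization), factor-to-program
recovery scoring, and two synthetic-data generators (known-rank ZIP tensors,
and Splatter-style multi-donor scRNA-seq counts with embedded identity and
activity gene expression programs) that make every stage testable offline.

## Worked example

```python
from ziptf import ModelSpec, explained_variance, fit, reconstruct, simulate_zip_tensor

sim = simulate_zip_tensor(shape=(8, 10, 60), rank=3, phi=0.6, seed=42)
for model in ("zip", "gamma_poisson"):
    res = fit(sim.tensor, ModelSpec(model, rank=3), max_iter=800, seed=1)
    ev = explained_variance(sim.mean_tensor.data,
                            reconstruct(res.point_estimate).data, squared=True)
    print(model, round(ev, 3))
```

prints (values from this exact script, `examples/01_zip_tensor_factorization.py`):

```
tensor (8, 10, 60), zero fraction 0.59 (excess-zero probability 0.6)
           zip: explained variance vs ground truth = 0.996
 gamma_poisson: explained variance vs ground truth = 0.630
```

With 60% of entries zeroed at random, the ZIP fit still explains ~99% of
the ground-truth mean tensor's variance because the gate absorbs the excess
zeros, while the Poisson fit shrinks its reconstruction toward
(1 − 0.6) × truth, leaving 1 − 0.6² ≈ 0.64 of the variance explained; the
gap widens further as the excess-zero probability grows.  The other example scripts walk
through pseudobulk program recovery (`examples/02_pseudobulk_recovery.py`)
and consensus aggregation with rank selection
(`examples/03_consensus_and_rank_selection.py`).

A thin CLI mirrors the library for batch use:

```bash
ziptf simulate-sc  --seed 1 --out sim/
ziptf pseudobulk   --seed 1 --out pb/  --counts-dir sim/ --cell-meta sim/cell_meta.tsv
ziptf consensus    --seed 1 --out fit/ --tensor pb/tensor --rank 8 --restarts 10
ziptf rank-scan    --seed 1 --out scan/ --tensor pb/tensor --ranks 2-14
ziptf evaluate     --seed 1 --out ev/  --factors fit/factors --truth sim/gep_truth.tsv
```

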