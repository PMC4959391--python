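# o2pls

Two-way Orthogonal PLS (O2PLS) for symmetric integration of two omics data
matrices, with component selection, explained-variation statistics, a
calibrated generative simulator for loading-recovery studies, and the usual
metabolomics/transcriptomics preprocessing chain.

## The problem and the model

Given two blocks measured on the same N samples — say a metabolite panel
X (N×p) and an expression matrix Y (N×q) — one wants to know which
variation is *shared* between the blocks, which is *systematic but
block-specific*, and which is noise. Plain two-block PLS mixes the first
two; O2PLS separates them:

```
X = T Wᵀ + T_Y⊥ P_Y⊥ᵀ + E
Y = U Cᵀ + U_X⊥ P_X⊥ᵀ + F
U = T B_T + H,   T = U B_U + H̃        (inner relations)
```

* **Joint part** — `a` latent components shared by the blocks. W, C are the
  leading singular vectors of the cross-product XᵀY: the directions
  maximizing the covariance between the block scores t = Xw and u = Yc.
* **Orthogonal part** — `n_x` (resp. `n_y`) components of systematic
  variation unique to one block, extracted as the leading left-singular
  vectors of the residual–score cross-product E₀ᵀT (resp. F₀ᵀU) and
  deflated before the joint part is re-estimated.
* **Noise** — E, F, and the inner-relation residual H.

The inner relations give two-way prediction: Ŷ = X_filtered · W B_T Cᵀ,
where "filtered" means the new samples' block-specific variation is removed
first — the reason to model it at all.

Component numbers are chosen by a two-stage procedure: at fixed `a`, pick
(n_x, n_y) on a grid maximizing the sum of the two inner-relation R²
values; then pick `a` by 10-fold cross-validated two-way prediction error.

The simulator draws data from the factor model above with normal-density
loading profiles over the variable index and noise variances calibrated so
noise accounts for an exact target fraction α of each block's expected sum
of squares. Replicate studies (`run_study`) summarize bias and spread of
the sign-corrected loading estimates.

## A worked example

```python
from o2pls import (fit_o2pls, low_dimensional_design, simulate_dataset,
                   variance_decomposition)

design = low_dimensional_design(alpha=0.05)   # N=500, p=100, q=50
data, truth = simulate_dataset(design, seed=1)
centered = data.center()
model = fit_o2pls(centered, a=1, n_x=1, n_y=1)
vd = variance_decomposition(model, centered)
print(f"R2X = {vd.r2x:.4f}, R2Y = {vd.r2y:.4f}, R2Yhat = {vd.r2y_hat:.4f}")
```

prints

```
R2X = 0.9503, R2Y = 0.9473, R2Yhat = 0.6835
```

With 5% simulated noise the model explains ~95% of each block; 68% of Y's
total variation is predictable from X through the inner relation (most of
the joint part of Y, R2Yhat/R2Ycorr ≈ 0.94). The `examples/` directory has
one short script per capability: fitting and variance decomposition,
component selection, the replicate loading-recovery study, and the
preprocessing chain (Box-Cox λ=1/4, mean centering, expression level × IQR
filtering, sample alignment, Pearson correlations).

A thin command-line interface wraps the same functions:

```
o2pls fit --x x.tsv --y y.tsv --a 1 --nx 1 --ny 1 --out model/
o2pls predict --model model/ --x xnew.tsv --direction x_to_y --out yhat.tsv
o2pls cv --x x.tsv --y y.tsv --a 1:5 --folds 10 --seed 0 --out cv.json
o2pls decompose --model model/ --x x.tsv --y y.tsv --out variance.tsv
o2pls simulate --design low --alpha 0.05 --replicates 100 --seed 0 --out study/
o2pls preprocess --in metab.tsv --out prep.tsv --boxcox 0.25 --center
```

Matrices travel as TSV/CSV with variable ids in the header row and sample
ids in the first column; every run writes a JSON manifest with input
digests, seed and version.

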