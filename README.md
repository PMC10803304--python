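# connectocca

Multivariate brain–behavior association analysis for functional
connectomics: ridge-regularized canonical correlation analysis (rCCA)
linking vectorized functional-connectome edges to a battery of behavioral
scores, with permutation-based mode significance, network-level
interpretation of canonical loadings, and nested cross-validated SVM
prediction of mode scores.

## The problem

Resting-state fMRI yields, per subject, a node × node matrix of Fisher-z
transformed Pearson correlations between regional time series — the
functional connectome. Psychological batteries yield a vector of
questionnaire totals per subject. Mass-univariate edge-by-score testing
ignores the interdependence on both sides; canonical correlation analysis
instead finds paired linear combinations ("covariation modes") of edges
and scores that are maximally correlated. With far more edges than
subjects the within-block covariances are singular, so ridge penalties
λ₁, λ₂ are added to their diagonals:

    S_xx = XᵀX/(n−1) + λ₁I,  S_yy = YᵀY/(n−1) + λ₂I,  S_xy = XᵀY/(n−1)

The modes are the SVD of the whitened cross-covariance
S_xx^(−1/2) S_xy S_yy^(−1/2) = U D Vᵀ, with weights aₖ = S_xx^(−1/2)uₖ,
bₖ = S_yy^(−1/2)vₖ, canonical correlations dₖ = Dₖₖ, and variates
ξₖ = Xaₖ, ωₖ = Ybₖ. Penalties are tuned by cross-validated grid search on
the held-out first-variate correlation; mode significance comes from
row-shuffle permutations with Benjamini–Hochberg FDR across modes; modes
are interpreted through canonical loadings (Pearson r between each
variable and its own block's variate) aggregated into network and node
strengths over a node → community table; and each retained mode's score is
predicted out-of-sample by a leakage-safe nested-CV linear support-vector
regression.

Because cohort data of this kind are rarely shareable, the package ships a
first-class synthetic-data generator that plants latent modes with known
canonical correlations, block-sparse edge loadings confined to named
community pairs, and linear age/sex/motion confound effects — every
downstream stage can be validated against recoverable ground truth.

## Worked example

```python
import numpy as np
from connectocca import (
    SyntheticSpec, generate_dataset, regress_confounds, standardize,
    RCCA, tune_lambdas,
)
from connectocca.inference import evaluate_modes

ds = generate_dataset(SyntheticSpec(n_subjects=400, n_nodes=40, seed=0))
X, _ = standardize(regress_confounds(ds.edge_features, ds.covariates))
Y, _ = standardize(ds.behaviors)

tuning = tune_lambdas(X, Y, grid_len=10, seed=0)
res = RCCA(X, Y).fit(*tuning.best_pair)
print(res.summary(max_modes=3))

modes = evaluate_modes(res, edge_index=ds.edge_index, n_perms=499, seed=1)
for m in modes:
    if m.selected:
        top = max(m.network_summary.pair_strength.items(), key=lambda t: t[1])
        print(f"mode {m.mode_id}: p={m.p_value:.3f} q={m.q_value:.3f} "
              f"top pair={top[0]} strength={top[1]:.2f}")
```

prints

```
Regularized Canonical Correlation Analysis
==========================================================
n subjects:   400    p (brain):   780    q (behavior):   17
lambda_x: 0.99    lambda_y: 0.8811
----------------------------------------------------------
mode      d_k  r(xi,omega)  cov. frac.
   0   0.8452       0.9797      0.1527
   1   0.7439       0.9675      0.1183
   2   0.5539       0.9551      0.0656
  ... 14 further modes
==========================================================
mode 0: p=0.002 q=0.017 top pair=('DAN', 'DMN') strength=15.97
mode 1: p=0.002 q=0.017 top pair=('AFN', 'VN') strength=9.96
```

The two planted modes (true canonical correlations 0.9 and 0.75, edge
loadings confined to the default-mode/dorsal-attention and
affective/visual community pairs) are the only ones surviving the
permutation-FDR and covariance-explained gates, and each mode's strongest
community pair is its planted block. dₖ is the regularized canonical
correlation; r(ξ,ω) is the plain Pearson correlation of the paired
variates; "cov. frac." is dₖ²/Σdⱼ².

The same workflow is available from the shell:

```bash
connectocca simulate --config spec.yaml --out data/
connectocca analyze  --config pipeline.yaml
connectocca predict  --config pipeline.yaml
```

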