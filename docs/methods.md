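# Methods

## Model

Given a brain block X (subjects × p standardized edge features) and a
behavior block Y (subjects × q standardized questionnaire totals),
ridge-regularized canonical correlation analysis (rCCA) solves the SVD of
the whitened cross-covariance

S_xx^(−1/2) · S_xy · S_yy^(−1/2) = U D Vᵀ,  with
S_xx = XᵀX/(n−1) + λ_x I,  S_yy = YᵀY/(n−1) + λ_y I,  S_xy = XᵀY/(n−1).

Weights are a_k = S_xx^(−1/2)u_k and b_k = S_yy^(−1/2)v_k (so
a_kᵀ(S_xx+λ_xI)a_k = 1), canonical correlations are the singular values
d_k clipped to [0, 1], and variates are ξ_k = Xa_k, ω_k = Yb_k. The model
centers its inputs defensively but expects standardized columns, which the
pipeline produces (sample sd, denominator n−1).

Two implementation facts carry the whole computational budget: the
penalized within-block matrices share eigenvectors with the unpenalized
ones for every λ, and row permutations of X leave S_xx and S_yy
unchanged. The within-block eigendecompositions are therefore computed
once and reused across the entire penalty grid and across thousands of
permutations; each new (λ_x, λ_y) or permutation costs only a rescaling
of the rotated cross-covariance plus a thin SVD. Inverse square roots use
a symmetric eigendecomposition with eigenvalues floored at 0 and the
penalized spectrum floored at 1e−12.

Signs of (a_k, b_k) are jointly flipped so the behavioral variable with
the largest-magnitude loading loads positively; CCA signs are otherwise
arbitrary and a fixed rule keeps outputs reproducible.

### Which "canonical correlation" is which

Three related quantities are reported and should not be conflated:

- d_k, the regularized singular value — the inference statistic used for
  permutation testing; shrunk below the population correlation by the
  penalties (for an isotropic single factor, toward
  s²/(s²+σ²+λ)).
- the empirical Pearson correlation of the paired variates — in-sample
  and optimistically biased when p ≫ n;
- the cross-validated first-variate correlation — the held-out quantity
  the penalty tuning maximizes, and the least biased estimate of the
  population canonical correlation. The planted-recovery checks measure
  this one, for that reason, and compare estimated loading vectors (not
  raw weights, whose direction is noisier at high dimension) against the
  planted loadings.

## Penalty tuning

All pairs from linspace(0.01, 0.99, 20)² (400 pairs by default) are scored
by k-fold cross-validation (default 5 folds): weights fit on training
folds, score = mean Pearson correlation of the held-out first-variate
projections. The in-sample first canonical correlation is monotone in the
penalties, so only a held-out criterion makes the grid search meaningful.

## Mode significance and selection

Permutations shuffle the subject rows of the (already residualized) brain
block only, keep Y fixed, refit at the tuned penalties, and use the
add-one estimator p = (1 + #{null ≥ observed})/(1 + B). By default every
mode's observed d_k is compared against the permutation distribution of
the first (largest) canonical correlation: trailing modes' observed
values are themselves in-sample maxima over a residual subspace, so a
same-rank comparison is anti-conservative — in simulation it admitted a
spurious third mode in about one seed in ten, while the max-statistic
reference (the standard choice for permutation inference in CCA) cleanly
separates planted from null modes and leaves the first mode's p value
unchanged. The per-rank comparison remains available (`null="rank"`) for
sensitivity analyses. P values are Benjamini–Hochberg adjusted across all
K = min(p, q) modes; a mode is retained when q < 0.05 and its covariance
fraction d_k²/Σd_j² exceeds 0.05. Note that with K = 17 modes the
smallest attainable q is 17/(B+1) for the top mode, so B must be ≥ 340
for any mode to survive q < 0.05; the pipeline default is B = 5000, and
the desk-scale checks use B = 499.

"Covariance explained" is not given a standard definition in this
literature; the squared-correlation fraction is used because it is
normalized, mode-monotone, and threshold-compatible.

## Interpretation

Canonical loadings are Pearson correlations between each original
variable and its own block's variate (zero-variance variables load 0 with
a warning). Contributing features default to |loading| ≥ 0.2; a bootstrap
rule (sign-stable and above threshold in ≥ 90% of subject-resampled
refits) is available. Network strength sums |loading| over contributing
edges per unordered community pair; node strength sums over edges
incident to each node. Absolute values are used because signed sums
cancel; each edge contributes to exactly one pair and both endpoint
nodes, so pair strengths conserve total |loading| mass exactly. Mode
overlap intersects two modes' contributing edge sets and averages their
strengths over the shared edges. Confound sensitivity refits without
residualization and correlates matched modes' loading vectors (greedy
matching by |r|, signs resolved to maximize |r|); covariate effects
regress each brain variate on age + sex by OLS with BH correction across
modes.

## Synthetic data

The generator emulates the targeted study design: ~100 subjects, a
136-node connectome (9180 edges), 17 questionnaire totals, two planted
modes with true canonical correlations (0.9, 0.75), edge loadings uniform
over the default-mode/dorsal-attention pair (mode 0) and affective/visual
pair (mode 1), disjoint behavior support sets (measures 0–8 and 9–16).
For each mode an i.i.d. standard-normal latent z_k feeds both blocks
through unit-norm loadings at scale s_k, plus isotropic Gaussian noise of
sd σ; since the population canonical correlation of such a factor is
s²/(s²+σ²), the closed form s_k = σ√(ρ_k/(1−ρ_k)) calibrates each mode
exactly when supports are disjoint (overlapping supports make it
approximate). Covariates model a student cohort — age ~ U(18, 28) years,
sex ~ Bernoulli(0.5) coded {0,1}, mean framewise displacement ~ lognormal
with median 0.1 mm — and each covariate adds a slope of
`confound_effect_size` (default 0.3) on its standardized value to a
disjoint 10% slice of edges, recorded in the truth sidecar. A separate
helper draws node time series with a prescribed population correlation
matrix (eigendecomposition coloring of white noise) so the connectome
construction path can be tested end to end.

What the generator does *not* emulate: hemodynamic autocorrelation,
heteroscedastic or non-Gaussian questionnaire marginals, motion artifact
structure, site effects, or edge-variance heterogeneity beyond the
planted signal. Passing tests therefore demonstrate correctness of the
algorithms under the stated statistical model, not performance on real
cohort data. One consequence worth knowing: uniform block loadings spread
signal variance thinly (s²/m per edge for an m-edge block), so
variance-ranked MAD selection at 5% keeps only a small part of the
planted support at 136 nodes; recovery checks therefore run at 40 nodes,
where blocks are small enough for the full edge set to be carried.

## Prediction

The target for a mode is the per-subject sum of z-scored contributing
measures, so it lives on a summed-z scale and MAE is reported on that
scale. Predictors pass through confound regression (age, sex, mean FD),
min-max scaling to [0, 1], and PCA keeping the smallest component count
reaching ≥ 80% cumulative variance — each fit on training subjects only,
per outer fold (the leakage contract is unit-tested by corrupting
held-out rows). The regressor is a linear ε-SVR (continuous targets;
"linear SVM" in the classification sense does not apply) with a capped
dual-coordinate solver budget; hyperparameters are tuned in an inner
10-fold loop by greedy coordinate search — C over {4⁻³…4³} at the grid's
middle ε, then ε over {0.01, 0.1, 0.5} at the best C — with full grid
search available by config. The outer 10-fold loop is repeated (default
10 reshuffles) and the mean over repeats of the pooled out-of-fold
Pearson r and MAE is reported. Label permutations rerun the pipeline with
one outer repeat and the observed fit's modal hyperparameters
(`refit=True` for the exact slow variant), with the add-one p value.

## Problem sizes of the verification suite

The bundled checks run at desk scale by design: oracle equivalence at
n=500, p=5, q=4; planted-mode recovery at n=300, p=200, q=17 over 20
seeds; permutation calibration at n=200, B=99, 200 replicates; two-mode
end-to-end recovery at n=400, 40 nodes, B=499 over 10 seeds; prediction
sanity at n=300 with 459 edges (40 informative) and B=99. The two
count identities (9180 edges from 136 nodes; 459 = top 5% of 9180) run at
full scale, as does the generator itself.

## Known limitations

- The rCCA eigendecomposition is O(p³) once per fit/fold; beyond a few
  thousand selected edges a truncated decomposition would be needed.
- The max-statistic null is conservative for trailing true modes when
  leading modes are very strong (their null reference includes the
  leading modes' chance maxima); this is the price of exact false-positive
  control and matches how the selection gate is used.
- Bootstrap contributor stability refits on resampled subjects at fixed
  penalties; re-tuning per resample would be more honest and far slower.
- Questionnaire totals are modeled as Gaussian; ordinal floor/ceiling
  effects in real instruments will attenuate loadings relative to the
  simulation.
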