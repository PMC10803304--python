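"""Ridge-regularized canonical correlation analysis.

Model
-----
Given standardized blocks X (subjects x p brain edges) and Y (subjects x q
behavioral scores), rCCA seeks weight vectors a_k, b_k maximising the
correlation between the canonical variates xi_k = X a_k and omega_k = Y b_k,
with ridge penalties lambda_x, lambda_y added to the diagonals of the
within-block covariances so they stay invertible when features outnumber
subjects:

    S_xx = X'X/(n-1) + lambda_x I,   S_yy = Y'Y/(n-1) + lambda_y I,
    S_xy = X'Y/(n-1).

The solution is the SVD of the whitened cross-covariance
``S_xx^{-1/2} S_xy S_yy^{-1/2} = U D V'`` with weights
``a_k = S_xx^{-1/2} u_k``, ``b_k = S_yy^{-1/2} v_k``; the singular values
d_k (clipped to [0, 1]) are the regularized canonical correlations.

Because ``S_xx + lambda I`` shares eigenvectors with ``S_xx`` for every
lambda, the within-block eigendecompositions are computed once and reused
across the penalty grid and across row permutations (which leave S_xx and
S_yy unchanged). This is what makes the 20 x 20 grid search and thousands
of permutations cheap.

Usage follows the statsmodels model/results convention::

    model = RCCA(X, Y)
    res = model.fit(lambda_x=0.5, lambda_y=0.5)   # or model.fit() after tune
    res.canonical_correlations, res.weights_x, res.summary()
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

__all__ = ["RCCA", "RCCAResults", "TuningResult", "tune_lambdas", "covariance_explained"]

_EIG_FLOOR = 1e-12


def _center(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=0)


def _eig_sym(S: np.ndarray):
    """Eigendecomposition of a symmetric PSD matrix; eigenvalues floored at 0."""
    vals, vecs = np.linalg.eigh(S)
    return np.maximum(vals, 0.0), vecs


@dataclass
class _WhitenCache:
    """Within-block eigendecompositions and the rotated cross-covariance."""

    evals_x: np.ndarray
    evecs_x: np.ndarray
    evals_y: np.ndarray
    evecs_y: np.ndarray
    # T = Vx' S_xy Vy; rescaling T is all a new (lambda_x, lambda_y) needs
    T: np.ndarray


def _build_cache(Xc: np.ndarray, Yc: np.ndarray) -> _WhitenCache:
    n = len(Xc)
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    ex, Vx = _eig_sym(Sxx)
    ey, Vy = _eig_sym(Syy)
    return _WhitenCache(ex, Vx, ey, Vy, Vx.T @ Sxy @ Vy)


def _solve(cache: _WhitenCache, lambda_x: float, lambda_y: float, T=None):
    """SVD of the whitened cross-covariance at the given penalties.

    Returns (d, A, B): canonical correlations and weight matrices.
    """
    wx = 1.0 / np.sqrt(np.maximum(cache.evals_x + lambda_x, _EIG_FLOOR))
    wy = 1.0 / np.sqrt(np.maximum(cache.evals_y + lambda_y, _EIG_FLOOR))
    M = (wx[:, None] * (cache.T if T is None else T)) * wy[None, :]
    U, d, Vt = np.linalg.svd(M, full_matrices=False)
    A = cache.evecs_x @ (wx[:, None] * U)
    B = cache.evecs_y @ (wy[:, None] * Vt.T)
    return np.clip(d, 0.0, 1.0), A, B


class RCCA:
    """Ridge-regularized CCA model for a brain block X and behavior block Y.

    Parameters
    ----------
    X : ndarray, shape (n_subjects, n_features)
        Brain block; columns are expected standardized (the model centers
        them defensively but does not rescale).
    Y : ndarray, shape (n_subjects, n_behaviors)
        Behavior block, same convention.
    feature_names, behavior_names : sequence of str, optional
        Column labels carried through to results.
    """

    def __init__(self, X, Y, feature_names=None, behavior_names=None):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2:
            raise ValueError("X and Y must be 2-D arrays")
        if len(X) != len(Y):
            raise ValueError("X and Y must have the same number of subjects")
        if len(X) < 3:
            raise ValueError("need at least 3 subjects")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
            raise ValueError("inputs contain non-finite values")
        if X.shape[1] < 1 or Y.shape[1] < 1:
            raise ValueError("each block needs at least one column")
        self.X = X
        self.Y = Y
        self.feature_names = (
            list(feature_names)
            if feature_names is not None
            else [f"x{i}" for i in range(X.shape[1])]
        )
        self.behavior_names = (
            list(behavior_names)
            if behavior_names is not None
            else [f"y{i}" for i in range(Y.shape[1])]
        )
        self._Xc = _center(X)
        self._Yc = _center(Y)
        self._cache: _WhitenCache | None = None

    @property
    def nobs(self) -> int:
        return len(self.X)

    @property
    def k_modes(self) -> int:
        return min(self.X.shape[1], self.Y.shape[1])

    def _get_cache(self) -> _WhitenCache:
        if self._cache is None:
            self._cache = _build_cache(self._Xc, self._Yc)
        return self._cache

    def fit(self, lambda_x: float, lambda_y: float) -> "RCCAResults":
        """Fit at fixed penalties; returns an :class:`RCCAResults`."""
        if lambda_x <= 0 or lambda_y <= 0:
            raise ValueError("ridge penalties must be positive")
        cache = self._get_cache()
        d, A, B = _solve(cache, lambda_x, lambda_y)
        variates_x = self._Xc @ A
        variates_y = self._Yc @ B

        # Sign convention: flip each mode so the behavioral variable whose
        # loading has the largest magnitude loads positively.
        for k in range(d.size):
            omega = variates_y[:, k]
            if omega.std() == 0:
                continue
            loads = _safe_corr_columns(self._Yc, omega)
            j = int(np.argmax(np.abs(loads)))
            if loads[j] < 0:
                A[:, k] *= -1
                B[:, k] *= -1
                variates_x[:, k] *= -1
                variates_y[:, k] *= -1

        emp = np.array(
            [
                _safe_corr(variates_x[:, k], variates_y[:, k])
                for k in range(d.size)
            ]
        )
        return RCCAResults(
            model=self,
            lambda_x=float(lambda_x),
            lambda_y=float(lambda_y),
            weights_x=A,
            weights_y=B,
            canonical_correlations=d,
            variates_x=variates_x,
            variates_y=variates_y,
            empirical_variate_correlations=emp,
        )

    def fit_permuted(self, perm: np.ndarray, lambda_x: float, lambda_y: float):
        """Canonical correlations after permuting the rows of X.

        Row shuffling leaves S_xx and S_yy untouched, so only the rotated
        cross-covariance is recomputed. Returns the vector d.
        """
        cache = self._get_cache()
        n = self.nobs
        Sxy = self._Xc[perm].T @ self._Yc / (n - 1)
        T = cache.evecs_x.T @ Sxy @ cache.evecs_y
        d, _, _ = _solve(cache, lambda_x, lambda_y, T=T)
        return d

    def tune(self, **kwargs) -> "TuningResult":
        """Grid-search the penalty pair; see :func:`tune_lambdas`."""
        return tune_lambdas(self.X, self.Y, **kwargs)


def _safe_corr(u: np.ndarray, v: np.ndarray) -> float:
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        return 0.0
    return float(np.corrcoef(u, v)[0, 1])


def _safe_corr_columns(Zc: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson r of each (centered) column of Zc with vector v; 0 if degenerate."""
    vc = v - v.mean()
    sv = np.sqrt(vc @ vc)
    sz = np.sqrt(np.sum(Zc**2, axis=0))
    denom = sz * sv
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Zc.T @ vc / np.where(denom > 0, denom, 1.0), 0.0)
    return r


@dataclass
class RCCAResults:
    """Fitted rCCA: weights, canonical correlations, variates.

    ``canonical_correlations`` are the regularized singular values d_k
    (the inference statistic); ``empirical_variate_correlations`` are the
    plain Pearson correlations of the paired variates, reported alongside
    because both are in common use.
    """

    model: RCCA
    lambda_x: float
    lambda_y: float
    weights_x: np.ndarray
    weights_y: np.ndarray
    canonical_correlations: np.ndarray
    variates_x: np.ndarray
    variates_y: np.ndarray
    empirical_variate_correlations: np.ndarray

    @property
    def k_modes(self) -> int:
        return self.canonical_correlations.size

    def covariance_explained(self) -> np.ndarray:
        """Fraction of total squared canonical correlation per mode."""
        return covariance_explained(self.canonical_correlations)

    def loadings(self):
        """Canonical loadings: r(variable, own-block variate) per mode.

        Returns ``(brain, behavior)`` arrays of shape (p, K) and (q, K).
        """
        brain = np.column_stack(
            [
                _safe_corr_columns(self.model._Xc, self.variates_x[:, k])
                for k in range(self.k_modes)
            ]
        )
        behavior = np.column_stack(
            [
                _safe_corr_columns(self.model._Yc, self.variates_y[:, k])
                for k in range(self.k_modes)
            ]
        )
        return brain, behavior

    def permutation_test(self, n_perms: int = 5000, seed=None):
        """Row-shuffle permutation test; see ``inference.permutation_test``."""
        from .inference import permutation_test

        return permutation_test(
            self.model.X,
            self.model.Y,
            self.lambda_x,
            self.lambda_y,
            n_perms=n_perms,
            seed=seed,
            model=self.model,
            observed=self.canonical_correlations,
        )

    def summary(self, max_modes: int = 10) -> str:
        frac = self.covariance_explained()
        lines = [
            "Regularized Canonical Correlation Analysis",
            "=" * 58,
            f"n subjects: {self.model.nobs:>5d}    "
            f"p (brain): {self.model.X.shape[1]:>5d}    "
            f"q (behavior): {self.model.Y.shape[1]:>4d}",
            f"lambda_x: {self.lambda_x:.4g}    lambda_y: {self.lambda_y:.4g}",
            "-" * 58,
            f"{'mode':>4} {'d_k':>8} {'r(xi,omega)':>12} {'cov. frac.':>11}",
        ]
        for k in range(min(self.k_modes, max_modes)):
            lines.append(
                f"{k:>4} {self.canonical_correlations[k]:>8.4f} "
                f"{self.empirical_variate_correlations[k]:>12.4f} "
                f"{frac[k]:>11.4f}"
            )
        if self.k_modes > max_modes:
            lines.append(f"  ... {self.k_modes - max_modes} further modes")
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot_variates(self, mode: int = 0, ax=None):
        """Scatter of paired canonical variates for one mode."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.variates_x[:, mode], self.variates_y[:, mode], s=12)
        ax.set_xlabel(f"brain variate {mode}")
        ax.set_ylabel(f"behavior variate {mode}")
        r = self.empirical_variate_correlations[mode]
        ax.set_title(f"mode {mode}: r = {r:.3f}")
        return ax

    def to_json(self, path) -> None:
        payload = {
            "lambda_x": self.lambda_x,
            "lambda_y": self.lambda_y,
            "canonical_correlations": self.canonical_correlations.tolist(),
            "empirical_variate_correlations": self.empirical_variate_correlations.tolist(),
            "covariance_explained": self.covariance_explained().tolist(),
            "weights_x": self.weights_x.tolist(),
            "weights_y": self.weights_y.tolist(),
            "feature_names": self.model.feature_names,
            "behavior_names": self.model.behavior_names,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def covariance_explained(canonical_correlations: np.ndarray) -> np.ndarray:
    """Per-mode fraction d_k^2 / sum_j d_j^2 (sums to 1, non-increasing)."""
    d = np.asarray(canonical_correlations, dtype=float)
    total = np.sum(d**2)
    if total == 0:
        raise ValueError("all canonical correlations are zero; nothing to apportion")
    return d**2 / total


@dataclass
class TuningResult:
    """Cross-validated grid search over the penalty pair."""

    grid: list = field(repr=False)
    cv_scores: np.ndarray = field(repr=False)
    best_pair: tuple = (np.nan, np.nan)

    @property
    def best_score(self) -> float:
        return float(np.max(self.cv_scores))


def tune_lambdas(
    X,
    Y,
    grid_min: float = 0.01,
    grid_max: float = 0.99,
    grid_len: int = 20,
    n_folds: int = 5,
    seed=None,
) -> TuningResult:
    """Pick (lambda_x, lambda_y) maximising the held-out first-mode correlation.

    All ``grid_len**2`` pairs from ``linspace(grid_min, grid_max, grid_len)``
    squared are scored by k-fold cross-validation: weights are fit on the
    training folds and the score is the mean Pearson correlation between
    the first-variate projections of the held-out subjects. The in-sample
    first canonical correlation is monotone in the penalties, so held-out
    correlation is the criterion that makes the grid search meaningful.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if grid_len < 1:
        raise ValueError("grid_len must be >= 1")
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if len(X) < 2 * n_folds:
        raise ValueError("too few subjects for the requested folds")
    lams = np.linspace(grid_min, grid_max, grid_len)
    grid = [(float(lx), float(ly)) for lx in lams for ly in lams]
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=_as_int_seed(seed))
    fold_scores = np.zeros((n_folds, len(grid)))
    for f, (tr, te) in enumerate(kf.split(X)):
        Xtr, Ytr = X[tr], Y[tr]
        mx, my = Xtr.mean(axis=0), Ytr.mean(axis=0)
        cache = _build_cache(Xtr - mx, Ytr - my)
        Xte, Yte = X[te] - mx, Y[te] - my
        for g, (lx, ly) in enumerate(grid):
            _, A, B = _solve(cache, lx, ly)
            fold_scores[f, g] = _safe_corr(Xte @ A[:, 0], Yte @ B[:, 0])
    scores = fold_scores.mean(axis=0)
    best = grid[int(np.argmax(scores))]
    return TuningResult(grid=grid, cv_scores=scores, best_pair=best)


def _as_int_seed(seed) -> int:
    """Map any seed-like input to a deterministic int for sklearn splitters."""
    if seed is None:
        return 0
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1)[0] % (2**31 - 1))
    return int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1))
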