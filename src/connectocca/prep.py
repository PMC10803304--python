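"""Feature preparation: confound removal, MAD edge selection, scaling.

The preparation order used by the pipeline is residualize -> MAD-select ->
standardize. Confound regression removes linear effects of age, sex and
mean framewise displacement from every edge; MAD selection keeps the
fraction of edges with the largest median absolute deviation across
subjects; standardization brings the surviving columns to mean 0, sd 1
(sample sd, denominator n-1) so covariances are correlations downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfoundRegressor",
    "Standardizer",
    "regress_confounds",
    "mad_select",
    "standardize",
]

CONFOUND_COLUMNS = ("age", "sex", "mean_fd")


def _design_matrix(cov: pd.DataFrame, columns=CONFOUND_COLUMNS) -> np.ndarray:
    missing = set(columns) - set(cov.columns)
    if missing:
        raise ValueError(f"covariates table missing columns {sorted(missing)}")
    X = cov.loc[:, list(columns)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates contain non-finite values")
    design = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "confound design matrix is rank deficient; remove a collinear "
            "covariate (e.g. a constant column)"
        )
    return design


@dataclass
class ConfoundRegressor:
    """Least-squares residualization of features on intercept + covariates.

    Fitting stores the regression coefficients so the identical transform
    can be applied to held-out subjects (required by the nested-CV
    prediction pipeline's leakage contract).
    """

    columns: tuple = CONFOUND_COLUMNS
    coef_: np.ndarray | None = None

    def fit(self, features: np.ndarray, cov: pd.DataFrame) -> "ConfoundRegressor":
        X = np.asarray(features, dtype=float)
        design = _design_matrix(cov, self.columns)
        if len(X) != len(design):
            raise ValueError("features and covariates have different row counts")
        self.coef_, *_ = np.linalg.lstsq(design, X, rcond=None)
        return self

    def transform(self, features: np.ndarray, cov: pd.DataFrame) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("ConfoundRegressor is not fitted")
        X = np.asarray(features, dtype=float)
        design = _design_matrix(cov, self.columns)
        return X - design @ self.coef_

    def fit_transform(self, features, cov) -> np.ndarray:
        return self.fit(features, cov).transform(features, cov)


def regress_confounds(
    features: np.ndarray, cov: pd.DataFrame, columns=CONFOUND_COLUMNS
) -> np.ndarray:
    """Residualize each feature column on intercept + age + sex + mean FD.

    Residuals are orthogonal to every covariate column (within numerical
    tolerance) and the operation is idempotent.
    """
    return ConfoundRegressor(columns=columns).fit_transform(features, cov)


def mad_select(features: np.ndarray, fraction: float = 0.05):
    """Select the top fraction of features by median absolute deviation.

    MAD is the raw ``median |x - median(x)|`` per column (no normal
    consistency factor; only the ranking matters). The number kept is
    ``fraction * n_features`` rounded half-up, with MAD ties broken in
    favour of the lower feature id.

    Returns
    -------
    (ndarray, float)
        Selected feature ids in ascending (original) order, and the
        smallest MAD among the selected features.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D table with at least 2 subjects")
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    p = X.shape[1]
    k = int(np.floor(fraction * p + 0.5))  # round half up
    k = max(k, 1)
    # sort by descending MAD, ties by ascending feature id
    order = np.lexsort((np.arange(p), -mad))
    chosen = np.sort(order[:k])
    return chosen, float(mad[order[k - 1]])


@dataclass
class Standardizer:
    """Column-wise z-scoring with stored mean/sd (sample sd, ddof=1)."""

    mean_: np.ndarray | None = None
    sd_: np.ndarray | None = None

    def fit(self, features: np.ndarray) -> "Standardizer":
        X = np.asarray(features, dtype=float)
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(self.sd_ == 0)
        if zero.size:
            raise ValueError(
                f"zero-variance column(s) {zero.tolist()} cannot be standardized"
            )
        return self

    def transform(self, features: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Standardizer is not fitted")
        return (np.asarray(features, dtype=float) - self.mean_) / self.sd_

    def fit_transform(self, features) -> np.ndarray:
        return self.fit(features).transform(features)


def standardize(features: np.ndarray):
    """Z-score columns; returns ``(standardized, Standardizer)``."""
    scaler = Standardizer()
    return scaler.fit_transform(features), scaler
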