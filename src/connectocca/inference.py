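"""Mode significance, loadings, and network-level interpretation.

Significance of each covariation mode is assessed by shuffling the subject
rows of the brain block (behavior fixed), refitting the rCCA at the tuned
penalties, and comparing each mode's canonical correlation against the
null distribution of the same rank. P values are corrected across modes by
Benjamini-Hochberg FDR, and a mode is retained when q < alpha and it
explains more than a threshold fraction of the covariance.

Interpretation works on canonical loadings (Pearson r between each
original variable and its own block's variate). Edges whose |loading|
passes a stability rule are aggregated into network strength (summed
|loading| per community pair) and node strength (summed |loading| over
incident edges).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .connectome import EdgeIndex
from .rcca import RCCA, RCCAResults, _safe_corr_columns, covariance_explained

__all__ = [
    "PermutationTest",
    "ModeResult",
    "NetworkSummary",
    "permutation_test",
    "bh_fdr",
    "select_modes",
    "canonical_loadings",
    "stable_contributors",
    "bootstrap_contributors",
    "network_strength",
    "mode_overlap",
    "sensitivity_compare",
    "covariate_effects",
    "evaluate_modes",
]


@dataclass
class PermutationTest:
    """Null distribution and per-mode p values from row-shuffle permutations."""

    observed: np.ndarray
    null: np.ndarray  # (n_perms, K)
    p_values: np.ndarray
    n_perms: int


def permutation_test(
    X,
    Y,
    lambda_x: float,
    lambda_y: float,
    n_perms: int = 5000,
    seed=None,
    model: RCCA | None = None,
    observed: np.ndarray | None = None,
    null: str = "max",
) -> PermutationTest:
    """Row-shuffle permutation test of the canonical correlations.

    Each permutation shuffles the subject rows of X only, keeping Y fixed,
    and refits at the same tuned penalties. P values use the add-one
    estimator ``p = (1 + #{null >= observed}) / (1 + B)``.

    ``null="max"`` (default) compares every mode's observed correlation
    against the permutation distribution of the FIRST (largest) canonical
    correlation. Trailing modes' observed values are themselves in-sample
    maxima over the residual subspace, so comparing them to same-rank null
    values is anti-conservative; the max-statistic reference is the
    standard remedy for permutation inference in CCA. ``null="rank"``
    gives the per-rank comparison for sensitivity analyses.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    if null not in ("max", "rank"):
        raise ValueError("null must be 'max' or 'rank'")
    if model is None:
        model = RCCA(X, Y)
    if observed is None:
        observed = model.fit(lambda_x, lambda_y).canonical_correlations
    rng = np.random.default_rng(seed)
    n = model.nobs
    K = observed.size
    null_d = np.empty((n_perms, K))
    for b in range(n_perms):
        perm = rng.permutation(n)
        null_d[b] = model.fit_permuted(perm, lambda_x, lambda_y)
    if null == "max":
        exceed = (null_d[:, [0]] >= observed[None, :]).sum(axis=0)
    else:
        exceed = (null_d >= observed[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perms)
    return PermutationTest(observed=observed, null=null_d, p_values=p, n_perms=n_perms)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_modes(
    q_values, covariance_fractions, alpha: float = 0.05, cov_threshold: float = 0.05
) -> np.ndarray:
    """Mode ids with FDR q < alpha AND covariance fraction > cov_threshold."""
    q = np.asarray(q_values, dtype=float)
    frac = np.asarray(covariance_fractions, dtype=float)
    return np.flatnonzero((q < alpha) & (frac > cov_threshold))


def canonical_loadings(results: RCCAResults):
    """Per-mode loadings: r(variable, own-block variate). See RCCAResults.loadings."""
    brain, behavior = results.loadings()
    if np.any(results.model._Xc.std(axis=0) == 0) or np.any(
        results.model._Yc.std(axis=0) == 0
    ):
        warnings.warn("zero-variance variable(s): loadings reported as 0")
    return brain, behavior


def stable_contributors(loadings, threshold: float = 0.2) -> np.ndarray:
    """Ids of variables with |loading| >= threshold (the default stability rule)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    loadings = np.asarray(loadings, dtype=float)
    return np.flatnonzero(np.abs(loadings) >= threshold)


def bootstrap_contributors(
    X,
    Y,
    lambda_x: float,
    lambda_y: float,
    mode: int = 0,
    block: str = "brain",
    threshold: float = 0.2,
    retain_frac: float = 0.9,
    n_boot: int = 1000,
    seed=None,
) -> np.ndarray:
    """Bootstrap stability rule: keep variables whose loading keeps its sign
    and stays above threshold in >= retain_frac of subject-resampled refits.

    Mode matching across resamples is by sign-resolved similarity of the
    loading vector to the full-sample one.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = len(X)
    full = RCCA(X, Y).fit(lambda_x, lambda_y)
    ref = full.loadings()[0 if block == "brain" else 1][:, mode]
    ref_sign = np.sign(ref)
    ok = np.zeros(ref.size)
    done = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if np.unique(idx).size < 3:
            continue
        try:
            res = RCCA(X[idx], Y[idx]).fit(lambda_x, lambda_y)
        except ValueError:
            continue
        lb, lbeh = res.loadings()
        L = lb if block == "brain" else lbeh
        # match to the reference mode by absolute loading similarity
        sims = np.abs(ref @ L[:, : full.k_modes])
        k = int(np.argmax(sims))
        vec = L[:, k]
        if ref @ vec < 0:
            vec = -vec
        ok += (np.sign(vec) == ref_sign) & (np.abs(vec) >= threshold)
        done += 1
    if done == 0:
        raise RuntimeError("no successful bootstrap refits")
    return np.flatnonzero(ok / done >= retain_frac)


@dataclass
class NetworkSummary:
    """Aggregated |loading| strengths per community pair and per node."""

    pair_strength: dict
    node_strength: dict
    top_nodes: list

    @property
    def total_strength(self) -> float:
        return float(sum(self.pair_strength.values()))

    def pair_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(
                ((f"{a}-{b}", s) for (a, b), s in self.pair_strength.items()),
                key=lambda t: -t[1],
            ),
            columns=["community_pair", "strength"],
        )

    def node_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.node_strength.items(), key=lambda t: -t[1]),
            columns=["node_id", "strength"],
        )


def network_strength(
    loadings_brain, contributing_edges, edge_index: EdgeIndex
) -> NetworkSummary:
    """Sum |edge loading| into community-pair and node strengths.

    Each contributing edge adds its |loading| to exactly one community
    pair and to both endpoint nodes, so the pair strengths conserve the
    total |loading| mass.
    """
    if edge_index.community_pair is None:
        raise ValueError("edge_index lacks community pairs; run assign_edge_communities")
    loadings_brain = np.asarray(loadings_brain, dtype=float)
    pair_strength: dict = {}
    node_strength: dict = {}
    for e in np.asarray(contributing_edges, dtype=int):
        if not 0 <= e < edge_index.n_edges:
            raise ValueError(f"edge id {e} outside the edge index")
        w = abs(float(loadings_brain[e]))
        pair = edge_index.community_pair[e]
        pair_strength[pair] = pair_strength.get(pair, 0.0) + w
        for v in (int(edge_index.node_i[e]), int(edge_index.node_j[e])):
            node_strength[v] = node_strength.get(v, 0.0) + w
    top_nodes = [v for v, _ in sorted(node_strength.items(), key=lambda t: -t[1])]
    return NetworkSummary(
        pair_strength=pair_strength, node_strength=node_strength, top_nodes=top_nodes
    )


@dataclass
class ModeResult:
    """Everything reported for one covariation mode."""

    mode_id: int
    observed_correlation: float
    p_value: float
    q_value: float
    covariance_fraction: float
    selected: bool
    loadings_brain: np.ndarray = field(repr=False)
    loadings_behavior: np.ndarray = field(repr=False)
    contributing_edges: np.ndarray = field(repr=False)
    contributing_behaviors: np.ndarray = field(repr=False)
    network_summary: NetworkSummary | None = None

    def to_dict(self) -> dict:
        return {
            "mode_id": self.mode_id,
            "observed_correlation": self.observed_correlation,
            "p_value": self.p_value,
            "q_value": self.q_value,
            "covariance_fraction": self.covariance_fraction,
            "selected": bool(self.selected),
            "contributing_edges": np.asarray(self.contributing_edges).tolist(),
            "contributing_behaviors": np.asarray(self.contributing_behaviors).tolist(),
        }


def evaluate_modes(
    results: RCCAResults,
    edge_index: EdgeIndex | None = None,
    n_perms: int = 5000,
    seed=None,
    alpha: float = 0.05,
    cov_threshold: float = 0.05,
    loading_threshold: float = 0.2,
) -> list[ModeResult]:
    """Full mode assessment: permutation p, FDR q, selection, loadings, strengths."""
    perm = results.permutation_test(n_perms=n_perms, seed=seed)
    q = bh_fdr(perm.p_values)
    frac = results.covariance_explained()
    chosen = set(select_modes(q, frac, alpha=alpha, cov_threshold=cov_threshold))
    brain, behavior = results.loadings()
    out = []
    for k in range(results.k_modes):
        edges = stable_contributors(brain[:, k], loading_threshold)
        behs = stable_contributors(behavior[:, k], loading_threshold)
        summary = (
            network_strength(brain[:, k], edges, edge_index)
            if edge_index is not None and edge_index.community_pair is not None
            else None
        )
        out.append(
            ModeResult(
                mode_id=k,
                observed_correlation=float(perm.observed[k]),
                p_value=float(perm.p_values[k]),
                q_value=float(q[k]),
                covariance_fraction=float(frac[k]),
                selected=k in chosen,
                loadings_brain=brain[:, k],
                loadings_behavior=behavior[:, k],
                contributing_edges=edges,
                contributing_behaviors=behs,
                network_summary=summary,
            )
        )
    return out


def mode_overlap(mode_a: ModeResult, mode_b: ModeResult, edge_index: EdgeIndex = None):
    """Shared contributing edges of two modes, with mean pair strengths.

    Returns ``(shared_edge_ids, NetworkSummary | None)``; the summary (mean
    of the two modes' strengths restricted to shared edges) requires an
    edge index with community pairs.
    """
    shared = np.intersect1d(
        np.asarray(mode_a.contributing_edges), np.asarray(mode_b.contributing_edges)
    )
    if edge_index is None or edge_index.community_pair is None:
        return shared, None
    sa = network_strength(mode_a.loadings_brain, shared, edge_index)
    sb = network_strength(mode_b.loadings_brain, shared, edge_index)
    pairs = set(sa.pair_strength) | set(sb.pair_strength)
    pair_strength = {
        p: (sa.pair_strength.get(p, 0.0) + sb.pair_strength.get(p, 0.0)) / 2.0
        for p in pairs
    }
    nodes = set(sa.node_strength) | set(sb.node_strength)
    node_strength = {
        v: (sa.node_strength.get(v, 0.0) + sb.node_strength.get(v, 0.0)) / 2.0
        for v in nodes
    }
    top = [v for v, _ in sorted(node_strength.items(), key=lambda t: -t[1])]
    return shared, NetworkSummary(pair_strength, node_strength, top)


def sensitivity_compare(results_a: RCCAResults, results_b: RCCAResults):
    """Correlate matched modes' loading vectors between two fits.

    Modes are matched greedily by |Pearson r| of the brain loading
    vectors (the order can swap between fits), signs resolved to maximise
    |r|. Returns a DataFrame with columns mode_a, mode_b, r_brain,
    r_behavior.
    """
    brain_a, beh_a = results_a.loadings()
    brain_b, beh_b = results_b.loadings()
    ka, kb = brain_a.shape[1], brain_b.shape[1]
    if ka != kb:
        warnings.warn(
            f"mode counts differ ({ka} vs {kb}); comparing the first "
            f"{min(ka, kb)} matched modes"
        )
    k = min(ka, kb)
    sim = np.zeros((k, kb))
    for i in range(k):
        for j in range(kb):
            sim[i, j] = abs(_pearson(brain_a[:, i], brain_b[:, j]))
    rows = []
    used = set()
    for i in np.argsort(-sim.max(axis=1)):
        order = np.argsort(-sim[i])
        j = next(int(j) for j in order if j not in used)
        used.add(j)
        rb = _pearson(brain_a[:, i], brain_b[:, j])
        sign = 1.0 if rb >= 0 else -1.0
        rows.append(
            {
                "mode_a": int(i),
                "mode_b": j,
                "r_brain": abs(rb),
                "r_behavior": abs(_pearson(beh_a[:, i], sign * beh_b[:, j])),
            }
        )
    return pd.DataFrame(sorted(rows, key=lambda r: r["mode_a"]))


def _pearson(u, v) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.std() == 0 or v.std() == 0:
        return 0.0
    return float(np.corrcoef(u, v)[0, 1])


def covariate_effects(variates_x: np.ndarray, cov: pd.DataFrame) -> pd.DataFrame:
    """Linear model of each brain variate on age + sex, FDR across modes.

    Returns one row per mode with slope/p for age, the sex coefficient and
    group means, and BH-FDR q values across modes.
    """
    V = np.asarray(variates_x, dtype=float)
    if V.ndim == 1:
        V = V[:, None]
    if len(V) != len(cov):
        raise ValueError("variates and covariates have different row counts")
    terms = []
    for name in ("age", "sex"):
        if name not in cov.columns:
            raise ValueError(f"covariates table missing column {name!r}")
        if cov[name].nunique() <= 1:
            warnings.warn(f"constant covariate {name!r} dropped from the model")
        else:
            terms.append(name)
    design = sm.add_constant(cov.loc[:, terms].to_numpy(dtype=float))
    rows = []
    for k in range(V.shape[1]):
        fit = sm.OLS(V[:, k], design).fit()
        row = {"mode_id": k}
        for t, name in enumerate(terms, start=1):
            row[f"{name}_coef"] = float(fit.params[t])
            row[f"{name}_p"] = float(fit.pvalues[t])
        if "sex" in cov.columns and cov["sex"].nunique() > 1:
            m = cov["sex"].to_numpy(dtype=float) == 1
            row["mean_sex1"] = float(V[m, k].mean())
            row["mean_sex0"] = float(V[~m, k].mean())
        rows.append(row)
    out = pd.DataFrame(rows)
    for name in terms:
        # OLS p values can underflow to exactly 0; clip for the BH step
        out[f"{name}_q"] = bh_fdr(np.clip(out[f"{name}_p"].to_numpy(), 1e-300, 1.0))
    return out
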