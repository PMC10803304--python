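"""Coupled brain/behavior simulation with planted covariation modes.

The generator emulates the study design the package targets: ~100 subjects,
a 136-node symmetric Fisher-z connectome (9180 edges), 17 correlated
questionnaire totals, K latent modes with chosen canonical correlations,
block-sparse edge loadings confined to named network-community pairs, and
linear age/sex/motion confound effects on the edges.

Generative model
----------------
For each mode k an i.i.d. standard-normal latent score z_k is drawn per
subject. With unit-norm loading vectors a_k (edges, supported on the
declared community-pair blocks) and b_k (behaviors, supported on the
declared index sets):

    X = sum_k s_k z_k a_k' + confounds + sigma * E_x
    Y = sum_k s_k z_k b_k' + sigma * E_y

with E iid standard normal. For a single factor with isotropic noise the
optimal weights are proportional to a_k and b_k, each variate correlating
``s_k / sqrt(s_k^2 + sigma^2)`` with z_k, so the population canonical
correlation between the blocks is the product

    rho_k = s_k^2 / (s_k^2 + sigma^2).

Inverting gives the closed-form signal-scale calibration used here:

    s_k = sigma * sqrt( rho_k / (1 - rho_k) )

The calibration is exact when modes use disjoint loading supports (the
default); overlapping supports make it approximate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import (
    COMMUNITIES,
    CommunityAssignment,
    EdgeIndex,
    assign_edge_communities,
    default_community_table,
)

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate_dataset", "generate_timeseries"]

#: Default planted structure: mode 0 lives in default-mode/dorsal-attention
#: edges (a stress-like pattern), mode 1 in affective/visual edges (an
#: anxiety-like pattern).
DEFAULT_EDGE_BLOCKS = ((("DMN", "DAN"),), (("AFN", "VN"),))
DEFAULT_BEHAVIOR_SETS = (tuple(range(0, 9)), tuple(range(9, 17)))


@dataclass
class SyntheticSpec:
    """Parameters of the planted-mode simulation.

    Defaults mirror the emulated study: 100 subjects, 136 nodes (9180
    edges), 17 questionnaire totals, two latent modes with canonical
    correlations (0.9, 0.75).
    """

    n_subjects: int = 100
    n_nodes: int = 136
    n_behaviors: int = 17
    n_modes: int = 2
    canonical_rhos: tuple = (0.9, 0.75)
    edge_loading_blocks: tuple = DEFAULT_EDGE_BLOCKS
    behavior_loading_sets: tuple = DEFAULT_BEHAVIOR_SETS
    confound_effect_size: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_nodes, self.n_behaviors) < 1:
            raise ValueError("counts must be positive")
        n_edges = self.n_nodes * (self.n_nodes - 1) // 2
        if self.n_modes > min(self.n_behaviors, n_edges):
            raise ValueError(
                f"n_modes={self.n_modes} exceeds the rank bound "
                f"min(n_behaviors={self.n_behaviors}, n_edges={n_edges})"
            )
        rhos = tuple(self.canonical_rhos)[: self.n_modes]
        if len(rhos) != self.n_modes:
            raise ValueError("need one canonical rho per mode")
        if any(not 0 < r < 1 for r in rhos):
            raise ValueError("canonical_rhos must lie in (0, 1)")
        if any(rhos[i] < rhos[i + 1] for i in range(len(rhos) - 1)):
            raise ValueError("canonical_rhos must be non-increasing")
        if self.confound_effect_size < 0:
            raise ValueError("confound_effect_size must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        valid = set(COMMUNITIES)
        for blocks in tuple(self.edge_loading_blocks)[: self.n_modes]:
            for pair in blocks:
                if not set(pair) <= valid:
                    raise ValueError(f"unknown community pair {pair!r}")
        for idx_set in tuple(self.behavior_loading_sets)[: self.n_modes]:
            if any(not 0 <= i < self.n_behaviors for i in idx_set):
                raise ValueError("behavior loading index out of range")


@dataclass
class SyntheticDataset:
    """Generated tables plus the generating ground truth."""

    edge_features: np.ndarray
    behaviors: np.ndarray
    covariates: pd.DataFrame
    edge_index: EdgeIndex
    communities: CommunityAssignment
    truth: dict
    timeseries: np.ndarray | None = None
    behavior_names: list = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.edge_features)

    def write(self, outdir) -> None:
        """Write CSV tables plus a JSON truth sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        subjects = [f"sub-{i:04d}" for i in range(self.n_subjects)]
        edges = pd.DataFrame(
            self.edge_features,
            columns=[f"edge_{i}" for i in range(self.edge_features.shape[1])],
        )
        edges.insert(0, "subject_id", subjects)
        edges.to_csv(outdir / "edge_features.csv", index=False)
        beh = pd.DataFrame(self.behaviors, columns=self.behavior_names)
        beh.insert(0, "subject_id", subjects)
        beh.to_csv(outdir / "behaviors.csv", index=False)
        cov = self.covariates.copy()
        cov.insert(0, "subject_id", subjects)
        cov.to_csv(outdir / "covariates.csv", index=False)
        self.communities.to_tsv(outdir / "communities.tsv")
        truth = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.truth.items()
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh)


def _block_loading(edge_index: EdgeIndex, blocks) -> np.ndarray:
    """Unit-norm loading vector, uniform over edges in the given community pairs."""
    wanted = {tuple(sorted(p)) for p in blocks}
    mask = np.array([p in wanted for p in edge_index.community_pair])
    if not mask.any():
        raise ValueError(f"no edges fall in community pairs {sorted(wanted)}")
    a = mask.astype(float)
    return a / np.linalg.norm(a)


def _set_loading(n: int, idx_set) -> np.ndarray:
    b = np.zeros(n)
    b[list(idx_set)] = 1.0
    if not b.any():
        raise ValueError("behavior loading set is empty")
    return b / np.linalg.norm(b)


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a coupled brain/behavior dataset with planted modes.

    Deterministic under ``spec.seed``. The returned ``truth`` dict records
    the latent scores, the unit-norm loading vectors, the target canonical
    correlations, and which edges carry confound effects.
    """
    rng = np.random.default_rng(spec.seed)
    n, K = spec.n_subjects, spec.n_modes
    communities = default_community_table(spec.n_nodes)
    edge_index = assign_edge_communities(
        EdgeIndex.from_n_nodes(spec.n_nodes), communities
    )
    p = edge_index.n_edges
    q = spec.n_behaviors
    sigma = spec.noise_sd

    rhos = np.array(tuple(spec.canonical_rhos)[:K], dtype=float)
    A = np.zeros((p, K))
    B = np.zeros((q, K))
    for k in range(K):
        A[:, k] = _block_loading(edge_index, tuple(spec.edge_loading_blocks)[k])
        B[:, k] = _set_loading(q, tuple(spec.behavior_loading_sets)[k])

    # closed-form calibration: rho = s^2/(s^2+sigma^2), i.e. each block's
    # variate correlates sqrt(rho) with the latent (see module docstring)
    s = sigma * np.sqrt(rhos / (1.0 - rhos)) if K else np.array([])

    Z = rng.standard_normal((n, K))
    X = (Z * s) @ A.T + sigma * rng.standard_normal((n, p))
    Y = (Z * s) @ B.T + sigma * rng.standard_normal((n, q))

    # covariates: a student cohort — age uniform 18-28 y, sex Bernoulli(0.5),
    # mean FD lognormal with median 0.1 mm
    age = rng.uniform(18.0, 28.0, n)
    sex = rng.integers(0, 2, n).astype(float)
    mean_fd = rng.lognormal(mean=np.log(0.1), sigma=0.4, size=n)
    covariates = pd.DataFrame({"age": age, "sex": sex, "mean_fd": mean_fd})

    # confound effects: each covariate pushes a disjoint 10% slice of edges
    # with a +confound_effect_size slope on its standardized value
    affected: dict[str, list] = {}
    if spec.confound_effect_size > 0:
        gamma = spec.confound_effect_size
        n_aff = max(1, p // 10)
        edge_perm = rng.permutation(p)
        for c, name in enumerate(("age", "sex", "mean_fd")):
            ids = np.sort(edge_perm[c * n_aff : (c + 1) * n_aff])
            col = covariates[name].to_numpy()
            colz = (col - col.mean()) / (col.std() if col.std() > 0 else 1.0)
            X[:, ids] += gamma * colz[:, None]
            affected[name] = ids.tolist()

    truth = {
        "latent_scores": Z,
        "edge_loadings": A,
        "behavior_loadings": B,
        "canonical_rhos": rhos,
        "signal_scales": s,
        "noise_sd": sigma,
        "confound_effect_size": spec.confound_effect_size,
        "affected_edges": affected,
    }
    return SyntheticDataset(
        edge_features=X,
        behaviors=Y,
        covariates=covariates,
        edge_index=edge_index,
        communities=communities,
        truth=truth,
        behavior_names=[f"measure_{j:02d}" for j in range(q)],
    )


def generate_timeseries(
    target_connectome: np.ndarray,
    t_points: int,
    n_subjects: int = 1,
    seed=None,
) -> np.ndarray:
    """Sample node time series whose correlation converges to a target.

    Parameters
    ----------
    target_connectome : ndarray (n_nodes, n_nodes)
        Desired population correlation matrix: symmetric, positive
        semi-definite, unit diagonal.
    t_points : int
        Number of time points (>= 2; correlation is undefined at 1).
    n_subjects : int
        Number of independent subject series to draw.

    Returns
    -------
    ndarray, shape (n_subjects, n_nodes, t_points)
    """
    C = np.asarray(target_connectome, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("target must be a square matrix")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("target correlation matrix must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-10):
        raise ValueError("target must have unit diagonal")
    if t_points < 2:
        raise ValueError("t_points must be >= 2 (correlation undefined at 1)")
    vals, vecs = np.linalg.eigh(C)
    if vals.min() < -1e-8:
        raise ValueError(
            f"target is not positive semi-definite (min eigenvalue {vals.min():.3g})"
        )
    root = vecs * np.sqrt(np.maximum(vals, 0.0))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_subjects, C.shape[0], t_points))
    return np.einsum("ij,sjt->sit", root, noise)
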