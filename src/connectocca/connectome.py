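"""Functional-connectome construction and edge bookkeeping.

A subject's connectome is the node x node matrix of Fisher-z transformed
Pearson correlations between regional time series. For multivariate
modelling the strict upper triangle is flattened into an edge feature
vector; :class:`EdgeIndex` fixes the edge ordering (row-major upper
triangle, 0-based node ids) and carries the mapping from each edge to its
unordered pair of network communities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "COMMUNITIES",
    "CommunityAssignment",
    "EdgeIndex",
    "fisher_z",
    "build_connectome",
    "vectorize",
    "devectorize",
    "assign_edge_communities",
    "default_community_table",
]

#: The seven canonical resting-state network communities.
COMMUNITIES = ("DMN", "CEN", "VAN", "DAN", "AFN", "SMN", "VN")

# |r| is clipped to 1 - _CLIP_EPS before atanh so z stays finite.
_CLIP_EPS = 1e-7


def fisher_z(r):
    """Fisher z-transform ``atanh(r)`` with clipping near ``|r| = 1``.

    Parameters
    ----------
    r : float or array-like
        Correlation coefficient(s) with ``|r| <= 1``.

    Returns
    -------
    float or ndarray
        ``atanh`` of the clipped input; always finite.
    """
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("fisher_z requires finite correlation values")
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise ValueError("correlations must satisfy |r| <= 1")
    clipped = np.clip(r, -(1.0 - _CLIP_EPS), 1.0 - _CLIP_EPS)
    out = np.arctanh(clipped)
    return float(out) if out.ndim == 0 else out


def build_connectome(timeseries: np.ndarray) -> np.ndarray:
    """Fisher-z connectivity matrix from a node x time series array.

    Parameters
    ----------
    timeseries : ndarray, shape (n_nodes, n_timepoints)
        Mean regional time series; needs at least 3 time points and no
        constant series.

    Returns
    -------
    ndarray, shape (n_nodes, n_nodes)
        Symmetric matrix of Fisher-z correlations with zero diagonal.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be a 2-D node x time array")
    if ts.shape[1] < 3:
        raise ValueError(
            f"need at least 3 time points, got {ts.shape[1]}"
        )
    sd = ts.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"constant time series for node(s) {bad.tolist()}: "
            "correlation undefined"
        )
    r = np.corrcoef(ts)
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)
    # enforce exact symmetry against floating-point asymmetry in corrcoef
    return (z + z.T) / 2.0


@dataclass
class EdgeIndex:
    """Mapping between edge ids and node pairs of the upper triangle.

    Edges are numbered row-major over the strict upper triangle: edge 0 is
    (0, 1), edge 1 is (0, 2), ..., the last edge is (n-2, n-1).
    """

    n_nodes: int
    node_i: np.ndarray = field(repr=False)
    node_j: np.ndarray = field(repr=False)
    community_pair: list | None = field(default=None, repr=False)

    @classmethod
    def from_n_nodes(cls, n_nodes: int) -> "EdgeIndex":
        if n_nodes < 2:
            raise ValueError("need at least 2 nodes to define edges")
        i, j = np.triu_indices(n_nodes, k=1)
        return cls(n_nodes=n_nodes, node_i=i, node_j=j)

    @property
    def n_edges(self) -> int:
        return self.node_i.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "edge_id": np.arange(self.n_edges),
                "node_i": self.node_i,
                "node_j": self.node_j,
            }
        )
        if self.community_pair is not None:
            df["community_pair"] = [
                f"{a}-{b}" for a, b in self.community_pair
            ]
        return df


@dataclass
class CommunityAssignment:
    """Node -> network community labels.

    ``table`` has columns ``node_id``, ``node_name``, ``community``;
    node ids must form a contiguous 0-based range and every community must
    be one of :data:`COMMUNITIES`.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"node_id", "node_name", "community"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"community table missing columns {sorted(missing)}")
        ids = np.sort(self.table["node_id"].to_numpy())
        if not np.array_equal(ids, np.arange(len(ids))):
            raise ValueError("node_id must be a contiguous 0-based range")
        unknown = set(self.table["community"]) - set(COMMUNITIES)
        if unknown:
            raise ValueError(f"unknown communities {sorted(unknown)}")

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    def labels(self) -> np.ndarray:
        """Community label per node, in node-id order."""
        return (
            self.table.sort_values("node_id")["community"].to_numpy()
        )

    @classmethod
    def from_tsv(cls, path) -> "CommunityAssignment":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def default_community_table(n_nodes: int = 136) -> CommunityAssignment:
    """Synthetic stand-in node -> community table.

    Assigns nodes to the seven communities in contiguous blocks of
    near-equal size. This is a generic placeholder for simulation and
    testing, not any published atlas mapping; users analysing real data
    supply their own table.
    """
    bounds = np.linspace(0, n_nodes, len(COMMUNITIES) + 1).round().astype(int)
    labels = np.empty(n_nodes, dtype=object)
    for k, comm in enumerate(COMMUNITIES):
        labels[bounds[k] : bounds[k + 1]] = comm
    table = pd.DataFrame(
        {
            "node_id": np.arange(n_nodes),
            "node_name": [f"node_{i:03d}" for i in range(n_nodes)],
            "community": labels,
        }
    )
    return CommunityAssignment(table)


def vectorize(conn: np.ndarray, atol: float = 1e-8):
    """Flatten a symmetric connectome into its upper-triangle edge vector.

    Returns
    -------
    (ndarray, EdgeIndex)
        Edge values in row-major strict-upper-triangle order (length
        ``n(n-1)/2``) and the matching :class:`EdgeIndex`.
    """
    conn = np.asarray(conn, dtype=float)
    if conn.ndim != 2 or conn.shape[0] != conn.shape[1]:
        raise ValueError("connectome must be a square matrix")
    if not np.allclose(conn, conn.T, atol=atol):
        raise ValueError("connectome is not symmetric within tolerance")
    index = EdgeIndex.from_n_nodes(conn.shape[0])
    return conn[index.node_i, index.node_j], index


def devectorize(edges: np.ndarray, n_nodes: int) -> np.ndarray:
    """Inverse of :func:`vectorize`: rebuild the symmetric matrix (zero diag)."""
    edges = np.asarray(edges, dtype=float)
    expected = n_nodes * (n_nodes - 1) // 2
    if edges.size != expected:
        raise ValueError(
            f"edge vector has length {edges.size}, expected {expected}"
        )
    out = np.zeros((n_nodes, n_nodes))
    i, j = np.triu_indices(n_nodes, k=1)
    out[i, j] = edges
    out[j, i] = edges
    return out


def assign_edge_communities(
    index: EdgeIndex, communities: CommunityAssignment
) -> EdgeIndex:
    """Fill each edge's unordered community pair from the node labels.

    With 7 communities there are 7 within-network pairs plus C(7,2) = 21
    between-network pairs, i.e. 28 possible values.
    """
    if communities.n_nodes < index.n_nodes:
        raise ValueError(
            f"community table labels {communities.n_nodes} nodes but the "
            f"edge index spans {index.n_nodes}"
        )
    labels = communities.labels()
    pairs = [
        tuple(sorted((labels[i], labels[j])))
        for i, j in zip(index.node_i, index.node_j)
    ]
    return EdgeIndex(
        n_nodes=index.n_nodes,
        node_i=index.node_i,
        node_j=index.node_j,
        community_pair=pairs,
    )
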