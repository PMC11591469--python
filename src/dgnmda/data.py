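"""Association and similarity data structures and graph assembly.

The prediction task lives on a bipartite network of M miRNAs and N
diseases.  Known associations form a binary M x N matrix; each node
family additionally carries square similarity matrices (functional or
semantic views supplied as input, Gaussian interaction-profile kernel
views computed here).  Both encoders consume a single heterogeneous
graph over the M+N nodes:

* a block adjacency ``[[0, A], [A^T, 0]]`` built from the associations,
* its symmetric renormalisation ``D^{-1/2}(A+I)D^{-1/2}``,
* an input feature matrix pairing each node's similarity profile with
  its association profile (width M+N),
* all-pairs hop distances feeding the transformer's Gaussian bias, and
* discrete neighbour lists (association edges plus top-k similarity
  edges) feeding the attention encoder.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationMatrix",
    "SimilarityView",
    "HeterogeneousGraph",
    "load_associations",
    "load_similarity",
    "save_similarity",
    "compute_gip_similarity",
    "fuse_similarities",
    "build_heterogeneous_adjacency",
    "normalize_adjacency",
    "build_feature_matrix",
    "hop_distances",
    "sparsify_similarity",
    "build_graph",
]

_SYM_TOL = 1e-6


@dataclass
class AssociationMatrix:
    """Binary M x N matrix of validated miRNA-disease links with id indices."""

    mirna_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        m, n = self.values.shape
        if m != len(self.mirna_ids) or n != len(self.disease_ids):
            raise ValueError("id lists inconsistent with matrix shape")
        if m < 1 or n < 1:
            raise ValueError("need at least one miRNA and one disease")
        if len(set(self.mirna_ids)) != m or len(set(self.disease_ids)) != n:
            raise ValueError("node ids must be unique within each family")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association entries must be 0 or 1")

    @property
    def n_mirna(self) -> int:
        return self.values.shape[0]

    @property
    def n_disease(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(list(self.mirna_ids), list(self.disease_ids), self.values.copy())

    def mask_pairs(self, pairs) -> "AssociationMatrix":
        """Return a copy with the given (i, j) entries zeroed (leakage masking)."""
        out = self.copy()
        for i, j in pairs:
            out.values[i, j] = 0
        return out

    def to_tsv(self, path) -> None:
        rows = np.argwhere(self.values == 1)
        df = pd.DataFrame(
            {
                "mirna_id": [self.mirna_ids[i] for i, _ in rows],
                "disease_id": [self.disease_ids[j] for _, j in rows],
            }
        )
        df.to_csv(path, sep="\t", index=False)


@dataclass
class SimilarityView:
    """Symmetric square similarity matrix in [0, 1] with unit diagonal."""

    node_family: str  # "mirna" | "disease"
    source: str  # "functional" | "semantic" | "gip" | "fused"
    values: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if self.node_family not in ("mirna", "disease"):
            raise ValueError(f"unknown node family {self.node_family!r}")
        if np.abs(v - v.T).max() > 1e-8:
            raise ValueError("similarity matrix not symmetric within 1e-8")
        if np.abs(np.diag(v) - 1.0).max() > 1e-8:
            raise ValueError("similarity diagonal must be 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass
class HeterogeneousGraph:
    """All graph-level inputs both encoders consume, over M+N nodes."""

    adjacency: np.ndarray
    norm_adjacency: np.ndarray
    features: np.ndarray
    hop_distance: np.ndarray
    neighbor_lists: list[np.ndarray]
    n_mirna: int
    n_disease: int

    @property
    def n_nodes(self) -> int:
        return self.n_mirna + self.n_disease


# ---------------------------------------------------------------------------
# I/O


def load_associations(path) -> AssociationMatrix:
    """Read an association edge list TSV into an :class:`AssociationMatrix`.

    Columns: miRNA id, disease id, optional binary label (default 1).
    A header row is tolerated.  Ids are deduplicated and sorted
    lexicographically so indexing is reproducible across runs.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.empty:
        raise ValueError(f"association file {path} is empty")
    if df.shape[1] < 2:
        raise ValueError("association file needs at least two columns")
    # drop a header row if the optional third column is non-numeric
    first = df.iloc[0]
    if str(first[0]).lower() in ("mirna_id", "mirna", "mir") or (
        df.shape[1] >= 3 and not str(first[2]).replace(".", "").isdigit()
    ):
        df = df.iloc[1:]
        if df.empty:
            raise ValueError(f"association file {path} has a header but no rows")
    labels = (
        pd.to_numeric(df.iloc[:, 2], errors="coerce").fillna(1).astype(int)
        if df.shape[1] >= 3
        else pd.Series(1, index=df.index)
    )
    keep = labels != 0
    pairs = list(zip(df.iloc[:, 0][keep], df.iloc[:, 1][keep]))
    if len(set(pairs)) != len(pairs):
        logger.warning("duplicate association pairs in %s; keeping one copy each", path)
    mirna_ids = sorted(set(df.iloc[:, 0]))
    disease_ids = sorted(set(df.iloc[:, 1]))
    mi = {m: i for i, m in enumerate(mirna_ids)}
    di = {d: j for j, d in enumerate(disease_ids)}
    values = np.zeros((len(mirna_ids), len(disease_ids)), dtype=np.int8)
    for m, d in pairs:
        values[mi[m], di[d]] = 1
    return AssociationMatrix(mirna_ids, disease_ids, values)


def load_similarity(path, node_family: str, source: str = "functional") -> SimilarityView:
    """Read a labeled square similarity CSV/TSV (ids in first row and column)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column ids differ")
    v = df.to_numpy(dtype=np.float64)
    if np.abs(v - v.T).max() > _SYM_TOL:
        raise ValueError(f"{path}: matrix not symmetric within {_SYM_TOL}")
    v = 0.5 * (v + v.T)
    np.fill_diagonal(v, 1.0)
    return SimilarityView(node_family, source, v, ids=list(df.index))


def save_similarity(view: SimilarityView, path, ids: list[str] | None = None) -> None:
    ids = ids if ids is not None else (view.ids or [str(i) for i in range(view.size)])
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    pd.DataFrame(view.values, index=ids, columns=ids).to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Similarity computation and fusion


def compute_gip_similarity(assoc: AssociationMatrix, family: str) -> SimilarityView:
    """Gaussian interaction-profile (GIP) kernel similarity for one node family.

    With IP(i) the i-th row (miRNA) or column (disease) of the association
    matrix, ``sim(i, j) = exp(-gamma * ||IP(i) - IP(j)||^2)`` where the
    bandwidth ``gamma = n / sum_i ||IP(i)||^2`` normalises by the mean
    squared profile norm.
    """
    if family == "mirna":
        profiles = assoc.values.astype(np.float64)
        ids = assoc.mirna_ids
    elif family == "disease":
        profiles = assoc.values.T.astype(np.float64)
        ids = assoc.disease_ids
    else:
        raise ValueError(f"unknown family {family!r}")
    sq_norms = (profiles**2).sum(axis=1)
    total = sq_norms.sum()
    if total == 0:
        raise ValueError("GIP bandwidth undefined: all interaction profiles are zero")
    gamma = len(ids) / total
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(d2, 0.0, out=d2)
    values = np.exp(-gamma * d2)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 1.0)
    return SimilarityView(family, "gip", values, ids=list(ids))


def fuse_similarities(a: SimilarityView, b: SimilarityView, mode: str = "mean") -> SimilarityView:
    """Combine two similarity views of the same family into one.

    mode "mean": elementwise average.  mode "prefer_a_nonzero": take a's
    entry wherever it is nonzero, else b's.
    """
    if a.node_family != b.node_family or a.size != b.size:
        raise ValueError("views must share family and size")
    if mode == "mean":
        v = 0.5 * (a.values + b.values)
    elif mode == "prefer_a_nonzero":
        v = np.where(a.values > 0, a.values, b.values)
    else:
        raise ValueError(f"unknown fusion mode {mode!r}")
    v = 0.5 * (v + v.T)
    np.fill_diagonal(v, 1.0)
    return SimilarityView(a.node_family, "fused", v, ids=a.ids or b.ids)


# ---------------------------------------------------------------------------
# Graph assembly


def build_heterogeneous_adjacency(assoc: AssociationMatrix) -> np.ndarray:
    """Block adjacency ``[[0, A], [A^T, 0]]`` over the M+N nodes."""
    m, n = assoc.values.shape
    adj = np.zeros((m + n, m + n), dtype=np.int8)
    adj[:m, m:] = assoc.values
    adj[m:, :m] = assoc.values.T
    return adj


def normalize_adjacency(adj: np.ndarray) -> np.ndarray:
    """Symmetric renormalisation with self-loops: ``D^{-1/2}(A + I)D^{-1/2}``.

    D is the degree matrix of A + I, so isolated nodes keep a unit
    self-loop instead of dividing by zero.
    """
    adj = np.asarray(adj, dtype=np.float64)
    if adj.shape[0] != adj.shape[1] or np.abs(adj - adj.T).max() > 1e-12:
        raise ValueError("adjacency must be square and symmetric")
    a_hat = adj + np.eye(adj.shape[0])
    dinv = 1.0 / np.sqrt(a_hat.sum(axis=1))
    return dinv[:, None] * a_hat * dinv[None, :]


def build_feature_matrix(
    m_sim: SimilarityView,
    d_sim: SimilarityView,
    assoc: AssociationMatrix,
    layout: str = "block_with_assoc",
) -> np.ndarray:
    """Stack per-family similarity profiles into (M+N) x (M+N) node features.

    Each miRNA row is its similarity profile followed by its association
    profile; each disease row is its association profile followed by its
    similarity profile.  `block_diagonal` zeroes the association blocks.
    """
    m, n = assoc.values.shape
    if m_sim.size != m or d_sim.size != n:
        raise ValueError("similarity sizes inconsistent with association matrix")
    feats = np.zeros((m + n, m + n), dtype=np.float64)
    feats[:m, :m] = m_sim.values
    feats[m:, m:] = d_sim.values
    if layout == "block_with_assoc":
        feats[:m, m:] = assoc.values
        feats[m:, :m] = assoc.values.T
    elif layout != "block_diagonal":
        raise ValueError(f"unknown layout {layout!r}")
    return feats


def hop_distances(adj: np.ndarray, cap: int = 10) -> np.ndarray:
    """All-pairs shortest-path hop counts, unreachable pairs set to `cap`."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    adj = np.asarray(adj)
    if np.abs(adj - adj.T).max() > 1e-12:
        raise ValueError("adjacency must be symmetric")
    d = shortest_path(adj.astype(np.float64), method="D", unweighted=True, directed=False)
    d[np.isinf(d)] = cap
    np.minimum(d, cap, out=d)
    return d.astype(np.int64)


def sparsify_similarity(sim: SimilarityView, top_k: int = 10) -> list[set[int]]:
    """Top-k most-similar neighbours per node, symmetrised by union.

    Ties broken toward lower index; the node itself is never its own
    neighbour here.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    n = sim.size
    if top_k >= n:
        warnings.warn("top_k >= matrix size; keeping all other nodes", stacklevel=2)
        top_k = n - 1
    neighbors: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        row = sim.values[i].copy()
        row[i] = -np.inf
        # stable sort on (-similarity, index): ties go to the lower index
        order = np.lexsort((np.arange(n), -row))
        for j in order[:top_k]:
            neighbors[i].add(int(j))
            neighbors[int(j)].add(i)
    return neighbors


def build_graph(
    assoc: AssociationMatrix,
    m_sim: SimilarityView,
    d_sim: SimilarityView,
    top_k: int = 10,
    distance_cap: int = 10,
    feature_layout: str = "block_with_assoc",
    neighbor_edges: str = "similarity",
) -> HeterogeneousGraph:
    """Assemble every graph-level input the encoders need.

    The attention encoder's neighbour lists come from the per-family
    top-k similarity networks (``neighbor_edges="similarity"``, the
    default: the attention encoder reads the similarity networks while
    association structure enters through the features and the block
    adjacency).  ``"similarity+association"`` additionally unions in the
    association edges.  Isolated nodes fall back to a self edge so
    attention neighbourhoods are never empty.

    Hop distances for the transformer's Gaussian bias are measured on
    the working graph (association edges united with the similarity
    edges); on the bipartite association graph alone every same-family
    pair would sit at two or more hops and the bias would suppress
    exactly the within-family attention the method relies on.
    """
    if neighbor_edges not in ("similarity", "similarity+association"):
        raise ValueError(f"unknown neighbor_edges mode {neighbor_edges!r}")
    m, n = assoc.values.shape
    adj = build_heterogeneous_adjacency(assoc)
    norm_adj = normalize_adjacency(adj)
    feats = build_feature_matrix(m_sim, d_sim, assoc, layout=feature_layout)

    sim_nbrs: list[set[int]] = [set() for _ in range(m + n)]
    for i, s in enumerate(sparsify_similarity(m_sim, top_k=min(top_k, max(1, m - 1)))):
        sim_nbrs[i].update(s)
    for j, s in enumerate(sparsify_similarity(d_sim, top_k=min(top_k, max(1, n - 1)))):
        sim_nbrs[m + j].update(m + x for x in s)

    working = adj.astype(np.int8).copy()
    for i, s in enumerate(sim_nbrs):
        for j in s:
            working[i, j] = working[j, i] = 1
    np.fill_diagonal(working, 0)
    hops = hop_distances(working, cap=distance_cap)

    nbrs = sim_nbrs
    if neighbor_edges == "similarity+association":
        for i in range(m + n):
            nbrs[i].update(np.flatnonzero(adj[i]))
    lists = []
    for i, s in enumerate(nbrs):
        s.discard(i)
        lists.append(np.array(sorted(s) if s else [i], dtype=np.intp))
    return HeterogeneousGraph(
        adjacency=adj,
        norm_adjacency=norm_adj,
        features=feats,
        hop_distance=hops,
        neighbor_lists=lists,
        n_mirna=m,
        n_disease=n,
    )
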