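"""Normalization, embedding, graph clustering and K-MST resolution selection.

The clustering workflow mirrors the standard graph pipeline: variance-stabilize
counts as Pearson residuals of a Gamma-Poisson fit with a library-size offset,
embed with PCA (50 components), build a shared-nearest-neighbor (SNN) graph
(k = 50, Jaccard weights, prune = 0) and detect communities by modularity
optimization at a given resolution.

The number of clusters is chosen nonparametrically: nuclei are embedded into a
K-minimum-spanning-tree graph (the union of k edge-disjoint MSTs on Euclidean
distances), and for each candidate resolution the within-cluster edge count
R_W is standardized against the uniform label-permutation null (cluster sizes
fixed).  Well-separated communities concentrate K-MST edges within clusters, so
the resolution maximizing the standardized count Z is selected.  The
permutation moments are exact: with n_k the cluster sizes, (n)_j the falling
factorial, m edges and s the number of edge pairs sharing an endpoint,

    E[R_W]   = m * sum_k (n_k)_2 / (n)_2
    E[R_W^2] = E[R_W] + 2*s * sum_k (n_k)_3 / (n)_3
               + 2*(C(m,2) - s) * [sum_k (n_k)_4 + sum_{k!=l} (n_k)_2 (n_l)_2] / (n)_4
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "Embedding",
    "NeighborGraph",
    "KMSTGraph",
    "ZStatistic",
    "ClusteringResult",
    "ResolutionScan",
    "normalize_residuals",
    "pca_embed",
    "build_snn_graph",
    "community_detect",
    "build_kmst",
    "build_kmst_snn",
    "within_edge_count_z",
    "select_resolution",
    "score_marker_panels",
]

DEFAULT_GRID = tuple(np.round(np.arange(0.05, 2.0001, 0.05), 4))


@dataclass
class Embedding:
    ids: list[str]
    coords: np.ndarray  # (n, n_components)
    variance_shares: np.ndarray


@dataclass
class NeighborGraph:
    n: int
    edges: np.ndarray  # (m, 2) with u < v
    weights: np.ndarray
    k: int
    mode: str = "snn"
    _igraph: object = field(default=None, repr=False, compare=False)

    def to_igraph(self) -> "igraph.Graph":
        if self._igraph is None:
            self._igraph = igraph.Graph(n=self.n, edges=[tuple(e) for e in self.edges])
        return self._igraph


@dataclass
class KMSTGraph:
    n: int
    edges: np.ndarray  # (m, 2) with u < v, unweighted union of k MSTs
    k: int


@dataclass
class ZStatistic:
    r_w: int
    e_rw: float
    var_rw: float
    z: float
    degenerate: bool


@dataclass
class ClusteringResult:
    labels: np.ndarray
    resolution: float
    algorithm: str
    seed: int

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


@dataclass
class ResolutionScan:
    scan: pd.DataFrame  # resolution, n_clusters, r_w, e_rw, var_rw, z, degenerate
    selected_resolution: float
    selected: ClusteringResult
    kmst: KMSTGraph = field(repr=False, default=None)


# ---------------------------------------------------------------- normalization

def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def normalize_residuals(
    adata_or_counts, library_sizes: np.ndarray | None = None
) -> np.ndarray:
    """Pearson residuals of a per-gene Gamma-Poisson fit with library offset.

    The fitted mean is mu_ig = t_i * (sum_i y_ig / sum_i t_i); the per-gene
    overdispersion is a method-of-moments estimate, and residuals
    (y - mu) / sqrt(mu + mu^2/theta) are clipped to +/- sqrt(n_nuclei).
    Genes with zero total count get all-zero residual columns.
    """
    X = adata_or_counts.X if isinstance(adata_or_counts, ad.AnnData) else adata_or_counts
    Y = _dense(X).astype(np.float64)
    n, g = Y.shape
    t = np.asarray(library_sizes, float) if library_sizes is not None else Y.sum(axis=1)
    if np.any(t <= 0):
        raise ValueError("library sizes must be positive")
    gene_tot = Y.sum(axis=0)
    rate = gene_tot / t.sum()
    mu = np.outer(t, rate)
    resid_num = Y - mu
    # moments estimator of 1/theta per gene, clipped; Poisson-like genes -> ~0
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (resid_num**2 - mu).sum(axis=0)
        den = (mu**2).sum(axis=0)
        inv_theta = np.clip(np.where(den > 0, num / den, 0.0), 0.0, 100.0)
    var = mu + inv_theta[None, :] * mu**2
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(var > 0, resid_num / np.sqrt(var), 0.0)
    clip = np.sqrt(n)
    np.clip(r, -clip, clip, out=r)
    r[:, gene_tot == 0] = 0.0
    return r


def pca_embed(
    residuals: np.ndarray,
    n_components: int = 50,
    n_top_genes: int = 3000,
    ids: list[str] | None = None,
    seed: int = 0,
) -> Embedding:
    """PCA of the residual matrix restricted to the most variable genes.

    Component signs are fixed (largest-magnitude loading positive) so
    coordinates are reproducible across runs.
    """
    n, g = residuals.shape
    if n_components > min(n, g):
        raise ValueError(
            f"n_components = {n_components} exceeds min(genes, nuclei) = {min(n, g)}"
        )
    gene_var = residuals.var(axis=0)
    if g > n_top_genes:
        top = np.argsort(gene_var)[::-1][:n_top_genes]
        mat = residuals[:, np.sort(top)]
    else:
        mat = residuals
    pca = PCA(n_components=n_components, random_state=seed)
    coords = pca.fit_transform(mat)
    # deterministic sign convention
    flip = np.sign(pca.components_[np.arange(n_components),
                                   np.abs(pca.components_).argmax(axis=1)])
    flip[flip == 0] = 1.0
    coords = coords * flip[None, :]
    ids = list(ids) if ids is not None else [str(i) for i in range(n)]
    return Embedding(ids=ids, coords=coords,
                     variance_shares=pca.explained_variance_ratio_.copy())


# ------------------------------------------------------------------ SNN graph

def build_snn_graph(embedding: Embedding, k: int = 50, prune: float = 0.0) -> NeighborGraph:
    """Shared-nearest-neighbor graph with Jaccard weights over kNN sets.

    Neighbor sets include the nucleus itself (size k); edges with Jaccard
    overlap <= ``prune`` are dropped (prune = 0 keeps all positive overlaps).
    """
    coords = embedding.coords
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k = {k} must be smaller than n = {n}")
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    _, idx = nn.kneighbors(coords)  # includes self as first neighbor
    rows = np.repeat(np.arange(n), k)
    A = sp.csr_matrix(
        (np.ones(n * k), (rows, idx.ravel())), shape=(n, n)
    )
    inter = (A @ A.T).tocoo()  # |kNN(u) & kNN(v)|
    u, v, c = inter.row, inter.col, inter.data
    keep = u < v
    u, v, c = u[keep], v[keep], c[keep]
    jac = c / (2 * k - c)
    pos = jac > prune
    return NeighborGraph(n=n, edges=np.column_stack([u[pos], v[pos]]),
                         weights=jac[pos], k=k, mode="snn")


def community_detect(graph: NeighborGraph, resolution: float, seed: int = 0) -> ClusteringResult:
    """Modularity community detection (Leiden refinement of Louvain) at a resolution.

    Labels are relabeled by decreasing cluster size; deterministic given seed.
    """
    if graph.n == 0 or len(graph.edges) == 0:
        raise ValueError("cannot cluster an empty graph")
    g = graph.to_igraph()
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=list(graph.weights),
        resolution_parameter=float(resolution),
        seed=int(seed),
        n_iterations=2,
    )
    raw = np.asarray(part.membership)
    order = np.argsort([-np.sum(raw == c) for c in range(raw.max() + 1)], kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(len(order))
    return ClusteringResult(labels=remap[raw], resolution=float(resolution),
                            algorithm="leiden-rbconfiguration", seed=int(seed))


# --------------------------------------------------------------------- K-MST

def build_kmst(embedding: Embedding, k: int = 5) -> KMSTGraph:
    """Union of the 1st..kth orthogonal MSTs on Euclidean distances.

    Each round computes the MST of the remaining complete graph and removes its
    edges, so the k trees are pairwise edge-disjoint and the union has exactly
    k*(n-1) edges.  Zero distances (duplicate points) are permitted.
    """
    coords = embedding.coords if isinstance(embedding, Embedding) else np.asarray(embedding)
    n = coords.shape[0]
    if n <= k:
        raise ValueError(f"need n > k; got n = {n}, k = {k}")
    D = squareform(pdist(coords))
    np.fill_diagonal(D, np.inf)  # inf marks absent edges; duplicates (d = 0) allowed
    edges = []
    for _ in range(k):
        tu, tv = _prim_mst(D)
        edges.append(np.column_stack([np.minimum(tu, tv), np.maximum(tu, tv)]))
        D[tu, tv] = np.inf
        D[tv, tu] = np.inf
    E = np.vstack(edges)
    return KMSTGraph(n=n, edges=E, k=k)


def _prim_mst(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Prim's MST on a dense symmetric distance matrix (inf = absent edge).

    Ties are broken toward the lowest vertex index, so construction is
    deterministic.
    """
    n = D.shape[0]
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    best = D[0].copy()
    parent = np.zeros(n, dtype=np.int64)
    us = np.empty(n - 1, dtype=np.int64)
    vs = np.empty(n - 1, dtype=np.int64)
    for it in range(n - 1):
        j = int(np.argmin(best))
        if not np.isfinite(best[j]):
            raise ValueError("graph disconnected during K-MST construction")
        us[it], vs[it] = parent[j], j
        in_tree[j] = True
        best[j] = np.inf
        row = D[j]
        upd = (row < best) & ~in_tree
        best[upd] = row[upd]
        parent[upd] = j
    return us, vs


def build_kmst_snn(graph: NeighborGraph, k: int = 5) -> KMSTGraph:
    """K-MST variant on SNN dissimilarities (1 - Jaccard), restricted to SNN edges.

    Offered for comparison only; the embedding-space K-MST is the default.
    """
    n = graph.n
    W = sp.coo_matrix(
        (2.0 - graph.weights, (graph.edges[:, 0], graph.edges[:, 1])), shape=(n, n)
    ).tocsr()
    W = W + W.T
    D = W.toarray()
    D[D == 0] = np.inf
    np.fill_diagonal(D, 0.0)
    edges = []
    for _ in range(k):
        tree = minimum_spanning_tree(D)
        tu, tv = tree.nonzero()
        if len(tu) != n - 1:
            raise ValueError(
                "SNN graph too sparse for edge-disjoint spanning trees; "
                "use the embedding-space K-MST"
            )
        edges.append(np.column_stack([np.minimum(tu, tv), np.maximum(tu, tv)]))
        D[tu, tv] = np.inf
        D[tv, tu] = np.inf
    return KMSTGraph(n=n, edges=np.vstack(edges), k=k)


def within_edge_count_z(kmst: KMSTGraph, labels: np.ndarray) -> ZStatistic:
    """Standardized within-cluster edge count under the label-permutation null."""
    labels = np.asarray(labels)
    n = kmst.n
    if len(labels) != n:
        raise ValueError("labels must cover all graph nodes")
    u, v = kmst.edges[:, 0], kmst.edges[:, 1]
    m = len(u)
    r_w = int(np.sum(labels[u] == labels[v]))

    sizes = np.bincount(pd.factorize(labels)[0]).astype(float)
    f2 = np.sum(sizes * (sizes - 1))
    f3 = np.sum(sizes * (sizes - 1) * (sizes - 2))
    f4 = np.sum(sizes * (sizes - 1) * (sizes - 2) * (sizes - 3))
    a2 = sizes * (sizes - 1)
    cross = np.sum(a2) ** 2 - np.sum(a2**2)

    nf2 = n * (n - 1)
    p2 = f2 / nf2
    e_rw = m * p2

    deg = np.bincount(np.concatenate([u, v]), minlength=n)
    s_shared = np.sum(deg * (deg - 1)) / 2.0  # unordered edge pairs sharing a node
    pairs_total = m * (m - 1) / 2.0
    s_disjoint = pairs_total - s_shared

    er2 = e_rw
    if s_shared > 0 and n >= 3:
        p3 = f3 / (nf2 * (n - 2))
        er2 += 2 * s_shared * p3
    if s_disjoint > 0 and n >= 4:
        p4 = (f4 + cross) / (nf2 * (n - 2) * (n - 3))
        er2 += 2 * s_disjoint * p4
    var_rw = er2 - e_rw**2
    if var_rw < 1e-9:
        return ZStatistic(r_w=r_w, e_rw=e_rw, var_rw=max(var_rw, 0.0), z=0.0,
                          degenerate=True)
    return ZStatistic(r_w=r_w, e_rw=e_rw, var_rw=var_rw,
                      z=(r_w - e_rw) / np.sqrt(var_rw), degenerate=False)


def select_resolution(
    embedding: Embedding,
    graph: NeighborGraph,
    grid: tuple[float, ...] = DEFAULT_GRID,
    k_mst: int = 5,
    seed: int = 0,
    kmst: KMSTGraph | None = None,
) -> ResolutionScan:
    """Scan resolutions, score each clustering on the K-MST, return the argmax-Z.

    Degenerate entries (single cluster / all singletons) are excluded from the
    argmax; ties go to the fewest clusters, then the lowest resolution.
    """
    if len(grid) == 0:
        raise ValueError("resolution grid is empty")
    if kmst is None:
        kmst = build_kmst(embedding, k=k_mst)
    rows = []
    results: list[ClusteringResult] = []
    for res in grid:
        cl = community_detect(graph, resolution=res, seed=seed)
        zs = within_edge_count_z(kmst, cl.labels)
        results.append(cl)
        rows.append(
            {
                "resolution": float(res),
                "n_clusters": cl.n_clusters,
                "r_w": zs.r_w,
                "e_rw": zs.e_rw,
                "var_rw": zs.var_rw,
                "z": zs.z,
                "degenerate": zs.degenerate,
            }
        )
    scan = pd.DataFrame(rows)
    ok = scan[~scan["degenerate"]]
    if ok.empty:
        raise ValueError(
            "every resolution gave a degenerate clustering (one cluster or all "
            "singletons); widen the resolution grid"
        )
    best = ok.sort_values(
        ["z", "n_clusters", "resolution"], ascending=[False, True, True]
    ).index[0]
    return ResolutionScan(
        scan=scan,
        selected_resolution=float(scan.loc[best, "resolution"]),
        selected=results[best],
        kmst=kmst,
    )


# ------------------------------------------------------------- marker panels

def score_marker_panels(
    adata: ad.AnnData, labels: np.ndarray, panels: dict[str, list[str]]
) -> pd.DataFrame:
    """Mean relative expression of each panel per cluster, plus an identity call.

    Expression is library-normalized; each gene is expressed relative to its
    overall mean, and a panel's score in a cluster is the mean over panel genes.
    The identity call is the panel with maximal score; exact ties are reported
    as 'tie:<a>|<b>', and clusters with no scorable panel as 'unassigned'.
    """
    X = _dense(adata.X).astype(float)
    lib = X.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    norm = X / lib
    overall = norm.mean(axis=0)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    name_to_col = {g: i for i, g in enumerate(adata.var_names)}

    panel_cols: dict[str, np.ndarray] = {}
    for name, genes_in in panels.items():
        cols = [name_to_col[g] for g in genes_in if g in name_to_col]
        if not cols:
            warnings.warn(f"panel '{name}' has no genes in the matrix", stacklevel=2)
            continue
        if len(cols) < len(genes_in):
            warnings.warn(
                f"panel '{name}': scoring over {len(cols)}/{len(genes_in)} genes "
                "present in the matrix",
                stacklevel=2,
            )
        panel_cols[name] = np.asarray(cols)

    rows = []
    for c in clusters:
        mask = labels == c
        cl_mean = norm[mask].mean(axis=0)
        scores = {}
        for name, cols in panel_cols.items():
            rel = cl_mean[cols] / np.maximum(overall[cols], 1e-12)
            scores[name] = float(rel.mean())
        if not scores:
            rows.append({"cluster": c, "identity": "unassigned", "margin": np.nan})
            continue
        ordered = sorted(scores.items(), key=lambda kv: -kv[1])
        if len(ordered) > 1 and ordered[0][1] == ordered[1][1]:
            identity = "tie:" + "|".join(
                sorted(n for n, s in ordered if s == ordered[0][1])
            )
            margin = 0.0
        else:
            identity = ordered[0][0]
            margin = ordered[0][1] - (ordered[1][1] if len(ordered) > 1 else 0.0)
        rows.append({"cluster": c, "identity": identity, "margin": margin, **scores})
    return pd.DataFrame(rows).set_index("cluster")
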