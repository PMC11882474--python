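import itertools

import numpy as np
import pytest

from mglia.cluster import (
    Embedding,
    KMSTGraph,
    build_kmst,
    build_snn_graph,
    community_detect,
    normalize_residuals,
    pca_embed,
    score_marker_panels,
    select_resolution,
    within_edge_count_z,
)


def _emb(coords):
    coords = np.asarray(coords, float)
    if coords.ndim == 1:
        coords = coords[:, None]
    return Embedding(ids=[str(i) for i in range(len(coords))], coords=coords,
                     variance_shares=np.array([]))


def brute_force_moments(edges, labels):
    """Exhaustive mean/variance of the within-cluster edge count over all
    distinct placements of the label multiset."""
    rs = []
    for perm in set(itertools.permutations(labels.tolist())):
        lab = np.array(perm)
        rs.append(int(np.sum(lab[edges[:, 0]] == lab[edges[:, 1]])))
    rs = np.array(rs, float)
    return rs.mean(), rs.var()


# ------------------------------------------------------------- residuals/PCA

def test_pearson_residuals_poisson_calibration():
    rng = np.random.default_rng(1)
    Y = rng.poisson(5.0, size=(3000, 20)).astype(float)
    r = normalize_residuals(Y, library_sizes=np.full(3000, 100.0))
    assert np.all(np.abs(r.var(axis=0) - 1.0) < 0.15)
    assert np.all(np.abs(r.mean(axis=0)) < 0.1)


def test_residuals_zero_gene_and_offset_invariance():
    rng = np.random.default_rng(2)
    Y = rng.poisson(3.0, size=(500, 10)).astype(float)
    Y[:, 0] = 0.0
    libs = np.full(500, 50.0)
    r1 = normalize_residuals(Y, library_sizes=libs)
    assert np.all(r1[:, 0] == 0)
    r2 = normalize_residuals(Y, library_sizes=2 * libs)
    assert np.allclose(r1, r2)


def test_pca_embed_properties():
    rng = np.random.default_rng(3)
    # rank-2 data
    U = rng.normal(size=(200, 2))
    V = rng.normal(size=(2, 40))
    X = U @ V
    emb = pca_embed(X, n_components=5)
    assert emb.variance_shares[2:].sum() < 1e-10
    assert np.all(np.diff(emb.variance_shares) <= 1e-12)
    # deterministic under re-run (sign convention fixed)
    emb2 = pca_embed(X, n_components=5)
    assert np.allclose(emb.coords, emb2.coords)
    with pytest.raises(ValueError):
        pca_embed(X, n_components=100)


# ----------------------------------------------------------------- SNN graph

def test_snn_identical_points_full_jaccard():
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(20, 3))
    pts[1] = pts[0]  # duplicate point: identical kNN sets
    g = build_snn_graph(_emb(pts), k=5)
    w = {tuple(e): wt for e, wt in zip(map(tuple, g.edges), g.weights)}
    assert w[(0, 1)] == 1.0


def test_snn_separated_blobs_no_cross_edges():
    rng = np.random.default_rng(5)
    a = rng.normal(size=(30, 2))
    b = rng.normal(size=(30, 2)) + 100.0
    g = build_snn_graph(_emb(np.vstack([a, b])), k=5)
    cross = (g.edges[:, 0] < 30) & (g.edges[:, 1] >= 30)
    assert cross.sum() == 0


def test_snn_k_too_large():
    with pytest.raises(ValueError):
        build_snn_graph(_emb(np.zeros((5, 2))), k=5)


def test_community_detect_disconnected_cliques_and_determinism():
    from mglia.cluster import NeighborGraph

    # two disconnected 10-cliques
    edges = []
    for base in (0, 10):
        edges += [(base + i, base + j) for i in range(10) for j in range(i + 1, 10)]
    edges = np.array(edges)
    g = NeighborGraph(n=20, edges=edges, weights=np.ones(len(edges)), k=9)
    r1 = community_detect(g, resolution=0.5, seed=0)
    r2 = community_detect(g, resolution=0.5, seed=0)
    assert r1.n_clusters == 2
    assert np.array_equal(r1.labels, r2.labels)
    # labels dense 0..K-1, size-ordered
    sizes = np.bincount(r1.labels)
    assert np.all(np.diff(sizes) <= 0)


# --------------------------------------------------------------------- K-MST

def test_kmst_counts_and_disjointness():
    rng = np.random.default_rng(7)
    pts = rng.normal(size=(10, 4))
    g = build_kmst(_emb(pts), k=3)
    assert len(g.edges) == 3 * 9
    assert len({tuple(e) for e in g.edges}) == 27


def test_kmst_near_exhaustion_and_failure():
    # K_n holds at most n/2 edge-disjoint spanning trees, and the greedy
    # orthogonal construction can fall short of even that bound; k far beyond
    # feasibility must fail loudly rather than return a deficient union.
    rng = np.random.default_rng(8)
    pts = rng.normal(size=(6, 3))
    g = build_kmst(_emb(pts), k=2)
    assert len(g.edges) == 2 * 5
    assert len({tuple(e) for e in g.edges}) == 10
    with pytest.raises(ValueError, match="disconnected"):
        build_kmst(_emb(pts), k=5)


def test_kmst_collinear_unique():
    g = build_kmst(_emb([0.0, 1.0, 3.0]), k=1)
    assert sorted(map(tuple, g.edges)) == [(0, 1), (1, 2)]


def test_kmst_duplicate_points_allowed():
    pts = np.zeros((6, 2))
    pts[3:] += 1.0
    g = build_kmst(_emb(pts), k=2)
    assert len(g.edges) == 2 * 5


# ------------------------------------------------------------- Z statistic

def test_zstat_path_graph_example():
    edges = np.array([[0, 1], [1, 2], [2, 3], [3, 4]])
    zs = within_edge_count_z(KMSTGraph(n=5, edges=edges, k=1),
                             np.array([1, 1, 1, 2, 2]))
    assert zs.r_w == 3
    assert zs.e_rw == pytest.approx(1.6)
    eb, vb = brute_force_moments(edges, np.array([1, 1, 1, 2, 2]))
    assert zs.e_rw == pytest.approx(eb, abs=1e-12)
    assert zs.var_rw == pytest.approx(vb, abs=1e-12)


def test_zstat_matches_enumeration_small_graphs():
    rng = np.random.default_rng(9)
    for _ in range(12):
        n = int(rng.integers(4, 9))
        pairs = list(itertools.combinations(range(n), 2))
        m = int(rng.integers(n - 1, len(pairs) + 1))
        edges = np.array([pairs[i] for i in rng.choice(len(pairs), m, replace=False)])
        labels = rng.integers(0, 3, n)
        if len(np.unique(labels)) < 2:
            labels[0] = (labels[0] + 1) % 3
        zs = within_edge_count_z(KMSTGraph(n=n, edges=edges, k=1), labels)
        eb, vb = brute_force_moments(edges, labels)
        assert zs.e_rw == pytest.approx(eb, abs=1e-10)
        assert zs.var_rw == pytest.approx(vb, abs=1e-10)


def test_zstat_degenerate_and_invariances():
    edges = np.array([[0, 1], [1, 2], [2, 3]])
    g = KMSTGraph(n=4, edges=edges, k=1)
    one = within_edge_count_z(g, np.zeros(4, dtype=int))
    assert one.degenerate and one.z == 0.0 and one.r_w == 3
    # relabeling invariance
    labels = np.array([0, 0, 1, 1])
    z1 = within_edge_count_z(g, labels)
    z2 = within_edge_count_z(g, 1 - labels)
    assert z1.z == pytest.approx(z2.z)
    # adding an edge inside a cluster raises R_W by exactly 1
    g2 = KMSTGraph(n=4, edges=np.vstack([edges, [0, 1]]), k=1)
    z3 = within_edge_count_z(g2, labels)
    assert z3.r_w == z1.r_w + 1


# -------------------------------------------------------- resolution selection

def test_select_resolution_grid_of_one(small_dataset):
    adata, _ = small_dataset
    resid = normalize_residuals(adata)
    emb = pca_embed(resid, n_components=10, ids=list(adata.obs_names))
    graph = build_snn_graph(emb, k=15)
    scan = select_resolution(emb, graph, grid=(0.3,), k_mst=3, seed=0)
    assert scan.selected_resolution == 0.3
    assert len(scan.scan) == 1


def test_select_resolution_recovers_planted_k(small_dataset):
    from sklearn.metrics import adjusted_rand_score

    adata, _ = small_dataset
    resid = normalize_residuals(adata)
    emb = pca_embed(resid, n_components=10, ids=list(adata.obs_names))
    graph = build_snn_graph(emb, k=15)
    scan = select_resolution(emb, graph, grid=(0.1, 0.3, 0.5, 0.8, 1.2), k_mst=5,
                             seed=0)
    assert scan.selected.n_clusters == 3
    assert adjusted_rand_score(adata.obs["true_cluster"],
                               scan.selected.labels) > 0.9


def test_empty_grid_rejected(small_dataset):
    adata, _ = small_dataset
    resid = normalize_residuals(adata)
    emb = pca_embed(resid, n_components=5, ids=list(adata.obs_names))
    graph = build_snn_graph(emb, k=10)
    with pytest.raises(ValueError):
        select_resolution(emb, graph, grid=())


# ------------------------------------------------------------- marker panels

def test_marker_panels_identity_call(small_dataset):
    adata, truth = small_dataset
    genes = truth.genes
    panels = {
        f"cluster{k}_panel": genes.loc[genes["marker_cluster"] == k, "gene"].tolist()
        for k in range(3)
    }
    res = score_marker_panels(adata, adata.obs["true_cluster"].to_numpy(), panels)
    for k in range(3):
        assert res.loc[k, "identity"] == f"cluster{k}_panel"
        assert res.loc[k, "margin"] > 0


def test_marker_panels_unassigned_and_tie(small_dataset):
    adata, _ = small_dataset
    labels = adata.obs["true_cluster"].to_numpy()
    with pytest.warns(UserWarning):
        res = score_marker_panels(adata, labels, {"ghost": ["NOPE1", "NOPE2"]})
    assert (res["identity"] == "unassigned").all()
    # identical panels tie
    g = list(adata.var_names[:5])
    res2 = score_marker_panels(adata, labels, {"a": g, "b": g})
    assert res2["identity"].str.startswith("tie:").all()
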