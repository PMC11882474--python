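import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mglia.de import (
    DesignSpec,
    de_test_all,
    estimate_dispersions,
    fit_nb_glm,
    fit_nb_glmm,
    gsea_preranked,
    ora_test,
    overlap_test,
    pseudo_mean_expression,
    storey_qvalues,
    wilcoxon_markers,
)
from mglia.syndata import SynthConfig, generate_dataset, simulate_nb_gene


def _design_stress():
    return DesignSpec(fixed="stress")


# -------------------------------------------------------------- dispersions

def test_dispersion_recovery_and_poisson_clamp():
    import anndata as ad
    import scipy.sparse as sp

    rng = np.random.default_rng(0)
    n = 2000
    libs = np.exp(rng.normal(np.log(2000), 0.4, n))
    obs = pd.DataFrame({
        "stress": np.repeat([0, 1], n // 2),
        "individual": [f"i{i % 12}" for i in range(n)],
    })
    # gene 0: NB theta=2; gene 1: Poisson
    mu = libs * 5e-4
    y_nb = rng.poisson(rng.gamma(2.0, mu / 2.0))
    y_pois = rng.poisson(mu)
    y_zero = np.zeros(n, dtype=np.int64)
    X = sp.csr_matrix(np.column_stack([y_nb, y_pois, y_zero]))
    adata = ad.AnnData(X=X, obs=obs,
                       var=pd.DataFrame(index=["nb", "pois", "zero"]))
    disp = estimate_dispersions(adata, _design_stress(),
                                offset=np.log(libs))
    assert 1.5 <= disp.loc["nb", "theta"] <= 2.7
    assert disp.loc["pois", "theta"] > 1e3  # at or near the Poisson clamp
    assert np.isinf(disp.loc["zero", "theta"]) and disp.loc["zero", "untestable"]


def test_dispersion_offset_invariance():
    rng = np.random.default_rng(1)
    d = simulate_nb_gene(beta=0.0, individual_sd=0.0, theta=3.0, seed=11)
    obs = pd.DataFrame({"stress": d["x"], "individual": d["individual"]})
    import anndata as ad
    import scipy.sparse as sp

    adata = ad.AnnData(X=sp.csr_matrix(d["y"][:, None]), obs=obs,
                       var=pd.DataFrame(index=["g"]))
    th1 = estimate_dispersions(adata, _design_stress(), offset=d["offset"])
    th2 = estimate_dispersions(adata, _design_stress(),
                               offset=d["offset"] + np.log(2.0))
    assert th1.loc["g", "theta"] == pytest.approx(th2.loc["g", "theta"], rel=0.05)


# ------------------------------------------------------------------- GLMM

def test_glmm_beta_recovery_and_coverage():
    """Planted log-2 group effect: near-unbiased estimates, ~95% CI coverage."""
    from scipy.stats import t as t_dist

    betas, cover = [], 0
    n_rep = 40
    for s in range(n_rep):
        d = simulate_nb_gene(beta=np.log(2), individual_sd=0.5, theta=2.0,
                             seed=2000 + s)
        X = np.column_stack([np.ones(len(d["y"])), d["x"]])
        r = fit_nb_glmm(d["y"], X, d["individual"], d["offset"], theta=2.0)
        betas.append(r.beta)
        crit = t_dist.ppf(0.975, 10)
        cover += r.beta - crit * r.se <= np.log(2) <= r.beta + crit * r.se
    assert abs(np.mean(betas) - np.log(2)) < 0.15
    assert cover / n_rep >= 0.85


def test_glmm_reduces_to_glm_without_donor_variance():
    d = simulate_nb_gene(beta=0.4, individual_sd=0.0, theta=3.0, seed=5)
    X = np.column_stack([np.ones(len(d["y"])), d["x"]])
    r = fit_nb_glmm(d["y"], X, d["individual"], d["offset"], theta=3.0)
    beta_glm, _ = fit_nb_glm(d["y"], X, d["offset"], theta=3.0)
    assert r.flag == "singular_refit"
    assert r.beta == pytest.approx(beta_glm[1], abs=1e-6)


def test_glmm_offset_invariance():
    d = simulate_nb_gene(beta=0.3, individual_sd=0.3, theta=2.0, seed=6)
    X = np.column_stack([np.ones(len(d["y"])), d["x"]])
    r1 = fit_nb_glmm(d["y"], X, d["individual"], d["offset"], theta=2.0)
    r2 = fit_nb_glmm(d["y"], X, d["individual"], d["offset"] + np.log(3.0),
                     theta=2.0)
    assert r1.beta == pytest.approx(r2.beta, abs=1e-5)
    assert r1.se == pytest.approx(r2.se, rel=1e-4)


def test_glmm_zero_gene_untestable():
    y = np.zeros(100)
    X = np.column_stack([np.ones(100), np.repeat([0, 1], 50)])
    r = fit_nb_glmm(y, X, np.repeat(np.arange(4), 25), np.zeros(100), theta=2.0)
    assert r.flag == "untestable" and np.isnan(r.beta)


def test_de_table_deterministic_and_contrast_checked(small_dataset):
    adata, _ = small_dataset
    sub = adata[:, :40].copy()
    t1 = de_test_all(sub, _design_stress())
    t2 = de_test_all(sub, _design_stress())
    pd.testing.assert_frame_equal(t1, t2)
    with pytest.raises(ValueError):
        de_test_all(sub, _design_stress(), contrast="wheel")


def test_ancova_design_coefficients(small_dataset):
    adata, _ = small_dataset
    spec = DesignSpec(fixed="ancova")
    X, names, _ = spec.build(adata.obs)
    assert names == ["Intercept", "stress", "distance", "stress:distance"]
    assert X.shape[1] == 4


# ------------------------------------------------------------------ Storey q

def test_storey_equals_bh_when_pi0_forced():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(2)
    for _ in range(10):
        p = rng.uniform(size=int(rng.integers(3, 400)))
        q, pi0 = storey_qvalues(p, pi0=1.0)
        assert pi0 == 1.0
        assert np.allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)


def test_storey_edge_cases():
    q, _ = storey_qvalues(np.ones(5))
    assert np.all(q == 1.0)
    q1, pi0 = storey_qvalues(np.array([0.01]))
    assert q1[0] == pytest.approx(pi0 * 0.01)
    with pytest.raises(ValueError):
        storey_qvalues(np.array([-0.1]))


@settings(max_examples=25, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=2, max_size=60))
def test_storey_q_monotone_in_p(pvals):
    p = np.asarray(pvals)
    q, _ = storey_qvalues(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)
    assert np.all((q >= 0) & (q <= 1))


# ------------------------------------------------------------- rank tests

def test_wilcoxon_shift_detected_and_ties(small_dataset):
    import anndata as ad
    import scipy.sparse as sp

    rng = np.random.default_rng(3)
    base = rng.poisson(5.0, size=(200, 3))
    base[:100, 0] += 6  # shifted gene in group A
    adata = ad.AnnData(X=sp.csr_matrix(base),
                       var=pd.DataFrame(index=["shift", "null1", "null2"]))
    res = wilcoxon_markers(adata, np.arange(100), np.arange(100, 200))
    assert res.loc["shift", "p"] < 0.05
    assert res.loc["shift", "log2fc"] > 0
    # saturation: all ties -> p = 1
    tied = ad.AnnData(X=sp.csr_matrix(np.full((6, 2), 4)),
                      var=pd.DataFrame(index=["a", "b"]))
    res2 = wilcoxon_markers(tied, [0, 1, 2], [3, 4, 5])
    assert np.all(res2["p"] == 1.0)


def test_pseudo_mean_expression_identities(small_dataset):
    adata, _ = small_dataset
    pm = pseudo_mean_expression(adata)
    assert pm.shape == (adata.obs["individual"].nunique(), adata.n_vars)
    # single-nucleus individual: row equals that nucleus's corrected vector
    one = adata[:1].copy()
    one.obs["individual"] = ["solo"]
    pm1 = pseudo_mean_expression(one)
    x = one.X.toarray()[0]
    lib = x.sum()
    np.testing.assert_allclose(pm1.loc["solo"].to_numpy(),
                               np.log1p(x / lib * lib))


# ----------------------------------------------------------- overlap / ORA

def test_overlap_test_exact_values():
    assert overlap_test(["a", "b"], ["c", "d"], 10) == 1.0
    u = [f"g{i}" for i in range(20)]
    assert overlap_test(u, u, 20) == 1.0
    p = overlap_test(u[:5], u[:3] + [u[6]], 20)
    assert p == pytest.approx(155 / 4845, rel=1e-12)


def test_ora_matches_hypergeometric_oracle():
    u = [f"g{i}" for i in range(20)]
    res = ora_test(u[:3] + [u[6]], {"setA": u[:5]}, u)
    assert res.loc[0, "p"] == pytest.approx(155 / 4845, rel=1e-12)
    assert res.loc[0, "gene_ratio"] == pytest.approx(3 / 4)
    assert res.loc[0, "count"] == 3
    # saturating input: every set gets p = 1
    res2 = ora_test(u, {"setA": u[:5]}, u)
    assert np.all(res2["p"] == 1.0)
    # duplicates deduplicated
    res3 = ora_test((u[:3] + [u[6]]) * 2, {"setA": u[:5]}, u)
    assert res3.loc[0, "count"] == 3


# ----------------------------------------------------------------- GSEA

def test_gsea_top_set_activated_and_antisymmetry():
    stats = pd.Series(np.linspace(3, -3, 500),
                      index=[f"g{i}" for i in range(500)])
    top = [f"g{i}" for i in range(15)]
    res = gsea_preranked(stats, {"top": top}, n_perm=300, seed=0)
    assert res.loc[0, "es"] > 0.9
    assert res.loc[0, "direction"] == "activated"
    assert res.loc[0, "p"] < 0.05
    res_neg = gsea_preranked(-stats, {"top": top}, n_perm=300, seed=0)
    assert res_neg.loc[0, "es"] == pytest.approx(-res.loc[0, "es"])
    assert res_neg.loc[0, "direction"] == "suppressed"


def test_gsea_es_cross_checked_against_gseapy():
    gseapy = pytest.importorskip("gseapy")
    rng = np.random.default_rng(4)
    stats = pd.Series(np.sort(rng.normal(size=300))[::-1],
                      index=[f"g{i}" for i in range(300)])
    members = [f"g{i}" for i in rng.choice(300, 25, replace=False)]
    mine = gsea_preranked(stats, {"s": members}, n_perm=50, seed=0).loc[0, "es"]
    ref = gseapy.prerank(
        rnk=stats.reset_index().rename(columns={"index": "gene", 0: "score"}),
        gene_sets={"s": members}, permutation_num=10, min_size=2,
        max_size=500, seed=1, outdir=None, no_plot=True, verbose=False,
    ).res2d
    assert mine == pytest.approx(float(ref["ES"].iloc[0]), abs=1e-6)
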