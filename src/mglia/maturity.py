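"""Transcriptional-diversity maturity scoring and mixed-model cluster comparison.

The score follows the principle that less differentiated cells express a
broader set of genes: each nucleus's detected-gene count is correlated
gene-by-gene with log-normalized expression, the most diversity-associated
genes form a signature, and the rank-normalized mean signature expression is
the score.  Scores lie in [0, 1]; higher = more transcriptional diversity =
less differentiated.  (The usual published description of such scores states
both poles as "mature" at one point; this implementation follows the diversity
principle: broad expression scores high and is read as immature.)

Cluster comparisons use a Gaussian linear mixed model with the cluster as the
fixed effect and the individual as a random intercept, so cluster effects are
estimated while accounting for donor-to-donor variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = ["MaturityTable", "LMMEffect", "maturity_score", "compare_maturity",
           "fit_gaussian_lmm"]


@dataclass
class MaturityTable:
    table: pd.DataFrame  # barcode, score, detected_genes, individual, cluster
    signature_genes: list[str]


@dataclass
class LMMEffect:
    contrast: str
    beta: float
    se: float
    p: float
    random_intercept_var: float
    residual_var: float
    converged: bool = True


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def maturity_score(
    adata: ad.AnnData,
    n_signature_genes: int = 200,
    smooth_knn: int = 0,
    cluster_labels: np.ndarray | None = None,
) -> MaturityTable:
    """Score each nucleus's transcriptional diversity on [0, 1].

    Pipeline: detected-gene count per nucleus; per-gene Pearson correlation of
    log-normalized expression with that count; signature = top
    ``n_signature_genes`` by correlation; raw score = mean signature
    log-normalized expression; optional kNN smoothing in PCA space; final score
    = empirical CDF (midrank) of the raw score.
    """
    X = _dense(adata.X).astype(float)
    n, g = X.shape
    if n_signature_genes > g:
        warnings.warn(
            f"n_signature_genes = {n_signature_genes} exceeds {g} genes; capped",
            stacklevel=2,
        )
        n_signature_genes = g
    detected = (X > 0).sum(axis=1).astype(float)
    lib = X.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    lognorm = np.log1p(X / lib * np.median(lib))

    # per-gene Pearson correlation with the detected-gene count
    dc = detected - detected.mean()
    gc = lognorm - lognorm.mean(axis=0, keepdims=True)
    num = dc @ gc
    den = np.sqrt((dc**2).sum()) * np.sqrt((gc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(den > 0, num / den, 0.0)
    top = np.argsort(-corr, kind="stable")[:n_signature_genes]
    raw = lognorm[:, top].mean(axis=1)

    if smooth_knn > 0 and n > smooth_knn:
        n_comp = min(30, n - 1, g)
        coords = PCA(n_components=n_comp, random_state=0).fit_transform(lognorm)
        _, idx = NearestNeighbors(n_neighbors=smooth_knn).fit(coords).kneighbors(coords)
        raw = raw[idx].mean(axis=1)

    score = (rankdata(raw, method="average") - 1) / (n - 1) if n > 1 else np.array([0.5])
    # all-tie degenerate input: midranks put every nucleus at 0.5
    table = pd.DataFrame(
        {
            "barcode": adata.obs_names,
            "score": score,
            "detected_genes": detected.astype(int),
            "individual": adata.obs["individual"].values
            if "individual" in adata.obs
            else "na",
        }
    )
    table["cluster"] = (
        np.asarray(cluster_labels)
        if cluster_labels is not None
        else adata.obs.get("cluster", pd.Series(["na"] * n, index=adata.obs_names)).values
    )
    return MaturityTable(table=table, signature_genes=list(adata.var_names[top]))


def fit_gaussian_lmm(
    data: pd.DataFrame,
    response: str,
    fixed: str,
    group: str = "individual",
    reference: object | None = None,
) -> list[LMMEffect]:
    """Gaussian LMM: response ~ C(fixed, ref) + (1 | group), REML, Wald tests.

    Returns one effect per non-reference level of the fixed factor.  Shared by
    the maturity and state-score comparisons.
    """
    import statsmodels.formula.api as smf

    df = data[[response, fixed, group]].copy()
    df.columns = ["y", "f", "g"]
    df["f"] = df["f"].astype(str)
    levels = sorted(df["f"].unique())
    if len(levels) < 2:
        raise ValueError(f"fixed factor '{fixed}' has a single level; no contrast")
    ref = str(reference) if reference is not None else levels[0]
    # warn about factor levels confined to one group (partial confounding)
    for lev in levels:
        if df.loc[df["f"] == lev, "g"].nunique() == 1:
            warnings.warn(
                f"level '{lev}' of '{fixed}' occurs in a single '{group}'; the "
                "fixed effect and the random intercept are partially confounded",
                stacklevel=2,
            )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(f"y ~ C(f, Treatment(reference='{ref}'))", df, groups=df["g"])
        fit = model.fit(reml=True, method=["lbfgs", "bfgs"])
    effects = []
    re_var = float(np.asarray(fit.cov_re)[0, 0])
    for name in fit.fe_params.index:
        if name == "Intercept":
            continue
        lev = name.split("[T.")[-1].rstrip("]")
        effects.append(
            LMMEffect(
                contrast=f"{lev} vs {ref}",
                beta=float(fit.fe_params[name]),
                se=float(fit.bse[name]),
                p=float(min(max(fit.pvalues[name], np.nextafter(0, 1)), 1.0)),
                random_intercept_var=re_var,
                residual_var=float(fit.scale),
                converged=bool(fit.converged),
            )
        )
    return effects


def compare_maturity(table: MaturityTable, reference_cluster: object) -> list[LMMEffect]:
    """Mixed-model comparison of maturity scores across clusters vs a reference."""
    return fit_gaussian_lmm(
        table.table, response="score", fixed="cluster", group="individual",
        reference=reference_cluster,
    )
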