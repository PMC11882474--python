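"""Differential expression and enrichment.

Per-gene counts are modeled with a negative-binomial mixed model: the log mean
is a linear predictor over treatment terms plus a per-individual random
intercept, with the log library size as an offset, so the many nuclei sampled
from one animal do not masquerade as independent replicates:

    y_ic ~ NB(mu_ic, theta_g),   log mu_ic = log L_c + x_c' beta + b_i,
    b_i ~ N(0, sigma^2).

Dispersions theta_g are estimated once per gene from a Gamma-Poisson fit with
fixed effects only, then held fixed while the mixed model is fit by Laplace
approximation.  Wald tests on the contrast coefficient use a t reference with
df = (number of individuals - rank of the between-individual design), which
keeps the test calibrated when the donor-level information, not the nucleus
count, limits precision.  FDR control across genes uses Storey q-values.

Also here: Wilcoxon rank-sum marker tests, per-individual mean corrected
expression (the input of the mediation screen), hypergeometric overlap tests,
Fisher over-representation over user-supplied GMT sets, and preranked GSEA
with a gene-label permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import fisher_exact, hypergeom, mannwhitneyu
from scipy.stats import t as t_dist

__all__ = [
    "DesignSpec",
    "GLMMRow",
    "estimate_dispersions",
    "fit_nb_glm",
    "fit_nb_glmm",
    "de_test_all",
    "storey_qvalues",
    "wilcoxon_markers",
    "pseudo_mean_expression",
    "overlap_test",
    "ora_test",
    "gsea_preranked",
]

THETA_MAX = 1e6
THETA_MIN = 1e-3


# ------------------------------------------------------------------- designs

@dataclass
class DesignSpec:
    """Fixed-effect design over barcode metadata, with individual random intercept.

    ``fixed`` is one of ``"stress"``, ``"wheel"``, ``"2x2"`` (stress + wheel +
    interaction), ``"distance"`` (a running-distance covariate, standardized),
    or ``"ancova"`` (stress + distance + stress x distance).  ``contrast``
    names the tested coefficient and defaults to the design's primary term.
    """

    fixed: str = "stress"
    distance_col: str = "dist_40d"
    contrast: str | None = None

    _COLUMNS = {
        "stress": ["Intercept", "stress"],
        "wheel": ["Intercept", "wheel"],
        "2x2": ["Intercept", "stress", "wheel", "stress:wheel"],
        "distance": ["Intercept", "distance"],
        "ancova": ["Intercept", "stress", "distance", "stress:distance"],
    }
    _DEFAULT_CONTRAST = {
        "stress": "stress",
        "wheel": "wheel",
        "2x2": "stress",
        "distance": "distance",
        "ancova": "stress",
    }

    def __post_init__(self) -> None:
        if self.fixed not in self._COLUMNS:
            raise ValueError(f"unknown design '{self.fixed}'")
        if self.contrast is None:
            self.contrast = self._DEFAULT_CONTRAST[self.fixed]
        if self.contrast not in self._COLUMNS[self.fixed]:
            raise ValueError(
                f"contrast '{self.contrast}' not in design {self._COLUMNS[self.fixed]}"
            )

    def build(self, obs: pd.DataFrame) -> tuple[np.ndarray, list[str], np.ndarray]:
        """Return (X, column names, individual codes) for a barcode table."""
        n = len(obs)
        cols: dict[str, np.ndarray] = {"Intercept": np.ones(n)}
        if self.fixed in ("stress", "2x2", "ancova"):
            cols["stress"] = obs["stress"].to_numpy(float)
        if self.fixed in ("wheel", "2x2"):
            cols["wheel"] = obs["wheel"].to_numpy(float)
        if self.fixed in ("distance", "ancova"):
            d = obs[self.distance_col].to_numpy(float)
            sd = d.std()
            cols["distance"] = (d - d.mean()) / (sd if sd > 0 else 1.0)
        if self.fixed == "2x2":
            cols["stress:wheel"] = cols["stress"] * cols["wheel"]
        if self.fixed == "ancova":
            cols["stress:distance"] = cols["stress"] * cols["distance"]
        names = self._COLUMNS[self.fixed]
        X = np.column_stack([cols[c] for c in names])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient for these barcodes")
        individuals = pd.factorize(obs["individual"])[0]
        return X, names, individuals


@dataclass
class GLMMRow:
    beta: float
    se: float
    stat: float
    p: float
    sigma2: float
    converged: bool
    flag: str = ""
    coefs: dict = field(default_factory=dict)


# ------------------------------------------------- NB likelihood and GLM fit

def _nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    # constant-in-mu terms dropped (theta fixed per gene)
    return float(np.sum(y * np.log(mu) - (y + theta) * np.log(mu + theta))
                 + len(y) * theta * np.log(theta))


def fit_nb_glm(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, theta: float,
    max_iter: int = 50, tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """NB regression with log link, fixed dispersion; returns (beta, cov_beta)."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-8)) - np.log(np.exp(offset).mean())
    for _ in range(max_iter):
        eta = offset + X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + mu / theta)  # mu^2 / (mu + mu^2/theta)
        z = (eta - offset) + (y - mu) / mu
        WX = X * w[:, None]
        H = X.T @ WX
        g = WX.T @ z
        new = np.linalg.solve(H + 1e-10 * np.eye(p), g)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    eta = offset + X @ beta
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu / (1.0 + mu / theta)
    cov = np.linalg.inv(X.T @ (X * w[:, None]) + 1e-10 * np.eye(p))
    return beta, cov


def _theta_mle(y: np.ndarray, mu: np.ndarray) -> float:
    """Profile ML of the NB size parameter for fixed means."""
    def nll(log_theta: float) -> float:
        th = np.exp(log_theta)
        return -float(
            np.sum(
                gammaln(y + th) - gammaln(th)
                + th * np.log(th / (th + mu))
                + y * np.log(mu / (th + mu))
            )
        )
    res = minimize_scalar(nll, bounds=(np.log(THETA_MIN), np.log(THETA_MAX)),
                          method="bounded", options={"xatol": 1e-3})
    return float(np.exp(res.x))


def estimate_dispersions(
    adata_or_counts, design: DesignSpec, obs: pd.DataFrame | None = None,
    offset: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene Gamma-Poisson dispersion with fixed-effect means and log-library offset.

    The random effect is ignored at this stage; theta is clamped to
    [1e-3, 1e6] and all-zero genes get a +inf sentinel with an untestable flag.
    """
    if isinstance(adata_or_counts, ad.AnnData):
        Y = adata_or_counts.X.toarray() if sp.issparse(adata_or_counts.X) else np.asarray(adata_or_counts.X)
        obs = adata_or_counts.obs
        genes = list(adata_or_counts.var_names)
    else:
        Y = np.asarray(adata_or_counts)
        genes = [f"g{i}" for i in range(Y.shape[1])]
    if offset is None:
        offset = np.log(np.maximum(Y.sum(axis=1), 1.0))
    X, _, _ = design.build(obs)
    rows = []
    for j in range(Y.shape[1]):
        y = Y[:, j].astype(float)
        if y.sum() == 0:
            rows.append({"gene": genes[j], "theta": np.inf, "untestable": True})
            continue
        # Poisson start (theta large), one alternation of (beta | theta)
        beta, _ = fit_nb_glm(y, X, offset, theta=THETA_MAX)
        mu = np.exp(np.clip(offset + X @ beta, -30, 30))
        th = _theta_mle(y, mu)
        beta, _ = fit_nb_glm(y, X, offset, theta=th)
        mu = np.exp(np.clip(offset + X @ beta, -30, 30))
        th = _theta_mle(y, mu)
        rows.append({"gene": genes[j], "theta": th, "untestable": False})
    out = pd.DataFrame(rows).set_index("gene")
    out.attrs["method"] = "gamma-poisson profile ML, fixed effects only"
    return out


# ----------------------------------------------------------------- NB GLMM

def _between_df(X: np.ndarray, groups: np.ndarray) -> int:
    """Residual df at the individual level: J - rank of the individual-mean design."""
    J = int(groups.max()) + 1
    U = np.vstack([X[groups == j].mean(axis=0) for j in range(J)])
    return max(J - np.linalg.matrix_rank(U), 1)


def fit_nb_glmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    offset: np.ndarray,
    theta: float,
    contrast_idx: int = 1,
    names: list[str] | None = None,
    max_iter: int = 200,
) -> GLMMRow:
    """Laplace-REML fit of the NB random-intercept model.

    The variance component is profiled on a Laplace criterion with the fixed
    effects integrated out through the Schur complement of the joint
    information, which keeps sigma^2 (and hence Wald SEs) unbiased at small
    donor counts.  ``groups`` are 0..J-1 individual codes.  Non-convergence
    is flagged with a p = 1 sentinel; a boundary fit (sigma^2 -> 0) falls
    back to the fixed-effects NB GLM with a 'singular_refit' flag.
    """
    y = np.asarray(y, float)
    if y.sum() == 0 or not np.isfinite(theta):
        return GLMMRow(beta=np.nan, se=np.nan, stat=np.nan, p=np.nan, sigma2=np.nan,
                       converged=False, flag="untestable")
    n, p = X.shape
    J = int(groups.max()) + 1
    df = _between_df(X, groups)

    beta0, _ = fit_nb_glm(y, X, offset, theta)
    mu0 = np.exp(np.clip(offset + X @ beta0, -30, 30))
    # crude per-group log-ratio for variance init
    sum_y = np.bincount(groups, weights=y, minlength=J)
    sum_mu = np.bincount(groups, weights=mu0, minlength=J)
    b_init = np.log((sum_y + 0.5) / (sum_mu + 0.5))
    sigma2_init = float(np.clip(np.var(b_init), 1e-3, 4.0))

    b_hat = np.zeros(J)
    Ip = 1e-10 * np.eye(p)

    def joint_mode(beta_start: np.ndarray, sigma2: float):
        """Joint (beta, b) mode by Newton with block elimination.

        The (p + J) Newton system is solved through the Schur complement
        S = X'WX - A diag(1/h) A' with A = X'WZ, which is also cov(beta)^-1
        at the mode.  Returns (beta, b, h, S).
        """
        beta = beta_start.copy()
        b = b_hat.copy()
        S = None
        h = None
        for _ in range(60):
            mu = np.exp(np.clip(offset + X @ beta + b[groups], -30, 30))
            score_i = y - (y + theta) * mu / (mu + theta)
            w = (y + theta) * theta * mu / (mu + theta) ** 2
            g_beta = X.T @ score_i
            g_b = np.bincount(groups, weights=score_i, minlength=J) - b / sigma2
            h = np.bincount(groups, weights=w, minlength=J) + 1.0 / sigma2
            A = np.vstack(
                [np.bincount(groups, weights=w * X[:, a], minlength=J)
                 for a in range(p)]
            )
            S = X.T @ (X * w[:, None]) - (A / h) @ A.T + Ip
            try:
                d_beta = np.linalg.solve(S, g_beta - A @ (g_b / h))
            except np.linalg.LinAlgError:
                break
            d_b = (g_b - A.T @ d_beta) / h
            step = max(np.max(np.abs(d_beta)), np.max(np.abs(d_b)))
            if step > 2.0:
                d_beta *= 2.0 / step
                d_b *= 2.0 / step
            beta += d_beta
            b += d_b
            if step < 1e-9:
                break
        b_hat[:] = b  # warm start for the next variance value
        return beta, b, h, S

    beta_cur = beta0.copy()

    def profiled(log_sigma2: float):
        """Laplace-REML criterion at one variance value (beta, b profiled out)."""
        nonlocal beta_cur
        sigma2 = float(np.exp(log_sigma2))
        beta, b, h, S = joint_mode(beta_cur, sigma2)
        beta_cur = beta
        mu = np.exp(np.clip(offset + X @ beta + b[groups], -30, 30))
        ll = _nb_loglik(y, mu, theta)
        ll -= 0.5 * np.sum(b**2) / sigma2 + 0.5 * J * np.log(sigma2)
        ll -= 0.5 * np.sum(np.log(h))
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            return np.inf, beta, S
        return -ll + 0.5 * logdet, beta, S

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        opt = minimize_scalar(lambda ls: profiled(ls)[0],
                              bounds=(np.log(1e-8), np.log(25.0)),
                              method="bounded", options={"xatol": 1e-3})
    sigma2 = float(np.exp(opt.x))
    if sigma2 < 1e-6:
        beta, cov = fit_nb_glm(y, X, offset, theta)
        se = float(np.sqrt(cov[contrast_idx, contrast_idx]))
        stat = beta[contrast_idx] / se
        pval = float(2 * t_dist.sf(abs(stat), df))
        return GLMMRow(beta=float(beta[contrast_idx]), se=se, stat=float(stat),
                       p=pval, sigma2=0.0, converged=True, flag="singular_refit",
                       coefs=_coef_dict(beta, np.sqrt(np.diag(cov)), df, names))
    _, beta_hat, S = profiled(opt.x)
    try:
        cov = np.linalg.inv(S)
        se_all = np.sqrt(np.maximum(np.diag(cov), 0.0))
        se = float(se_all[contrast_idx])
        if not (np.isfinite(se) and se > 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        return GLMMRow(beta=float(beta_hat[contrast_idx]), se=np.nan, stat=np.nan,
                       p=1.0, sigma2=sigma2, converged=False, flag="singular_hessian")
    beta_c = float(beta_hat[contrast_idx])
    stat = beta_c / se
    pval = float(2 * t_dist.sf(abs(stat), df))
    return GLMMRow(beta=beta_c, se=se, stat=float(stat), p=pval, sigma2=sigma2,
                   converged=bool(opt.success), flag="" if opt.success else "nonconverged",
                   coefs=_coef_dict(beta_hat, se_all, df, names))


def _coef_dict(beta, se, df, names) -> dict:
    if names is None:
        names = [f"b{i}" for i in range(len(beta))]
    out = {}
    for nm, b, s in zip(names, beta, se):
        pv = float(2 * t_dist.sf(abs(b / s), df)) if s > 0 else np.nan
        out[nm] = {"beta": float(b), "se": float(s), "p": pv}
    return out


def de_test_all(
    adata: ad.AnnData,
    design: DesignSpec,
    contrast: str | None = None,
    min_detection: float = 0.01,
    dispersions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene NB GLMM over genes passing the detection filter, with Storey q.

    Non-convergent genes are flagged and excluded from the q-value computation
    so the FDR denominator counts only testable genes.
    """
    contrast = contrast or design.contrast
    X, names, groups = design.build(adata.obs)
    if contrast not in names:
        raise ValueError(f"contrast '{contrast}' absent from design {names}")
    cidx = names.index(contrast)
    Y = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
    lib = Y.sum(axis=1)
    offset = np.log(np.maximum(lib, 1.0))
    det = (Y > 0).mean(axis=0)
    tested = det >= min_detection
    if dispersions is None:
        disp_in = ad.AnnData(
            X=sp.csr_matrix(Y[:, tested]), obs=adata.obs,
            var=pd.DataFrame(index=adata.var_names[tested]),
        )
        dispersions = estimate_dispersions(disp_in, design, offset=offset)
    rows = []
    mean_expr = Y.mean(axis=0)
    for j, gene in enumerate(adata.var_names):
        if not tested[j]:
            rows.append({"gene": gene, "contrast": contrast, "beta": np.nan,
                         "se": np.nan, "stat": np.nan, "p": np.nan, "q": np.nan,
                         "mean_expr": mean_expr[j], "flag": "low_detection",
                         "converged": False})
            continue
        th = float(dispersions.loc[gene, "theta"])
        fit = fit_nb_glmm(Y[:, j], X, groups, offset, th, contrast_idx=cidx,
                          names=names)
        rows.append({"gene": gene, "contrast": contrast, "beta": fit.beta,
                     "se": fit.se, "stat": fit.stat, "p": fit.p, "q": np.nan,
                     "mean_expr": mean_expr[j], "flag": fit.flag,
                     "converged": fit.converged})
    table = pd.DataFrame(rows).set_index("gene")
    ok = table["converged"] & table["p"].notna()
    if ok.any():
        q, pi0 = storey_qvalues(table.loc[ok, "p"].to_numpy())
        table.loc[ok, "q"] = q
        table.attrs["pi0"] = pi0
    table["direction"] = np.where(table["beta"] > 0, "up", "down")
    table.loc[table["beta"].isna(), "direction"] = "na"
    return table


# -------------------------------------------------------------- Storey q

def storey_qvalues(
    pvals: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    pi0: float | None = None,
) -> tuple[np.ndarray, float]:
    """Storey q-values with the smoother estimate of pi0 over a lambda grid.

    Forcing ``pi0 = 1`` reproduces Benjamini-Hochberg adjusted p-values exactly.
    Returns (q, pi0_hat); q is monotone in p and bounded by 1.
    """
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p.copy(), 1.0
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        lam = (np.arange(0.05, 0.96, 0.05)
               if lambda_grid is None else np.asarray(lambda_grid, float))
        pi0_lam = np.array([np.mean(p > l) / (1 - l) for l in lam])
        if np.all(pi0_lam == 0):
            pi0 = float(min(1.0, 2 * np.mean(p)))  # all p tiny: effectively 0 nulls
        else:
            # cubic smoother evaluated at the largest lambda (Storey & Tibshirani)
            coef = np.polyfit(lam, pi0_lam, deg=3)
            pi0 = float(np.clip(np.polyval(coef, lam.max()), 0.0, 1.0))
        if pi0 <= 0:
            pi0 = float(max(np.min(pi0_lam[pi0_lam > 0], initial=1e-3), 1e-3))
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_ranked = pi0 * m * ranked / np.arange(1, m + 1)
    q_ranked = np.minimum.accumulate(q_ranked[::-1])[::-1]
    q_ranked = np.minimum(q_ranked, 1.0)
    q = np.empty(m)
    q[order] = q_ranked
    return q, float(pi0)


# ------------------------------------------------------- nonparametric tests

def wilcoxon_markers(
    adata: ad.AnnData, cells_a: np.ndarray, cells_b: np.ndarray
) -> pd.DataFrame:
    """Wilcoxon rank-sum marker table between two nucleus groups.

    Normal-approximation p with tie correction on log-normalized expression;
    genes with all-tied values get p = 1.  log2 fold change compares
    library-normalized means.
    """
    X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
    lib = X.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    norm = X / lib * np.median(lib)
    A = norm[np.asarray(cells_a)]
    B = norm[np.asarray(cells_b)]
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = mannwhitneyu(A, B, alternative="two-sided", axis=0,
                               method="asymptotic")
    p = np.where(np.isfinite(p), p, 1.0)
    eps = 1e-9
    log2fc = np.log2((A.mean(axis=0) + eps) / (B.mean(axis=0) + eps))
    return pd.DataFrame(
        {"statistic": stat, "p": p, "log2fc": log2fc}, index=adata.var_names
    )


def pseudo_mean_expression(
    adata: ad.AnnData, individual_col: str = "individual"
) -> pd.DataFrame:
    """Individual x gene matrix of mean library-corrected expression.

    Each nucleus is depth-corrected (counts / library * median library, then
    log1p) and averaged within individuals; this is the unit of the mediation
    analyses.
    """
    X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
    lib = X.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    corrected = np.log1p(X / lib * np.median(lib))
    df = pd.DataFrame(corrected, index=adata.obs[individual_col].values,
                      columns=adata.var_names)
    return df.groupby(level=0).mean()


def overlap_test(list_a, list_b, universe_size: int) -> float:
    """Upper-tail hypergeometric p for the overlap of two gene lists."""
    a = set(list_a)
    b = set(list_b)
    k = len(a & b)
    return float(hypergeom.sf(k - 1, universe_size, len(a), len(b)))


def ora_test(
    de_genes, gmt_sets: dict[str, list[str]], universe
) -> pd.DataFrame:
    """One-sided Fisher over-representation of each GMT set in a DE list.

    GeneRatio is hits / input genes (restricted to the universe); FDR across
    sets is Benjamini-Hochberg.  Sets with no universe overlap are dropped
    with a warning.
    """
    from statsmodels.stats.multitest import multipletests

    uni = set(universe)
    de = list(dict.fromkeys(g for g in de_genes if g in uni))
    n_uni, n_de = len(uni), len(de)
    rows = []
    for name, genes_in in gmt_sets.items():
        s = set(genes_in) & uni
        if not s:
            warnings.warn(f"set '{name}' has no genes in the universe; dropped",
                          stacklevel=2)
            continue
        k = len(s & set(de))
        table = [[k, n_de - k], [len(s) - k, n_uni - n_de - len(s) + k]]
        _, p = fisher_exact(table, alternative="greater")
        rows.append({"set": name, "gene_ratio": k / max(n_de, 1), "count": k,
                     "set_size": len(s), "p": float(p)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


# ------------------------------------------------------------ preranked GSEA

def _es_from_positions(pos: np.ndarray, w_abs: np.ndarray, n: int) -> float:
    """Weighted KS enrichment score given sorted hit positions (0-based)."""
    s = len(pos)
    order = np.argsort(pos)
    pos = pos[order]
    w = w_abs[order]
    W = w.sum()
    if W <= 0:
        w = np.ones(s)
        W = float(s)
    hit_cum = np.cumsum(w) / W
    miss_after = (pos + 1 - np.arange(1, s + 1)) / (n - s)
    miss_before = (pos - np.arange(s)) / (n - s)
    dev_after = hit_cum - miss_after
    dev_before = np.concatenate([[0.0], hit_cum[:-1]]) - miss_before
    hi = dev_after.max()
    lo = dev_before.min()
    return float(hi if hi >= -lo else lo)


def gsea_preranked(
    ranked_stats: pd.Series,
    gmt_sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Preranked GSEA: weighted running-sum ES with a gene-label permutation null.

    NES = ES / mean(|null ES| of the matching sign); a positive NES marks the
    set as activated (members concentrated at the top of the ranking), a
    negative NES as suppressed.  Empirical p uses the matching-sign null.
    """
    rng = np.random.default_rng(seed)
    stats = ranked_stats.sort_values(ascending=False)
    genes_arr = np.asarray(stats.index)
    vals = stats.to_numpy(float)
    n = len(genes_arr)
    pos_of = {g: i for i, g in enumerate(genes_arr)}
    w_all = np.abs(vals) ** weight
    rows = []
    for name, members in gmt_sets.items():
        pos = np.array(sorted(pos_of[g] for g in set(members) if g in pos_of))
        s = len(pos)
        if s == 0 or s == n:
            warnings.warn(f"set '{name}' empty or saturating after intersection",
                          stacklevel=2)
            continue
        es = _es_from_positions(pos, w_all[pos], n)
        null = np.empty(n_perm)
        for b in range(n_perm):
            rpos = rng.choice(n, size=s, replace=False)
            null[b] = _es_from_positions(rpos, w_all[rpos], n)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if len(same) == 0:
            nes, p = np.nan, 1.0 / (n_perm + 1)
        else:
            nes = es / np.mean(np.abs(same))
            p = (1 + np.sum(np.abs(same) >= abs(es))) / (1 + len(same))
        rows.append({"set": name, "size": s, "es": es, "nes": nes, "p": float(p),
                     "direction": "activated" if es > 0 else "suppressed"})
    out = pd.DataFrame(rows)
    if not out.empty:
        from statsmodels.stats.multitest import multipletests

        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
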