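"""Activation-state scores, composition tests and up/down goodness of fit.

M1 (proinflammatory), M2 (anti-inflammatory) and metabolism scores are raw
transcript-count ratios: the sum of counts over a predefined gene set divided
by the nucleus's total counts.  Being ratios they are invariant to sequencing
depth, and the all-genes set scores exactly 1.  Group/subcluster comparisons of
the scores reuse the Gaussian mixed model (individual random intercept) shared
with the maturity analysis.

Composition analyses test subcluster x group contingency tables with Pearson's
chi-square (no continuity correction) and pairwise two-sided Fisher exact
tests at alpha = 0.05.  The up/down goodness-of-fit statistic for a DEG list is
the 1-df chi-square against a 50:50 split: (n_up - n_down)^2 / (n_up + n_down).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import chi2, chi2_contingency, fisher_exact

from .maturity import LMMEffect, fit_gaussian_lmm

__all__ = [
    "StateScoreTable",
    "CompositionTestResult",
    "GofResult",
    "state_scores",
    "score_lmm",
    "composition_tests",
    "updown_gof",
]


@dataclass
class StateScoreTable:
    table: pd.DataFrame  # barcode, one column per set, individual, group, subcluster
    coverage: dict[str, float]  # fraction of each set found in the gene universe


@dataclass
class CompositionTestResult:
    contingency: pd.DataFrame
    chi2: float
    df: int
    p: float
    pairwise: pd.DataFrame  # subcluster, group_a, group_b, odds_ratio, p, significant


@dataclass
class GofResult:
    n_up: int
    n_down: int
    chi2: float
    p: float


def state_scores(
    adata: ad.AnnData,
    gene_sets: dict[str, list[str]],
    subcluster: np.ndarray | None = None,
) -> StateScoreTable:
    """Per-nucleus raw-count ratio scores for each gene set.

    Missing set genes are scored over the intersection with the matrix (the
    coverage fraction is reported); an empty intersection is an error naming
    the set.
    """
    X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
    total = X.sum(axis=1)
    total_safe = np.maximum(total, 1.0)
    col_of = {g: i for i, g in enumerate(adata.var_names)}
    out = pd.DataFrame(index=adata.obs_names.copy())
    coverage = {}
    for name, genes_in in gene_sets.items():
        cols = [col_of[g] for g in dict.fromkeys(genes_in) if g in col_of]
        if not cols:
            raise ValueError(f"gene set '{name}' has no genes in the matrix")
        coverage[name] = len(cols) / max(len(set(genes_in)), 1)
        if coverage[name] < 1.0:
            warnings.warn(
                f"set '{name}': scoring over {len(cols)}/{len(set(genes_in))} genes",
                stacklevel=2,
            )
        out[name] = X[:, cols].sum(axis=1) / total_safe
    for col in ("individual", "stress", "wheel"):
        if col in adata.obs:
            out[col] = adata.obs[col].values
    if "stress" in out and "wheel" in out:
        out["group"] = out["stress"].astype(int).astype(str) + "x" + out[
            "wheel"
        ].astype(int).astype(str)
    if subcluster is not None:
        out["subcluster"] = np.asarray(subcluster)
    return StateScoreTable(table=out, coverage=coverage)


def score_lmm(
    scores: StateScoreTable,
    score_col: str,
    fixed: str = "subcluster",
    reference: object | None = None,
) -> list[LMMEffect]:
    """Mixed-model comparison of one score across subclusters or groups."""
    df = scores.table
    for col in (score_col, fixed, "individual"):
        if col not in df:
            raise ValueError(f"score table lacks column '{col}'")
    return fit_gaussian_lmm(df, response=score_col, fixed=fixed,
                            group="individual", reference=reference)


def composition_tests(
    labels: np.ndarray,
    groups: np.ndarray,
    alpha: float = 0.05,
    adjust: bool = False,
) -> CompositionTestResult:
    """Chi-square on the subcluster x group table plus pairwise Fisher tests.

    Pairwise tests are two-sided on each (subcluster vs rest) x (group pair)
    2x2 table, uncorrected by default (``adjust=True`` applies BH).
    """
    tab = pd.crosstab(pd.Series(labels, name="subcluster"),
                      pd.Series(groups, name="group"))
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        chi2_stat, p, dof = 0.0, 1.0, 0
    else:
        chi2_stat, p, dof, _ = chi2_contingency(tab.to_numpy(), correction=False)
    rows = []
    group_names = list(tab.columns)
    for sub in tab.index:
        in_sub = tab.loc[sub]
        rest = tab.sum(axis=0) - in_sub
        for i in range(len(group_names)):
            for j in range(i + 1, len(group_names)):
                ga, gb = group_names[i], group_names[j]
                table = [[in_sub[ga], in_sub[gb]], [rest[ga], rest[gb]]]
                odds, pf = fisher_exact(table, alternative="two-sided")
                rows.append({"subcluster": sub, "group_a": ga, "group_b": gb,
                             "odds_ratio": odds, "p": pf})
    pw = pd.DataFrame(rows)
    if not pw.empty:
        if adjust:
            from statsmodels.stats.multitest import multipletests

            pw["p_adj"] = multipletests(pw["p"], method="fdr_bh")[1]
            pw["significant"] = pw["p_adj"] < alpha
        else:
            pw["significant"] = pw["p"] < alpha
    return CompositionTestResult(contingency=tab, chi2=float(chi2_stat),
                                 df=int(dof), p=float(p), pairwise=pw)


def updown_gof(n_up: int, n_down: int) -> GofResult:
    """1-df chi-square goodness of fit of an up/down DEG split against 50:50."""
    if n_up < 0 or n_down < 0:
        raise ValueError("counts must be nonnegative")
    total = n_up + n_down
    if total == 0:
        raise ValueError("no genes to test (n_up + n_down = 0)")
    stat = (n_up - n_down) ** 2 / total
    return GofResult(n_up=int(n_up), n_down=int(n_down), chi2=float(stat),
                     p=float(chi2.sf(stat, df=1)))
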