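"""Bootstrap causal mediation at the individual level.

For a treatment T, mediator M and outcome Y the linear structural pair

    M = a0 + a*T + e_M
    Y = c0 + c'*T + b*M + e_Y

defines the average causal mediation effect ACME = a*b (the indirect path),
the average direct effect ADE = c', and the total effect a*b + c'.  Point
estimates are ordinary least squares on the full data; confidence intervals
are percentile bootstrap over individuals (rows), so no normality of a*b is
assumed.  An effect is called significant when its CI excludes zero.

The gene screen runs every candidate gene through two triples: direction 1
(stress -> gene expression -> 6-week running distance) asks whether the gene
mediates the stress effect on running; direction 2 (stress -> running ->
gene) asks whether the gene is downstream of altered running.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MediationResult", "mediate", "screen_mediators"]


@dataclass
class MediationResult:
    treatment: str
    mediator: str
    outcome: str
    acme: float
    ade: float
    total: float
    prop_mediated: float
    acme_ci: tuple[float, float]
    ade_ci: tuple[float, float]
    total_ci: tuple[float, float]
    n_boot: int
    seed: int
    significant: bool  # ACME CI excludes 0


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]


def _effects(T: np.ndarray, M: np.ndarray, Y: np.ndarray) -> tuple[float, float, float]:
    one = np.ones_like(T)
    a = _ols(np.column_stack([one, T]), M)[1]
    cb = _ols(np.column_stack([one, T, M]), Y)
    c_prime, b = cb[1], cb[2]
    return a * b, c_prime, a * b + c_prime


def mediate(
    data: pd.DataFrame,
    treatment: str,
    mediator: str,
    outcome: str,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> MediationResult:
    """Estimate ACME/ADE/total for one triple with percentile bootstrap CIs."""
    cols = [treatment, mediator, outcome]
    df = data[cols]
    if df.isna().any().any():
        raise ValueError("missing values in the treatment/mediator/outcome triple")
    if len(df) < 6:
        raise ValueError(f"need >= 6 observations, got {len(df)}")
    if n_boot < 100:
        warnings.warn(f"n_boot = {n_boot} is small; CIs will be unstable",
                      stacklevel=2)
    T = df[treatment].to_numpy(float)
    M = df[mediator].to_numpy(float)
    Y = df[outcome].to_numpy(float)
    if M.std() == 0:
        raise ValueError(f"mediator '{mediator}' has zero variance")
    if Y.std() == 0:
        raise ValueError(f"outcome '{outcome}' has zero variance")
    if T.std() == 0:
        raise ValueError(f"treatment '{treatment}' has zero variance")
    acme, ade, total = _effects(T, M, Y)

    rng = np.random.default_rng(seed)
    n = len(T)
    boots = np.empty((n_boot, 3))
    for bb in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Tb, Mb, Yb = T[idx], M[idx], Y[idx]
        if Tb.std() == 0 or Mb.std() == 0:
            boots[bb] = boots[bb - 1] if bb else (acme, ade, total)
            continue
        boots[bb] = _effects(Tb, Mb, Yb)
    lo = (1 - ci_level) / 2 * 100
    hi = 100 - lo
    cis = np.percentile(boots, [lo, hi], axis=0)
    acme_ci = (float(cis[0, 0]), float(cis[1, 0]))
    return MediationResult(
        treatment=treatment, mediator=mediator, outcome=outcome,
        acme=float(acme), ade=float(ade), total=float(total),
        prop_mediated=float(acme / total) if total != 0 else np.nan,
        acme_ci=acme_ci,
        ade_ci=(float(cis[0, 1]), float(cis[1, 1])),
        total_ci=(float(cis[0, 2]), float(cis[1, 2])),
        n_boot=n_boot, seed=seed,
        significant=bool(acme_ci[0] > 0 or acme_ci[1] < 0),
    )


def screen_mediators(
    de_genes,
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    treatment_col: str = "stress",
    distance_col: str = "dist_40d",
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[list[MediationResult], list[MediationResult]]:
    """Two-direction mediation screen over candidate genes.

    ``expr`` is an individual x gene matrix of mean corrected expression;
    ``meta`` carries per-individual treatment and running distance, indexed
    compatibly with ``expr``.  Returns (direction-1 results, direction-2
    results); per-gene bootstrap seeds are spawned from ``seed`` so the screen
    is deterministic.
    """
    meta = meta.loc[expr.index]
    base = pd.DataFrame(
        {
            treatment_col: meta[treatment_col].to_numpy(float),
            distance_col: meta[distance_col].to_numpy(float),
        },
        index=expr.index,
    )
    ss = np.random.SeedSequence(seed)
    dir1: list[MediationResult] = []
    dir2: list[MediationResult] = []
    for gene in de_genes:
        if gene not in expr.columns:
            warnings.warn(f"gene '{gene}' absent from expression table; skipped",
                          stacklevel=2)
            continue
        child = ss.spawn(1)[0]
        s1, s2 = (int(x) for x in child.generate_state(2) >> np.uint32(1))
        df = base.copy()
        df[gene] = expr[gene].to_numpy(float)
        dir1.append(
            mediate(df, treatment=treatment_col, mediator=gene,
                    outcome=distance_col, n_boot=n_boot, seed=s1)
        )
        dir2.append(
            mediate(df, treatment=treatment_col, mediator=distance_col,
                    outcome=gene, n_boot=n_boot, seed=s2)
        )
    return dir1, dir2
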