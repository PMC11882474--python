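"""Synthetic snRNA-seq data with the statistical structure the pipeline assumes.

The generator emulates a 2x2 stress-by-wheel-access rodent study: four treatment
groups of six individuals, nuclei pooled across individuals, negative-binomial
UMI counts with gene-specific dispersion, planted transcriptomic clusters with
marker genes, donor random intercepts, treatment log-fold effects on designated
genes, lognormal library sizes (median ~2000 UMIs, matching typical striatal
snRNA-seq depth), a small mitochondrial gene fraction, an optional
expression-breadth (maturity) gradient, planted quality-control violators, and a
running-distance model in which stress suppresses wheel running to ~14.9% of
control levels.

Counts for nucleus *i* of individual *j* in cluster *k* are drawn

    y_gi ~ NB(mean = L_i * exp(b_j) * p_g(k, j),  size = theta_g)

where p(k, j) is a softmax over gene log-rates (baseline + marker + treatment +
per-individual gene shifts), L_i is the planted library size, and b_j is the
donor random intercept, applied identically to all genes of a nucleus.

A separate single-gene simulator, :func:`simulate_nb_gene`, produces counts with
a *per-gene* donor intercept; it defines the conditions for the mixed-model
calibration studies, where the donor effect must act on a single gene's mean.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "SynthConfigError",
    "QCViolators",
    "RunningModel",
    "MediationChain",
    "SynthConfig",
    "TruthTable",
    "generate_dataset",
    "simulate_nb_gene",
    "synthetic_state_sets",
]

MITO_PREFIX = "Mt-"
_MITO_LOG_BOOST = 0.5
_BASE_LOG_SD = 0.8
# library band for non-violator barcodes when QC violators are planted, so
# survivor counts are exact arithmetic
_QC_SAFE_LIB = (1500.0, 12000.0)

DIST_COLUMNS = ("dist_40d", "dist_24h", "dist_3h", "dist_30_90m", "dist_30m")


class SynthConfigError(ValueError):
    """Infeasible or inconsistent generator configuration."""


@dataclass
class QCViolators:
    """Counts of planted barcodes violating exactly one QC rule each."""

    low_umi: int = 0
    low_gene: int = 0
    high_umi: int = 0
    high_gene: int = 0
    high_mito: int = 0

    def total(self) -> int:
        return self.low_umi + self.low_gene + self.high_umi + self.high_gene + self.high_mito


@dataclass
class RunningModel:
    """Per-individual wheel-running distances over five time windows.

    The 6-week total is lognormal; stressed runners are suppressed to
    ``suppression_factor`` of the non-stressed level (default 0.149).  Shorter
    windows are noisy shares of the total so that their correlation with the
    6-week total decays with window length.
    """

    baseline_logmean: float = float(np.log(150.0))  # km over 6 weeks
    baseline_logsd: float = 0.45
    suppression_factor: float = 0.149
    window_noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "dist_24h": 0.5,
            "dist_3h": 0.9,
            "dist_30_90m": 1.1,
            "dist_30m": 1.4,
        }
    )


@dataclass
class MediationChain:
    """Planted causal structure linking stress, gene expression and running.

    ``mediator_genes`` maps gene index -> (stress_shift, running_slope): the
    gene's individual-level log-expression is shifted by ``stress_shift`` in
    stressed animals plus donor noise, and the individual's log running
    distance responds with ``running_slope`` per unit of the gene's
    donor-specific (within-treatment-group) component.  ``consequence_genes``
    maps gene index -> slope on the individual's within-group standardized
    log(1 + 6-week distance): genes that respond to running rather than cause
    it.

    Coupling the downstream variable to the *within-group* component of the
    upstream one is what makes the direction of causation identifiable from a
    linear screen: the gene <-> distance partial association (given treatment)
    is symmetric between the two regression directions, so a gene whose entire
    treatment association is transmitted through the planted arm would flag in
    both directions.  With within-group coupling the reverse direction's
    treatment arm is null by construction, and only the true direction's ACME
    is bootstrap-significant.
    """

    mediator_genes: Mapping[int, tuple[float, float]] = field(default_factory=dict)
    consequence_genes: Mapping[int, float] = field(default_factory=dict)
    mediator_noise_sd: float = 0.4
    consequence_noise_sd: float = 0.4
    direct_log_suppression: float = 0.0  # extra direct stress effect on log distance


@dataclass
class SynthConfig:
    """Full description of one synthetic dataset; all randomness flows from ``seed``."""

    n_genes: int = 2000
    n_nuclei: int = 40000
    n_individuals_per_group: int = 6
    groups: Sequence[tuple[int, int]] = ((0, 0), (0, 1), (1, 0), (1, 1))  # (stress, wheel)
    n_clusters: int = 3
    cluster_proportions: Sequence[float] | None = None
    marker_genes_per_cluster: int = 20
    marker_log2fc: float = 2.0
    treatment_effect_genes: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    individual_sd: float = 0.15
    dispersion_range: tuple[float, float] = (0.5, 10.0)
    library_size_logmean: float = float(np.log(2000.0))
    library_size_logsd: float = 0.4
    mito_gene_fraction: float = 0.01
    maturity_gradient: bool = False
    breadth_range: tuple[float, float] = (0.25, 1.0)
    qc_violators: QCViolators = field(default_factory=QCViolators)
    running: RunningModel = field(default_factory=RunningModel)
    mediation: MediationChain = field(default_factory=MediationChain)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_proportions is None:
            self.cluster_proportions = tuple([1.0 / self.n_clusters] * self.n_clusters)
        props = np.asarray(self.cluster_proportions, dtype=float)
        if len(props) != self.n_clusters:
            raise SynthConfigError("cluster_proportions length must equal n_clusters")
        if abs(props.sum() - 1.0) > 1e-9:
            raise SynthConfigError("cluster_proportions must sum to 1")
        if (props < 0).any():
            raise SynthConfigError("cluster_proportions must be nonnegative")
        for name in ("n_genes", "n_nuclei", "n_individuals_per_group", "n_clusters",
                     "marker_genes_per_cluster"):
            if getattr(self, name) < 0:
                raise SynthConfigError(f"{name} must be nonnegative")
        if not (0 < self.running.suppression_factor <= 1):
            raise SynthConfigError("suppression_factor must lie in (0, 1]")
        if self.individual_sd < 0:
            raise SynthConfigError("individual_sd must be nonnegative")
        lo, hi = self.dispersion_range
        if not (0 < lo <= hi):
            raise SynthConfigError("dispersion_range must satisfy 0 < lo <= hi")
        n_mito = int(round(self.mito_gene_fraction * self.n_genes))
        n_markers = self.marker_genes_per_cluster * self.n_clusters
        if n_markers + n_mito > self.n_genes:
            raise SynthConfigError(
                f"{n_markers} marker genes + {n_mito} mito genes exceed "
                f"n_genes = {self.n_genes}"
            )
        for factor, genes in self.treatment_effect_genes.items():
            if factor not in ("stress", "wheel", "stress:wheel"):
                raise SynthConfigError(f"unknown treatment factor '{factor}'")
            for g in genes:
                if not (0 <= g < self.n_genes):
                    raise SynthConfigError(f"treatment gene index {g} out of range")
        for g in list(self.mediation.mediator_genes) + list(self.mediation.consequence_genes):
            if not (0 <= g < self.n_genes):
                raise SynthConfigError(f"mediation gene index {g} out of range")
        v = self.qc_violators
        if v.total() > self.n_nuclei:
            raise SynthConfigError("more QC violators than nuclei")
        if v.high_gene > 0 and self.n_genes <= 5500:
            raise SynthConfigError(
                "planting high-gene violators (>5000 detected genes) needs n_genes > 5500"
            )
        if v.low_gene > 0 and self.n_genes < 350:
            raise SynthConfigError("planting low-gene violators needs n_genes >= 350")


@dataclass
class TruthTable:
    """Ground truth for parameter-recovery tests: one row per nucleus / gene / individual."""

    nuclei: pd.DataFrame
    genes: pd.DataFrame
    individuals: pd.DataFrame


def _make_individuals(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    idx = 0
    for gi, (stress, wheel) in enumerate(cfg.groups):
        for _ in range(cfg.n_individuals_per_group):
            rows.append(
                {
                    "individual": f"ind{idx:02d}",
                    "group": gi,
                    "stress": stress,
                    "wheel": wheel,
                    "pool": f"pool{idx % 4}",
                }
            )
            idx += 1
    df = pd.DataFrame(rows)
    df["intercept"] = rng.normal(0.0, cfg.individual_sd, len(df))
    return df


def _running_distances(
    cfg: SynthConfig,
    indiv: pd.DataFrame,
    mediator_vals: dict[int, np.ndarray],
    rng: np.random.Generator,
) -> pd.DataFrame:
    run = cfg.running
    n = len(indiv)
    stress = indiv["stress"].to_numpy(float)
    log_d = run.baseline_logmean + run.baseline_logsd * rng.normal(size=n)
    if cfg.mediation.mediator_genes:
        for g, (a, slope) in cfg.mediation.mediator_genes.items():
            m = mediator_vals[g]
            log_d = log_d + slope * (m - a * stress)  # donor-specific component
        log_d = log_d + cfg.mediation.direct_log_suppression * stress
    else:
        log_d = log_d + np.log(run.suppression_factor) * stress
    dist = np.exp(log_d) * indiv["wheel"].to_numpy(float)
    out = indiv.copy()
    out["dist_40d"] = dist
    # shorter windows: share of the total times lognormal noise of growing SD
    shares = {"dist_24h": 1 / 42, "dist_3h": 1 / 336, "dist_30_90m": 1 / 1008,
              "dist_30m": 1 / 2016}
    for col, share in shares.items():
        sd = run.window_noise_sd.get(col, 1.0)
        out[col] = dist * share * np.exp(rng.normal(0.0, sd, n) - sd**2 / 2)
    return out


def _gene_table(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_mito = int(round(cfg.mito_gene_fraction * cfg.n_genes))
    names = np.array(
        [f"{MITO_PREFIX}g{i}" for i in range(n_mito)]
        + [f"Gene{i}" for i in range(cfg.n_genes - n_mito)]
    )
    base_log = rng.normal(0.0, _BASE_LOG_SD, cfg.n_genes)
    base_log[:n_mito] += _MITO_LOG_BOOST
    lo, hi = cfg.dispersion_range
    theta = np.exp(rng.uniform(np.log(lo), np.log(hi), cfg.n_genes))
    genes = pd.DataFrame(
        {
            "gene": names,
            "is_mito": np.arange(cfg.n_genes) < n_mito,
            "base_log": base_log,
            "theta": theta,
            "marker_cluster": -1,
        }
    )
    # marker genes: disjoint, non-mito, away from mediation genes
    reserved = set(range(n_mito))
    reserved |= set(cfg.mediation.mediator_genes) | set(cfg.mediation.consequence_genes)
    for genes_for_factor in cfg.treatment_effect_genes.values():
        reserved |= set(genes_for_factor)
    candidates = np.array([g for g in range(cfg.n_genes) if g not in reserved])
    need = cfg.marker_genes_per_cluster * cfg.n_clusters
    if need > len(candidates):
        raise SynthConfigError("not enough free genes to plant cluster markers")
    chosen = rng.choice(candidates, size=need, replace=False)
    for k in range(cfg.n_clusters):
        sel = chosen[k * cfg.marker_genes_per_cluster : (k + 1) * cfg.marker_genes_per_cluster]
        genes.loc[sel, "marker_cluster"] = k
    for factor, table in cfg.treatment_effect_genes.items():
        col = f"lfc_{factor.replace(':', 'x')}"
        genes[col] = 0.0
        for g, l2fc in table.items():
            genes.loc[g, col] = l2fc
    return genes


def _log_rate_matrix(cfg: SynthConfig, genes: pd.DataFrame, indiv: pd.DataFrame,
                     mediator_vals: dict[int, np.ndarray],
                     consequence_shift: dict[int, np.ndarray]) -> np.ndarray:
    """Per-(cluster, individual) gene log-rates before softmax: (K, J, G)."""
    K, J, G = cfg.n_clusters, len(indiv), cfg.n_genes
    base = np.tile(genes["base_log"].to_numpy(), (K, J, 1))
    ln2 = np.log(2.0)
    marker_cluster = genes["marker_cluster"].to_numpy()
    for k in range(K):
        base[k, :, marker_cluster == k] += cfg.marker_log2fc * ln2
    factors = {
        "stress": indiv["stress"].to_numpy(float),
        "wheel": indiv["wheel"].to_numpy(float),
        "stress:wheel": (indiv["stress"] * indiv["wheel"]).to_numpy(float),
    }
    for factor, table in cfg.treatment_effect_genes.items():
        x = factors[factor]
        for g, l2fc in table.items():
            base[:, :, g] += l2fc * ln2 * x
    for g, m in mediator_vals.items():
        base[:, :, g] += m[None, :]
    for g, shift in consequence_shift.items():
        base[:, :, g] += shift[None, :]
    return base


def _plant_violators(cfg: SynthConfig, X: np.ndarray, genes: pd.DataFrame,
                     rng: np.random.Generator) -> np.ndarray:
    """Overwrite the first ``violators.total()`` rows with single-rule QC violators.

    Returns the per-nucleus violation label ('' for clean barcodes).
    """
    v = cfg.qc_violators
    labels = np.array([""] * X.shape[0], dtype=object)
    non_mito = np.flatnonzero(~genes["is_mito"].to_numpy())
    mito = np.flatnonzero(genes["is_mito"].to_numpy())
    base_p = np.exp(genes["base_log"].to_numpy())
    base_p /= base_p.sum()
    row = 0

    def multinom(total: int, p: np.ndarray) -> np.ndarray:
        return rng.multinomial(total, p / p.sum())

    for _ in range(v.low_umi):
        X[row] = multinom(int(rng.integers(200, 700)), base_p)
        labels[row] = "low_umi"
        row += 1
    for _ in range(v.low_gene):
        sel = rng.choice(non_mito, size=300, replace=False)
        p = np.zeros(cfg.n_genes)
        p[sel] = 1.0
        X[row] = multinom(1500, p)
        labels[row] = "low_gene"
        row += 1
    for _ in range(v.high_umi):
        X[row] = multinom(int(rng.integers(25000, 40000)), base_p)
        labels[row] = "high_umi"
        row += 1
    for _ in range(v.high_gene):
        sel = rng.choice(non_mito, size=5600, replace=False)
        r = np.zeros(cfg.n_genes, dtype=np.int64)
        r[sel] = 1
        X[row] = r
        labels[row] = "high_gene"
        row += 1
    for _ in range(v.high_mito):
        p = base_p.copy()
        if len(mito) == 0:
            raise SynthConfigError("high-mito violators need mito_gene_fraction > 0")
        p_mito = p[mito].sum()
        p_rest = p.sum() - p_mito
        p[mito] *= (0.2 / 0.8) * p_rest / max(p_mito, 1e-12)
        X[row] = multinom(3000, p)
        labels[row] = "high_mito"
        row += 1
    return labels


def generate_dataset(config: SynthConfig) -> tuple[ad.AnnData, TruthTable]:
    """Generate one synthetic dataset; byte-identical for identical configs."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    indiv = _make_individuals(cfg, rng)
    J = len(indiv)
    genes = _gene_table(cfg, rng)

    # individual-level gene values for the planted mediation structure
    stress = indiv["stress"].to_numpy(float)
    mediator_vals = {
        g: a * stress + rng.normal(0.0, cfg.mediation.mediator_noise_sd, J)
        for g, (a, _slope) in cfg.mediation.mediator_genes.items()
    }
    indiv = _running_distances(cfg, indiv, mediator_vals, rng)
    # consequence genes track the within-treatment-group component of running
    activity = np.log1p(indiv["dist_40d"].to_numpy())
    grp = indiv["group"].to_numpy()
    resid = activity.copy()
    for gcode in np.unique(grp):
        mask = grp == gcode
        resid[mask] = activity[mask] - activity[mask].mean()
    act_sd = resid.std() if resid.std() > 0 else 1.0
    z_act = resid / act_sd
    consequence_shift = {
        g: slope * z_act + rng.normal(0.0, cfg.mediation.consequence_noise_sd, J)
        for g, slope in cfg.mediation.consequence_genes.items()
    }

    log_rates = _log_rate_matrix(cfg, genes, indiv, mediator_vals, consequence_shift)
    profiles = np.exp(log_rates)
    profiles /= profiles.sum(axis=2, keepdims=True)  # (K, J, G)

    n = cfg.n_nuclei
    cluster = rng.choice(cfg.n_clusters, size=n, p=np.asarray(cfg.cluster_proportions))
    ind_idx = rng.integers(0, J, size=n)
    libs = np.exp(rng.normal(cfg.library_size_logmean, cfg.library_size_logsd, n))
    maturity_rank = rng.uniform(0.0, 1.0, n)

    has_violators = cfg.qc_violators.total() > 0
    intercepts = indiv["intercept"].to_numpy()
    lib_eff = libs * np.exp(intercepts[ind_idx])
    if has_violators:
        lib_eff = np.clip(lib_eff, *_QC_SAFE_LIB)

    theta = genes["theta"].to_numpy()
    lo_b, hi_b = cfg.breadth_range
    X = np.zeros((n, cfg.n_genes), dtype=np.int64)
    chunk = 512
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        p = profiles[cluster[start:stop], ind_idx[start:stop], :]
        if cfg.maturity_gradient:
            breadth = lo_b + (hi_b - lo_b) * maturity_rank[start:stop]
            mask = rng.random(p.shape) < breadth[:, None]
            p = p * mask
            rowsum = p.sum(axis=1, keepdims=True)
            rowsum[rowsum == 0] = 1.0
            p = p / rowsum
        mu = lib_eff[start:stop, None] * p
        lam = rng.gamma(np.broadcast_to(theta, mu.shape), mu / theta)
        X[start:stop] = rng.poisson(lam)

    violation = np.array([""] * n, dtype=object)
    if has_violators:
        violation = _plant_violators(cfg, X, genes, rng)

    barcodes = np.array([f"BC{i:06d}" for i in range(n)])
    obs = pd.DataFrame(
        {
            "individual": indiv["individual"].to_numpy()[ind_idx],
            "pool": indiv["pool"].to_numpy()[ind_idx],
            "stress": indiv["stress"].to_numpy()[ind_idx],
            "wheel": indiv["wheel"].to_numpy()[ind_idx],
            "true_cluster": cluster,
            "maturity_rank": maturity_rank,
            # expected total count: drawn library times the donor intercept factor
            "planted_lib": lib_eff,
            "qc_violation": violation.astype(str),
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    for col in DIST_COLUMNS:
        obs[col] = indiv[col].to_numpy()[ind_idx]
    var = genes.set_index("gene")
    adata = ad.AnnData(X=sp.csr_matrix(X), obs=obs, var=var)
    adata.uns["syndata"] = {"seed": cfg.seed, "config": _config_dict(cfg)}

    truth = TruthTable(
        nuclei=obs.reset_index()[
            ["barcode", "individual", "true_cluster", "maturity_rank", "planted_lib",
             "qc_violation"]
        ],
        genes=genes,
        individuals=indiv,
    )
    return adata, truth


def _config_dict(cfg: SynthConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["groups"] = [list(g) for g in cfg.groups]
    d["mediation"]["mediator_genes"] = {
        int(k): list(v) for k, v in cfg.mediation.mediator_genes.items()
    }
    d["mediation"]["consequence_genes"] = {
        int(k): float(v) for k, v in cfg.mediation.consequence_genes.items()
    }
    return d


def simulate_nb_gene(
    n_individuals: int = 12,
    nuclei_per_individual: int = 200,
    beta: float = 0.0,
    individual_sd: float = 0.5,
    theta: float = 2.0,
    base_rate: float = 5e-4,
    library_logmean: float = float(np.log(2000.0)),
    library_logsd: float = 0.4,
    seed: int | np.random.Generator = 0,
) -> dict[str, np.ndarray]:
    """Simulate one gene's counts with a per-gene donor random intercept.

    Individuals are split half/half into two groups; the group effect ``beta``
    acts on the log mean, as does the donor intercept b_j ~ N(0, individual_sd).
    Counts are NB with size ``theta`` and mean  lib * base_rate * exp(beta*x + b_j).
    Returns arrays y, x (group indicator), individual (codes) and offset
    (log library size) — the inputs of the NB mixed-model fitter.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    J = n_individuals
    groups_j = (np.arange(J) >= J // 2).astype(float)
    b = rng.normal(0.0, individual_sd, J)
    ind = np.repeat(np.arange(J), nuclei_per_individual)
    x = groups_j[ind]
    libs = np.exp(rng.normal(library_logmean, library_logsd, len(ind)))
    mu = libs * base_rate * np.exp(beta * x + b[ind])
    lam = rng.gamma(theta, mu / theta)
    y = rng.poisson(lam).astype(np.int64)
    return {"y": y, "x": x, "individual": ind, "offset": np.log(libs), "b": b}


def synthetic_state_sets(
    var_names: Sequence[str], n_per_set: int = 15, seed: int = 0
) -> dict[str, list[str]]:
    """Synthetic stand-in M1/M2/metabolism gene sets drawn from a gene universe.

    Real analyses should supply curated polarization/metabolism panels as GMT;
    these disjoint random sets exist so the scoring machinery is testable.
    """
    rng = np.random.default_rng(seed)
    names = np.asarray(var_names)
    if len(names) < 3 * n_per_set:
        raise SynthConfigError("gene universe too small for three disjoint sets")
    pick = rng.choice(len(names), size=3 * n_per_set, replace=False)
    return {
        "M1": list(names[pick[:n_per_set]]),
        "M2": list(names[pick[n_per_set : 2 * n_per_set]]),
        "metabolism": list(names[pick[2 * n_per_set :]]),
    }
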