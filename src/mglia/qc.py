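"""Barcode-level quality filters.

Barcodes are kept when their UMI total lies in [min_umi, max_umi], their
detected-gene count in [min_genes, max_genes], and their mitochondrial fraction
is at most ``max_mito_frac``.  The printed exclusion rules are strict
inequalities ("< 750" removed, "> 5%" removed), so boundary barcodes are kept.
Removals are attributed to the first violated rule in a fixed order so reports
are deterministic and sum to the input count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import numpy as np

__all__ = ["QCThresholds", "FilterReport", "apply_qc_filters", "RULE_ORDER"]

RULE_ORDER = ("min_umi", "min_genes", "max_umi", "max_genes", "mito")


@dataclass(frozen=True)
class QCThresholds:
    min_umi: int = 750
    min_genes: int = 500
    max_umi: int = 20000
    max_genes: int = 5000
    max_mito_frac: float = 0.05

    def __post_init__(self) -> None:
        if not self.min_umi < self.max_umi:
            raise ValueError("min_umi must be < max_umi")
        if not self.min_genes < self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if not (0 < self.max_mito_frac < 1):
            raise ValueError("max_mito_frac must lie in (0, 1)")


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    n_removed_by_rule: dict[str, int]
    kept_barcodes: list[str]
    all_removed: bool = False
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    def __post_init__(self) -> None:
        assert self.n_input == self.n_kept + sum(self.n_removed_by_rule.values())


def apply_qc_filters(
    adata: ad.AnnData,
    thresholds: QCThresholds | None = None,
    mito_gene_ids: Sequence[str] | None = None,
    mito_mode: str = "umi_fraction",
) -> tuple[ad.AnnData, FilterReport]:
    """Filter barcodes; returns (filtered AnnData, report).

    ``mito_mode`` selects the denominator of the mitochondrial fraction:
    ``"umi_fraction"`` (mitochondrial UMIs / total UMIs, the standard reading)
    or ``"gene_fraction"`` (detected mitochondrial genes / detected genes).
    ``mito_gene_ids`` defaults to the ``is_mito`` column of ``.var`` when
    present, else to genes prefixed ``Mt-``/``mt-``.
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("cannot QC-filter an empty matrix")
    th = thresholds or QCThresholds()
    if mito_gene_ids is None:
        if "is_mito" in adata.var:
            mito_mask = adata.var["is_mito"].to_numpy(bool)
        else:
            mito_mask = np.array(
                [n.startswith(("Mt-", "mt-")) for n in adata.var_names]
            )
    else:
        missing = set(mito_gene_ids) - set(adata.var_names)
        if missing:
            raise ValueError(f"mito gene ids not in matrix: {sorted(missing)[:5]}")
        mito_mask = adata.var_names.isin(mito_gene_ids)

    X = adata.X
    umi = np.asarray(X.sum(axis=1)).ravel()
    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    if mito_mode == "umi_fraction":
        mito_num = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
        denom = np.maximum(umi, 1)
    elif mito_mode == "gene_fraction":
        mito_num = np.asarray((X[:, mito_mask] > 0).sum(axis=1)).ravel()
        denom = np.maximum(detected, 1)
    else:
        raise ValueError(f"unknown mito_mode '{mito_mode}'")
    mito_frac = mito_num / denom

    fails = {
        "min_umi": umi < th.min_umi,
        "min_genes": detected < th.min_genes,
        "max_umi": umi > th.max_umi,
        "max_genes": detected > th.max_genes,
        "mito": mito_frac > th.max_mito_frac,
    }
    removed_by: dict[str, int] = {}
    unattributed = np.ones(adata.n_obs, dtype=bool)
    keep = np.ones(adata.n_obs, dtype=bool)
    for rule in RULE_ORDER:
        hit = fails[rule] & unattributed
        removed_by[rule] = int(hit.sum())
        unattributed &= ~hit
        keep &= ~fails[rule]

    kept = adata[keep].copy()
    report = FilterReport(
        n_input=adata.n_obs,
        n_kept=int(keep.sum()),
        n_removed_by_rule=removed_by,
        kept_barcodes=list(adata.obs_names[keep]),
        all_removed=not keep.any(),
        thresholds=th,
    )
    if report.all_removed:
        warnings.warn("QC removed every barcode", stacklevel=2)
    return kept, report
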