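import numpy as np
import pytest

from mglia.syndata import QCViolators, SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Small 3-cluster dataset shared by tests that only need plumbing."""
    cfg = SynthConfig(n_genes=300, n_nuclei=400, n_clusters=3,
                      marker_genes_per_cluster=10, seed=42)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def qc_fixture():
    """100 barcodes with disjoint planted QC violators: 5+3+2+0+1."""
    cfg = SynthConfig(
        n_genes=2000, n_nuclei=100, n_clusters=1, marker_genes_per_cluster=0,
        qc_violators=QCViolators(low_umi=5, low_gene=3, high_umi=2, high_gene=0,
                                 high_mito=1),
        seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def gradient_dataset():
    """Expression-breadth (maturity) gradient fixture."""
    cfg = SynthConfig(n_genes=1000, n_nuclei=2000, n_clusters=1,
                      marker_genes_per_cluster=0, maturity_gradient=True, seed=3)
    return generate_dataset(cfg)
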