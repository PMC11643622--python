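import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from vrcall.io_catalog import CountMatrix, GeneCatalog
from vrcall.preprocess import classify_cells, compute_qc, filter_cells, lognormalize
from vrcall.synthetic_data import SimConfig, generate_dataset
from vrcall.threshold_detect import detect_family_thresholds


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """3 cells x 4 genes with hand-checkable entries."""
    arr = np.array([[5, 0, 3, 0], [1, 2, 0, 4], [0, 0, 0, 7]])
    return CountMatrix(["c1", "c2", "c3"], ["gA", "gB", "gC", "gD"], sp.csr_matrix(arr))


def make_catalog(rows: dict[str, tuple[str, str]]) -> GeneCatalog:
    df = pd.DataFrame(
        [{"gene_id": g, "class": c, "subfamily": s} for g, (c, s) in rows.items()]
    ).set_index("gene_id")
    return GeneCatalog(df)


@pytest.fixture
def tiny_catalog() -> GeneCatalog:
    return make_catalog(
        {
            "gA": ("other", ""),
            "gB": ("mito", ""),
            "gC": ("hemoglobin", ""),
            "gD": ("other", ""),
        }
    )


#: reduced-scale simulation for unit tests (the full default config is the
#: acceptance-scale study condition)
SMALL_SIM = SimConfig(
    n_mature_gnao1=400,
    n_mature_gnai2=600,
    n_immature_gnao1=100,
    n_immature_gnai2=100,
    n_progenitor=100,
    n_other=200,
    n_V1R=90,
    n_ABD=45,
    n_background=400,
    n_ER=20,
    doublet_rate=0.01,
    seed=11,
)


@pytest.fixture(scope="session")
def sim_bundle():
    """(counts, catalog, labels, truth) for a reduced-scale simulation."""
    return generate_dataset(SMALL_SIM)


@pytest.fixture(scope="session")
def sim_norm(sim_bundle):
    counts, catalog, labels, truth = sim_bundle
    qc = compute_qc(counts, catalog)
    return lognormalize(filter_cells(counts, qc))


@pytest.fixture(scope="session")
def sim_labels(sim_bundle, sim_norm):
    _, catalog, _, _ = sim_bundle
    return classify_cells(sim_norm, catalog)


@pytest.fixture(scope="session")
def sim_thresholds(sim_bundle, sim_norm, sim_labels):
    _, catalog, _, _ = sim_bundle
    mature = [
        b for b in sim_norm.barcodes
        if sim_labels[b] in ("mature_Gnao1", "mature_Gnai2")
    ]
    return detect_family_thresholds(sim_norm, catalog, cells=mature)
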