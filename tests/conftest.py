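import numpy as np
import pytest

from genecore import geno_io
from genecore.simdata import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale synthetic study shared across tests (90 accessions, 300 loci)."""
    cfg = SimConfig(
        seed=7,
        n_loci=300,
        pop_sizes=(25, 35, 30),
        n_pops=3,
        n_adaptive=8,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_imputed(small_dataset):
    gm, markers = small_dataset.genotypes, small_dataset.markers
    markers = geno_io.compute_marker_metrics(gm, markers)
    gm_f, markers_f, _ = geno_io.filter_markers(gm, markers)
    gm_i = geno_io.impute_svd(gm_f, rank=4)
    gm_r = gm_i.with_provenance("imputed")
    gm_r.dosage = np.round(gm_r.dosage)
    return gm_r, markers_f
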