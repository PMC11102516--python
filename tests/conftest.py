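import numpy as np
import pytest

from cdrank import synthetic
from cdrank.io import CellLineProfile, DrugProfile


@pytest.fixture(scope="session")
def small_sim():
    """A small generated study: (drugs, cells, gene_panel, dose-response records)."""
    cfg = synthetic.SimConfig(n_drugs=40, n_moas=4, n_cells=40, n_cancers=4,
                              n_genes=60, genes_per_cancer=12,
                              unknown_cancer_count=1, seed=7)
    return synthetic.generate(cfg)


@pytest.fixture
def toy_drugs():
    rng = np.random.default_rng(0)
    drugs = []
    for i in range(12):
        m = i % 3
        fp = rng.integers(0, 2, size=16).astype(np.uint8)
        drugs.append(DrugProfile(drug_id=f"d{i:02d}", fingerprint=fp,
                                 gene_targets={f"T{m}"}, moa=f"M{m}"))
    return drugs


@pytest.fixture
def toy_cells():
    rng = np.random.default_rng(1)
    return [CellLineProfile(cell_id=f"c{i:02d}", cancer_type=f"K{i % 2}",
                            expression=rng.normal(size=8))
            for i in range(10)]
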