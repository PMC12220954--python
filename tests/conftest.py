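import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import trmtime as tm


@pytest.fixture(scope="session")
def small_design():
    """A fast desk-scale design: 6 timepoints, 4 tissues, 250 genes."""
    return tm.TimeCourseDesign(
        timepoints=(0.0, 10.0, 20.0, 30.0, 45.0, 60.0),
        cells_per_sample=60,
        n_genes=250,
    )


@pytest.fixture(scope="session")
def small_two_comp(small_design):
    """Two-compartment simulation reused across read-only tests."""
    datasets, truth = tm.simulate_two_compartments(
        small_design,
        n_shared_resident=20,
        n_tissue_specific=10,
        n_circulating=15,
        n_circulating_overlap=5,
        seed=7,
    )
    return datasets, truth


@pytest.fixture()
def toy_counts():
    """Hand-built 4-gene x 6-cell matrix with tissue/day metadata."""
    genes = ["Cd3d", "Cd8a", "Trac", "Gzmb"]
    counts = np.array(
        [
            [1, 0, 2, 3, 1, 1],
            [2, 1, 0, 1, 1, 4],
            [1, 1, 1, 0, 2, 1],
            [0, 5, 1, 2, 0, 3],
        ]
    )
    barcodes = [f"cell{i}" for i in range(6)]
    meta = pd.DataFrame(
        {
            "barcode": barcodes,
            "tissue": ["skin"] * 3 + ["dLN"] * 3,
            "day": [0.0, 10.0, 20.0, 0.0, 10.0, 20.0],
        }
    )
    return tm.CountMatrix(genes, barcodes, sp.csr_matrix(counts)), meta
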