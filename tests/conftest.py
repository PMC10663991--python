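import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from pseudotempo.tenx_io import CellCounts


@pytest.fixture
def toy_counts():
    """5 genes x 4 cells with one mitochondrial gene, hand-computable."""
    mat = np.array(
        [
            [1, 0, 0, 2],   # mt-Nd1
            [9, 5, 0, 0],   # Actb
            [0, 3, 4, 1],   # Krt14
            [0, 0, 0, 7],   # Elf5
            [2, 2, 2, 2],   # Csn3
        ]
    )
    genes = pd.DataFrame(
        {
            "ensembl_id": [f"ENSMUSG{i:04d}" for i in range(5)],
            "symbol": ["mt-Nd1", "Actb", "Krt14", "Elf5", "Csn3"],
        }
    )
    cells = pd.DataFrame(
        {
            "barcode": [f"S1-bc{i}" for i in range(4)],
            "sample": "S1",
        }
    )
    return CellCounts(sp.csc_matrix(mat), genes, cells)


def make_counts(mat, symbols, sample="S1", barcodes=None):
    mat = np.asarray(mat)
    genes = pd.DataFrame(
        {
            "ensembl_id": [f"ENS{i:04d}" for i in range(mat.shape[0])],
            "symbol": list(symbols),
        }
    )
    if barcodes is None:
        barcodes = [f"{sample}-bc{i}" for i in range(mat.shape[1])]
    cells = pd.DataFrame({"barcode": barcodes, "sample": sample})
    return CellCounts(sp.csc_matrix(mat), genes, cells)


@pytest.fixture
def make_counts_factory():
    return make_counts


@pytest.fixture(scope="session")
def small_sim():
    """Session-shared small cell-level simulation."""
    from pseudotempo.trajectory_sim import SimConfig, simulate_cells

    cfg = SimConfig(
        seed=1,
        n_samples=3,
        n_clusters=3,
        cells_per_cluster=50,
        n_genes=300,
        n_mito=5,
    )
    return simulate_cells(cfg)


@pytest.fixture(scope="session")
def printed_pseudotimes():
    """The 22 retained pseudo-bulk pseudotimes of the mammary example."""
    from pseudotempo.trajectory_sim import mammary_pseudobulk_table

    tab = mammary_pseudobulk_table()
    return np.sort(tab.loc[tab["cell_number"] > 30, "pseudotime"].to_numpy())
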