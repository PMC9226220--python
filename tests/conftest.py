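import numpy as np
import pandas as pd
import pytest

from ervkit import (
    BulkSimSpec,
    CellMatrix,
    ExpressionMatrix,
    FeatureTable,
    simulate_bulk,
)


@pytest.fixture(scope="session")
def bulk_sim():
    """One default bulk simulation shared across read-only tests."""
    return simulate_bulk(BulkSimSpec(seed=1))


@pytest.fixture()
def toy_features():
    return FeatureTable(
        pd.DataFrame(
            {
                "feature_class": ["gene", "gene", "repeat", "repeat"],
                "family": ["", "", "MERVL-int", "MERVL-int"],
                "length": [1000, 2000, 500, 500],
            },
            index=pd.Index(["g1", "g2", "r1", "r2"], name="feature_id"),
        )
    )


@pytest.fixture()
def toy_counts():
    return ExpressionMatrix(
        pd.DataFrame(
            {"s1": [10, 10, 5, 0], "s2": [0, 4, 1, 3]},
            index=pd.Index(["g1", "g2", "r1", "r2"], name="feature_id"),
        )
    )


@pytest.fixture()
def qc_toy():
    """6 cells x 5 genes: two low-UMI cells, one high-mito cell, one rare
    gene; exactly 3 cells x 4 genes survive the standard QC.

    Hand tally: gene detection on the original 6 cells — g_rare is
    expressed only in c2 and c3 (2 < 3 cells) and is dropped; g1..g3 and
    mt-1 are each detected in >= 3 cells and stay.  Cells: c5 and c6 have
    nUMI 499 and 100 (< 500, dropped); c4 has mito fraction 150/600 = 0.25
    (> 0.2, dropped); c1 (nUMI exactly 500, mito 0.1), c2 (601, 0.05) and
    c3 (1002, 0.02) stay.
    """
    counts = pd.DataFrame(
        {
            "g1": [250, 300, 480, 300, 250, 40],
            "g2": [100, 150, 300, 100, 149, 30],
            "g3": [100, 119, 200, 50, 50, 20],
            "mt-1": [50, 30, 20, 150, 50, 10],
            "g_rare": [0, 1, 2, 0, 0, 0],
        },
        index=pd.Index([f"c{i}" for i in range(1, 7)], name="cell_id"),
    )
    return CellMatrix(counts, mito_genes={"mt-1"})


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
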