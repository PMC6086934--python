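import numpy as np
import pandas as pd
import pytest

import cellgraph as cg


@pytest.fixture(scope="session")
def small_sim():
    """600 cells, 4 well-separated clusters — shared across modules."""
    design = cg.SimulationDesign(
        n_cells=600, n_genes=800, n_clusters=4, seed=11
    )
    m, truth = cg.generate_counts(design)
    return design, m, truth


@pytest.fixture(scope="session")
def clustered_profile(small_sim):
    """Aggregated profile over the ground-truth clusters with all
    statistic layers filled (enrichment without q-values for speed)."""
    _, m, truth = small_sim
    labels = truth["cluster"].to_numpy()
    profile = cg.aggregate(m, labels)
    cg.enrichment(profile, cg.EnrichmentParams())
    cg.trinarize_profile(profile)
    return profile


@pytest.fixture()
def toy_matrix():
    """3 cells × 5 genes with fully known counts."""
    counts = np.array(
        [
            [0, 1, 2, 0, 5],
            [3, 0, 0, 1, 0],
            [1, 1, 1, 1, 1],
        ]
    )
    return cg.ExpressionMatrix(
        counts=counts,
        cell_attrs=pd.DataFrame({"CellID": ["a", "b", "c"]}),
        gene_attrs=pd.DataFrame({"Gene": [f"G{i}" for i in range(5)]}),
    )
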