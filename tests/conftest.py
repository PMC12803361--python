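import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from tmeniche.simulate import (
    CohortSpec,
    Region,
    SimSpec,
    TissueSpec,
    generate_multimodal,
    generate_repertoire_cohort,
    generate_tissue,
)
from tmeniche.types import CellRecord, MultimodalDataset


@pytest.fixture(scope="session")
def small_multimodal():
    """Clustered 500-cell multimodal dataset with planted structure."""
    return generate_multimodal(SimSpec(n_cells=500, n_genes=100, n_adts=20, seed=7))


@pytest.fixture(scope="session")
def tissue():
    """One cancer nest plus one lymphoid aggregate, well separated."""
    return generate_tissue(TissueSpec(seed=11))


@pytest.fixture(scope="session")
def cohort():
    return generate_repertoire_cohort(CohortSpec(seed=13))


@pytest.fixture()
def toy_dataset():
    """3 genes x 4 cells, 3 ADTs, hand-checkable."""
    cells = [
        CellRecord(cell_id=f"c{i}", sample_id="S1", cluster_label="A")
        for i in range(4)
    ]
    rna = np.array([[1, 0, 2, 3], [0, 5, 1, 0], [2, 2, 2, 2]])
    adt = np.array([[1, 0, 2, 2], [3, 0, 2, 2], [9, 0, 2, 2]])
    return MultimodalDataset(rna, adt, ["g1", "g2", "g3"], ["a1", "a2", "a3"], cells)
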