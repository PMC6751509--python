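import numpy as np
import pytest

from precda.ingest import AssociationDB, DiseaseSimilarityMatrix
from precda.simulate import GeneratorConfig, generate


@pytest.fixture
def toy_dsim() -> DiseaseSimilarityMatrix:
    ids = ["DOID:1", "DOID:2", "DOID:3", "DOID:4"]
    vals = np.array(
        [
            [1.0, 0.9, 0.2, 0.1],
            [0.9, 1.0, 0.3, 0.2],
            [0.2, 0.3, 1.0, 0.8],
            [0.1, 0.2, 0.8, 1.0],
        ]
    )
    return DiseaseSimilarityMatrix(disease_ids=ids, values=vals)


@pytest.fixture
def toy_assoc() -> AssociationDB:
    return AssociationDB(
        label="toy",
        pairs=frozenset(
            {
                ("circA", "DOID:1"),
                ("circA", "DOID:2"),
                ("circB", "DOID:2"),
                ("circC", "DOID:3"),
                ("circC", "DOID:4"),
            }
        ),
    )


@pytest.fixture
def strong_bundle():
    """One strong-signal synthetic instance under the default conditions."""
    return generate(GeneratorConfig(seed=11))
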