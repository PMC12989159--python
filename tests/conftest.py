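import numpy as np
import pandas as pd
import pytest

from diseaseome.types import DISEASE, REFERENCE, ExpressionDataset, GeneSet, GeneSetCollection


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """4 genes x 6 samples (3 disease / 3 reference), hand-checkable values."""
    values = pd.DataFrame(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            [2.0, 2.0, 2.0, 1.0, 2.0, 3.0],
            [0.0, 1.0, 2.0, 3.0, 4.0, 5.0],
            [5.0, 4.0, 3.0, 2.0, 1.0, 0.0],
        ],
        index=["GA", "GB", "GC", "GD"],
        columns=["d1", "d2", "d3", "r1", "r2", "r3"],
    )
    groups = pd.Series(
        [DISEASE] * 3 + [REFERENCE] * 3, index=values.columns
    )
    return ExpressionDataset(dataset_id="TINY", values=values, groups=groups)


@pytest.fixture
def small_collection() -> GeneSetCollection:
    return GeneSetCollection(
        [
            GeneSet("S1", ("GA", "GB", "GC"), (("alpha response", "src1"),)),
            GeneSet("S2", ("GB", "GC", "GD"), (("beta response", "src1"),)),
            GeneSet("S3", ("GA", "GD", "GX"), (("gamma signature", "src2"),)),
        ]
    )


def random_collection(rng: np.random.Generator, n_sets: int = 8) -> GeneSetCollection:
    """Random gene-set collection for round-trip / reduction properties."""
    universe = [f"g{i}" for i in range(60)]
    sets = []
    for i in range(n_sets):
        size = int(rng.integers(3, 15))
        genes = tuple(rng.choice(universe, size=size, replace=False))
        sets.append(GeneSet(f"set{i:02d}", genes, ((f"term {i}", "rand"),)))
    return GeneSetCollection(sets)
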