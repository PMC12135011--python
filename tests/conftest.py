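import numpy as np
import pandas as pd
import pytest

from lineagefit import GenotypeClass, LineageCountTable


@pytest.fixture
def small_table() -> LineageCountTable:
    """Two wild-type and two mutant lineages over P0..T3, hand-written counts."""
    counts = pd.DataFrame(
        {
            "P0": [100, 100, 200, 200],
            "T1": [120, 110, 180, 170],
            "T2": [150, 140, 160, 150],
            "T3": [180, 170, 130, 120],
        },
        index=pd.Index(["WT_A", "WT_B", "MUT_A", "MUT_B"], name="barcode"),
    )
    classes = {
        "WT_A": GenotypeClass.WILD_TYPE,
        "WT_B": GenotypeClass.WILD_TYPE,
        "MUT_A": GenotypeClass.MUTANT,
        "MUT_B": GenotypeClass.MUTANT,
    }
    return LineageCountTable(counts=counts, classes=classes,
                             replicate_id="toy", concentration=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250901)
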