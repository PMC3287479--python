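import numpy as np
import pandas as pd
import pytest

from pleiomine.traits import ItemizedDataset, TraitTable


@pytest.fixture
def toy_transactions() -> ItemizedDataset:
    """The classic 4-transaction DB: {AB, ABC, AC, BC}."""
    txns = [frozenset(s) for s in ("AB", "ABC", "AC", "BC")]
    return ItemizedDataset(items=["A", "B", "C"], transactions=txns, ids=list("wxyz"))


@pytest.fixture
def small_trait_table() -> TraitTable:
    values = pd.DataFrame(
        {
            "TG": [80.0, 200.0, 150.0, 95.0],
            "LDL": [90.0, 150.0, 150.0, 85.0],
        },
        index=pd.Index(["a", "b", "c", "d"], name="IID"),
    )
    cov = pd.DataFrame(
        {"SEX": ["1", "2", "1", "2"], "AREA": ["Ansung", "Ansan", "Ansung", "Ansan"]},
        index=values.index,
    )
    return TraitTable(values=values, covariates=cov)


def random_trait_table(rng: np.random.Generator, n: int, traits: list[str]) -> TraitTable:
    values = pd.DataFrame(
        rng.normal(100, 20, size=(n, len(traits))),
        columns=traits,
        index=pd.Index([f"I{i:05d}" for i in range(n)], name="IID"),
    )
    return TraitTable(values=values)
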