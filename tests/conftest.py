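import numpy as np
import pandas as pd
import pytest

from clinenrich import (
    AttributeSpec,
    ClinotypeTable,
    Embedding2D,
)


@pytest.fixture
def small_table() -> ClinotypeTable:
    """Six samples, one categorical + one numerical attribute, one missing cell."""
    df = pd.DataFrame(
        {
            "sample_id": [f"P{i}" for i in range(1, 7)],
            "grade": ["II", "III", "II", "IV", "III", "II"],
            "age": ["61", "70", "NA", "55", "48", "66"],
        }
    )
    return ClinotypeTable.from_dataframe(df, id_column="sample_id")


@pytest.fixture
def three_level_table() -> ClinotypeTable:
    """The worked one-hot example: X in {low, normal, high}, explicit level order."""
    data = pd.DataFrame(
        {"X": ["high", "low", "normal"]},
        index=pd.Index(["P1", "P2", "P3"], name="sample_id"),
    )
    spec = AttributeSpec("X", "categorical", ("low", "normal", "high"))
    return ClinotypeTable(data, [spec])


@pytest.fixture
def grid_embedding() -> Embedding2D:
    """Nine samples on a 3x3 unit grid centered at the origin."""
    pts = [(x, y) for x in (-1, 0, 1) for y in (-1, 0, 1)]
    ids = [f"G{i}" for i in range(9)]
    return Embedding2D(ids, np.array(pts, dtype=float))
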