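import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_matrix(rng):
    """10-gene, 20-sample matrix: one exact monotone partner of G00, one
    duplicate row, and noise genes."""
    base = rng.standard_normal(20)
    rows = {
        "G00": base,
        "G01": np.exp(base),          # exact monotone partner
        "G02": base.copy(),           # duplicate of the query
        "G03": -base,                 # exact negative partner
    }
    for i in range(4, 10):
        rows[f"G{i:02d}"] = rng.standard_normal(20)
    return pd.DataFrame(rows).T


@pytest.fixture
def pathway_map():
    return {
        "A1": frozenset({"P1"}),
        "A2": frozenset({"P1"}),
        "B1": frozenset({"P2"}),
        "B2": frozenset({"P2", "P3"}),
        "C1": frozenset({"P3"}),
    }
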