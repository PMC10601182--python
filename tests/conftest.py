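import numpy as np
import pandas as pd
import pytest

from autozyg import PedigreeTable


@pytest.fixture
def fullsib_pedigree():
    """A, B founders -> C, D full sibs -> E (F = 0.25)."""
    return PedigreeTable(pd.DataFrame({
        "id": ["A", "B", "C", "D", "E"],
        "sire": ["0", "0", "A", "A", "C"],
        "dam": ["0", "0", "B", "B", "D"],
        "birth_year": [2000, 2000, 2001, 2001, 2002],
        "sex": ["M", "F", "M", "F", "M"],
    }))


@pytest.fixture
def halfsib_pedigree():
    """Shared sire S, unrelated dams -> half sibs H1, H2 -> O (F = 0.125)."""
    return PedigreeTable(pd.DataFrame({
        "id": ["S", "D1", "D2", "H1", "H2", "O"],
        "sire": ["0", "0", "0", "S", "S", "H1"],
        "dam": ["0", "0", "0", "D1", "D2", "H2"],
    }))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_pedigree_table(parents: dict) -> PedigreeTable:
    """PedigreeTable from a {id: (sire, dam)} parent map (None = unknown)."""
    return PedigreeTable(pd.DataFrame({
        "id": list(parents),
        "sire": [s if s is not None else "0" for s, _ in parents.values()],
        "dam": [d if d is not None else "0" for _, d in parents.values()],
    }))
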