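import numpy as np
import pandas as pd
import pytest

from laipt.encoders import PropertyTable
from laipt.peptides import AMINO_ACIDS, PeptideWindow


@pytest.fixture(scope="session")
def default_table() -> PropertyTable:
    return PropertyTable.default()


@pytest.fixture()
def toy_table() -> PropertyTable:
    """One unstandardized property: A=1, K=2, every other residue 0."""
    values = {aa: 0.0 for aa in AMINO_ACIDS}
    values["A"] = 1.0
    values["K"] = 2.0
    df = pd.DataFrame([values], index=["toy"])
    return PropertyTable(df, standardized=False)


def random_window(rng: np.random.Generator, n: int, allow_x: bool = False) -> PeptideWindow:
    alphabet = AMINO_ACIDS + ("X" if allow_x else "")
    chars = [alphabet[i] for i in rng.integers(len(alphabet), size=2 * n + 1)]
    chars[n] = "K"
    return PeptideWindow(
        residues="".join(chars), label="unlabeled", protein_id="rnd", position=n + 1
    )
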