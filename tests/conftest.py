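import numpy as np
import pandas as pd
import pytest

from ctldscreen.io_formats import CountMatrix, SampleDesign
from ctldscreen.synthetic_data import SimConfig


@pytest.fixture
def small_config():
    return SimConfig(seed=7, n_proteins=20, n_genes=60, n_pairs=3, n_de=5)


@pytest.fixture
def tiny_counts():
    """3 pairs x (control, curdlan), deterministic small integers."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(8)]
    samples = [
        ("f1_control", "f1", "control"),
        ("f1_curdlan", "f1", "curdlan"),
        ("f2_control", "f2", "control"),
        ("f2_curdlan", "f2", "curdlan"),
        ("f3_control", "f3", "control"),
        ("f3_curdlan", "f3", "curdlan"),
    ]
    counts = pd.DataFrame(
        rng.integers(0, 200, size=(8, 6)), index=genes, columns=[s[0] for s in samples]
    )
    lengths = pd.Series(rng.integers(500, 3000, size=8), index=genes)
    return CountMatrix(counts=counts, gene_lengths=lengths), SampleDesign(tuple(samples))
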