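import numpy as np
import pandas as pd
import pytest
from importlib import resources

from oncomotif import (
    MiRNACatalogue,
    MiRNARecord,
    ScreenCountTable,
    read_fasta,
)

HIT_FASTA = resources.files("oncomotif") / "data" / "oncomotif_mirnas.fasta"


@pytest.fixture(scope="session")
def hit_catalogue() -> MiRNACatalogue:
    """The four validated screen-hit miRNAs shipped with the package."""
    return read_fasta(HIT_FASTA)


@pytest.fixture(scope="session")
def decoy_catalogue(hit_catalogue) -> MiRNACatalogue:
    """Four hits plus two motif-free decoy miRNAs."""
    decoys = [
        MiRNARecord("decoy-1", "CCCCUUUUGGGGACACACACAC"),
        MiRNARecord("decoy-2", "UGUGUGUGCCCCAAAAGGGGAU"),
    ]
    return MiRNACatalogue(list(hit_catalogue.records) + decoys)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160801)


@pytest.fixture
def small_screen_table(rng) -> ScreenCountTable:
    """A 10-vector random screen table with the standard 3x3 design."""
    cols = [f"{c}_rep{r}" for c in ("Ctrl0", "Ctrl30", "Gef30") for r in (1, 2, 3)]
    counts = pd.DataFrame(
        rng.integers(100, 5000, size=(10, 9)),
        index=[f"v{i}" for i in range(10)],
        columns=cols,
    )
    return ScreenCountTable.from_frame(counts)
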