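import numpy as np
import pandas as pd
import pytest

from biocharnet import synthgen
from biocharnet.community import OTUTable


@pytest.fixture(scope="session")
def default_community():
    """One default synthetic community (the incubation design at seed 1)."""
    return synthgen.gen_community(synthgen.CommunityConfig(seed=1))


@pytest.fixture(scope="session")
def wgcna_result(default_community):
    from biocharnet.wgcna import WGCNAConfig, run_wgcna

    comm = default_community
    return run_wgcna(comm.table, comm.trait, WGCNAConfig(seed=1), power=6)


def make_table(counts: dict, treatments: dict, genera: dict | None = None) -> OTUTable:
    """Small OTU table helper: counts {otu: [per-sample]}, labels, genera."""
    df = pd.DataFrame(counts).T
    df.columns = list(treatments)
    genera = genera or {}
    tax = pd.Series(
        {
            otu: f"k__Bacteria;p__P;c__C;o__O;f__F;g__{genera.get(otu, 'Genus' + otu)};s__"
            for otu in df.index
        }
    )
    return OTUTable(df, tax, pd.Series(treatments))


@pytest.fixture
def toy_table():
    rng = np.random.default_rng(0)
    counts = {f"O{i}": rng.integers(1, 50, 6).tolist() for i in range(8)}
    treatments = {f"S{i}": ("NB" if i < 3 else "AB") for i in range(6)}
    return make_table(counts, treatments)
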