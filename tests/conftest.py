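import numpy as np
import pandas as pd
import pytest

from sipcall import LibraryMetadata, OtuTable, PipelineConfig


@pytest.fixture
def config():
    return PipelineConfig()


def make_meta(library_id, **kw):
    defaults = dict(
        marker="16S",
        experiment="substrate_sip",
        treatment="methanol",
        isotope="c13",
        pool="H",
        ph_condition="not_applicable",
    )
    defaults.update(kw)
    return LibraryMetadata(library_id=library_id, **defaults)


def make_table(counts: dict, metas: list) -> OtuTable:
    """counts: {library_id: {phylotype: n}}; metas: list of LibraryMetadata."""
    frame = pd.DataFrame(counts).fillna(0).astype("int64")
    frame.index.name = "phylotype_id"
    return OtuTable(counts=frame, libraries=metas)


def random_table(rng: np.random.Generator, n_phylotypes=20, n_libraries=4):
    """A random valid OtuTable for property-style tests."""
    counts = rng.integers(0, 30, size=(n_phylotypes, n_libraries))
    pids = [f"otu_{i:03d}" for i in range(n_phylotypes)]
    lib_ids = [f"lib_{j}" for j in range(n_libraries)]
    pools = ["H", "M", "L", "H"]
    isotopes = ["c13", "c13", "c13", "c12"]
    metas = [
        make_meta(lib_ids[j], pool=pools[j % 4], isotope=isotopes[j % 4],
                  treatment=["methanol", "acetate"][j // 4 % 2])
        for j in range(n_libraries)
    ]
    frame = pd.DataFrame(counts, index=pids, columns=lib_ids, dtype="int64")
    frame.index.name = "phylotype_id"
    return OtuTable(counts=frame, libraries=metas)
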