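import numpy as np
import pandas as pd
import pytest

from schoco.formats import AsvTable, SampleMeta, TaxonomyLineage, RANKS
from schoco.simulate import make_toy_refdb


def lineage(*names: str) -> TaxonomyLineage:
    padded = (list(names) + [""] * len(RANKS))[: len(RANKS)]
    return TaxonomyLineage(tuple(zip(RANKS, padded)), dialect="silva")


@pytest.fixture(scope="session")
def toy_refdb():
    """Toy chloroplast + planted-decoy reference database."""
    return make_toy_refdb(seed=0)


@pytest.fixture(scope="session")
def toy_chloroplast(toy_refdb):
    return toy_refdb[0]


@pytest.fixture
def small_table() -> AsvTable:
    """3 ASVs x 4 samples (2 paired cells), hand-checkable counts."""
    counts = pd.DataFrame(
        {
            "c1.C": [7000, 2500, 500],
            "c1.T": [1000, 8000, 1000],
            "c2.C": [8000, 1500, 500],
            "c2.T": [2000, 7000, 1000],
        },
        index=["asv_chl", "asv_bact", "asv_unk"],
        dtype="int64",
    )
    taxonomy = {
        "asv_chl": lineage("Bacteria", "Cyanobacteria", "Cyanobacteriia",
                           "Chloroplast"),
        "asv_bact": lineage("Bacteria", "Proteobacteria",
                            "Gammaproteobacteria", "Alteromonadales",
                            "Colwelliaceae", "Colwellia"),
        "asv_unk": lineage("Bacteria", "Proteobacteria"),
    }
    samples = {
        "c1.C": SampleMeta("c1.C", "c1", "A1", "full", "SC-PCR", "SC-seq"),
        "c1.T": SampleMeta("c1.T", "c1", "A1", "full", "SC-PCR", "SCHoCO-seq"),
        "c2.C": SampleMeta("c2.C", "c2", "A1", "full", "SC-PCR", "SC-seq"),
        "c2.T": SampleMeta("c2.T", "c2", "A1", "full", "SC-PCR", "SCHoCO-seq"),
    }
    return AsvTable(counts=counts, taxonomy=taxonomy, samples=samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
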