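import numpy as np
import pytest

from digiseq import Assay, Panel, synthetic_panel


@pytest.fixture(scope="session")
def panel1() -> Panel:
    """Single-assay synthetic panel (100 nt amplicon)."""
    return synthetic_panel(n_assays=1)


@pytest.fixture(scope="session")
def panel5() -> Panel:
    """Five-assay synthetic panel, as used for panel-wide statistics."""
    return synthetic_panel(n_assays=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240301)


@pytest.fixture()
def tiny_panel() -> Panel:
    """Hand-written two-assay panel with short amplicons for exact checks."""
    a = Assay(
        name="A",
        gene="GENE1",
        amplicon_seq="ACGTACGTACGTACGTACGT",
        contig="chr1",
        start=100,
    )
    b = Assay(
        name="B",
        gene="GENE2",
        amplicon_seq="TTGCATGCATGCATGCAAGG",
        contig="chr2",
        start=500,
    )
    return Panel(assays=(a, b), umi_length=8, anchor_seq="ACGTAC", min_reads_per_umi=3)
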