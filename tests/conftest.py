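import pytest

from tp53spectrum.io_core import GeneModel
from tp53spectrum.paper_cohort import paper_cohort, toy_gene_model


@pytest.fixture(scope="session")
def tp53_model() -> GeneModel:
    """Full-size toy gene model with real TP53 exon structure."""
    return toy_gene_model()


@pytest.fixture(scope="session")
def cohort():
    """The deterministic study-scale fixture cohort (built once)."""
    return paper_cohort()


@pytest.fixture(scope="session")
def annotated(cohort):
    return cohort.annotated()


@pytest.fixture()
def toy12() -> GeneModel:
    """The 12-nt toy CDS used by the classification examples."""
    return GeneModel(
        cds_sequence="ATGCCGTTACGA",
        exon_bounds=((1, 1, 6), (2, 7, 12)),
        hotspot_codons=frozenset(),
        pah_codons=frozenset(),
    )
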