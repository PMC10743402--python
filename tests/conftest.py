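import pytest

from construct_otof import (
    AnnotationMap,
    ProteinInterval,
    default_otoferlin_annotation,
    load_blosum80,
)


@pytest.fixture(scope="session")
def amap():
    return default_otoferlin_annotation()


@pytest.fixture(scope="session")
def blosum80():
    return load_blosum80()


@pytest.fixture()
def toy_map():
    """A 20-residue map with every layer populated, for flag/exon tests."""
    return AnnotationMap(
        protein_length=20,
        domains=(ProteinInterval(3, 6, 1, "D1"), ProteinInterval(10, 14, 2, "D2")),
        regions=(ProteinInterval(7, 9, 1, "R1"),),
        comp_bias=(ProteinInterval(4, 5, 1, "CB1"),),
        coiled_coil=(ProteinInterval(15, 18, 1, "CC"),),
        exon_map=(ProteinInterval(1, 10, 1, "e1"), ProteinInterval(11, 20, 2, "e2")),
    )
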