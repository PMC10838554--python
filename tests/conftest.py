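import pytest

from mitocharacter import refdata
from mitocharacter.annotation import Feature, GenomeAnnotation
from mitocharacter.simulate import SyntheticSpec, generate_genome


@pytest.fixture(scope="session")
def ref_ann():
    """The bundled published annotation (39 features, 17,827 bp, circular)."""
    return refdata.reference_annotation()


@pytest.fixture(scope="session")
def ref_table():
    """The published annotation table verbatim (printed length/intergenic)."""
    return refdata.reference_annotation_table()


@pytest.fixture(scope="session")
def ref_composition():
    return refdata.reference_composition()


@pytest.fixture(scope="session")
def ref_codon_usage():
    return refdata.reference_codon_usage()


@pytest.fixture(scope="session")
def default_synthetic():
    """Default synthetic genome: duplicate-CR template, reference-isomorphic
    architecture, fixed seed."""
    return generate_genome(SyntheticSpec(seed=11))


def make_annotation(features, length, circular=True, genome_id="toy"):
    return GenomeAnnotation(genome_id, length, circular, features)


def F(name, start, stop, ftype="PCG", strand="H", **kw):
    return Feature(name=name, ftype=ftype, strand=strand, start=start, stop=stop, **kw)


@pytest.fixture
def toy():
    """Helpers for building small annotations inline."""
    return F, make_annotation
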