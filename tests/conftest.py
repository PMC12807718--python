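import pytest

from mitekit import fixtures


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic dataset (10 entries, seed 7) plus sequences."""
    return fixtures.generate()


@pytest.fixture(scope="session")
def dataset(bundle):
    return bundle.dataset


@pytest.fixture(scope="session")
def bot():
    """The curated bottromycin-style cascade fixture."""
    return fixtures.bottromycin_fixture()


@pytest.fixture(scope="session")
def minimal_entry_kwargs():
    """Building blocks for a minimal valid entry, overridable per test."""
    return dict(
        accession="MITE9999001",
        status="active",
        enzyme=dict(name="TestEnzyme", uniprot_id="P12345"),
        reactions=[dict(
            smarts="[c:1][OX2;H1:2]>>[c:1][O:2]C",
            tailoring_terms=["Methylation"],
            examples=[dict(substrate="Oc1ccc(CC)cc1",
                           products=["CCc1ccc(OC)cc1"])],
            evidence_codes=["in-vitro assay"],
        )],
        references=["10.1000/test.0001"],
    )
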