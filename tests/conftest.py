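import pytest

from histonecode import bundled_references, parse_peptide


@pytest.fixture(scope="session")
def refs():
    return bundled_references()


@pytest.fixture(scope="session")
def h4(refs):
    return refs["H4"]


@pytest.fixture(scope="session")
def h2a(refs):
    return refs["H2A"]


@pytest.fixture(scope="session")
def h4_five_peptides(h4):
    """Hand-built H4 N-terminal peptide set with known per-site counts.

    Covering K16 five times with three unambiguous acetylations there;
    one N-terminal acetylation; one pS1; one ambiguous K12 acetylation
    (excluded from numerators by default).
    """
    rows = [
        "ac-SGRGKacGGKacGLGKacGGAKacRHRKme2VLR",
        "SGRGKGGKGLGKGGAKacRHRKVLRD",
        "pSGRGKGGKGLGKGGAKacRHRKVLRD",
        "SGRGKGGKGLGKGGAKRHRKVLRD",
        "SGRGKGGKGLGK(ac)GGAKRHRKVLRD",
    ]
    return [parse_peptide(r, h4) for r in rows]
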