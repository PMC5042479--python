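"""Shared fixtures: the toy gene is expensive enough to build once."""

import pytest

from isopipe.simulate import ToyGeneConfig, make_toy_gene


@pytest.fixture(scope="session")
def gene():
    return make_toy_gene(ToyGeneConfig(seed=0))


@pytest.fixture(scope="session")
def amplicon_index(gene):
    return gene.amplicon_index()
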