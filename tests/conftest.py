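import pytest

from seqmine.simulate import FixtureSpec, gen_annotation


@pytest.fixture(scope="session")
def toy_annotation():
    """Eight toy genes, the first two with a shared-exon second isoform."""
    index, truth = gen_annotation(FixtureSpec(seed=0, n_genes=8, n_isoform_genes=2))
    return index, truth
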