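import pytest

from mtroute import load_haplogroup_tree, load_reference
from mtroute.seqio import MtHaplotype


@pytest.fixture(scope="session")
def ref():
    return load_reference()


@pytest.fixture(scope="session")
def hg_tree():
    return load_haplogroup_tree()


def make_hap(sample_id, variants, region=((1, 16569),), **kw):
    return MtHaplotype(sample_id=sample_id, variants=tuple(variants), region=region, **kw)


@pytest.fixture
def hap():
    return make_hap
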