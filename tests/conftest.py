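import pytest

from pathkg import fixtures as fx


@pytest.fixture(scope="session")
def table1():
    """The full labelled relation dataset (1267 positive / 876 negative)."""
    instances, corpus = fx.table1_dataset(seed=42)
    return instances, corpus


@pytest.fixture(scope="session")
def thesaurus():
    return fx.toy_thesaurus()
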