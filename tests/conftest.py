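import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def paper_tables():
    from cwgtscreen import load_paper_tables

    return load_paper_tables()
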