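import hypothesis
import pytest

from dispro.vocabulary import builtin_term_sets

hypothesis.settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=30
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def vocab():
    return builtin_term_sets()
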