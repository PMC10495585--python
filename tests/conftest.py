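import pytest
from hypothesis import settings

from scalemine.lexicon import default_lexicon
from scalemine.mesh import mini_tree

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def tree():
    return mini_tree()
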