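import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


class ScriptedRNG:
    """Duck-typed generator whose first uniform draws are scripted.

    Used to force a specific branch or formula reduction in move
    operators; once the script is exhausted, draws fall through to a
    real seeded generator.
    """

    def __init__(self, script, seed=0):
        self.script = list(script)
        self.inner = np.random.default_rng(seed)

    def random(self, size=None):
        if size is None and self.script:
            return self.script.pop(0)
        return self.inner.random(size)

    def integers(self, *a, **kw):
        return self.inner.integers(*a, **kw)

    def standard_normal(self, *a, **kw):
        return self.inner.standard_normal(*a, **kw)

    def uniform(self, *a, **kw):
        return self.inner.uniform(*a, **kw)


@pytest.fixture
def scripted_rng():
    return ScriptedRNG
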