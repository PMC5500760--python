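import pytest

from mzidkit import synth


@pytest.fixture(scope="session")
def make_doc():
    """Session-cached access to generated fixture documents.

    Callers must not mutate returned documents; ``synth.corrupt`` already
    deep-copies, so corruption tests are safe.
    """
    cache = {}

    def get(workflow, **kwargs):
        key = (workflow, tuple(sorted(kwargs.items())))
        if key not in cache:
            cache[key] = synth.generate(workflow, **kwargs)
        return cache[key]

    return get
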