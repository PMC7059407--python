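import pytest

from dualorf.synth import make_fixture_transcript


@pytest.fixture(scope="session")
def fixture_bundle():
    """The canonical POLG-like miniature: (transcript, orfs, extras)."""
    return make_fixture_transcript(seed=7)


@pytest.fixture(scope="session")
def fixture_transcript(fixture_bundle):
    return fixture_bundle[0]


@pytest.fixture(scope="session")
def fixture_orfs(fixture_bundle):
    return {o.name: o for o in fixture_bundle[1]}


@pytest.fixture(scope="session")
def fixture_extras(fixture_bundle):
    return fixture_bundle[2]
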