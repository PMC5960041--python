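import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


from termtrends.corpus_io import Abstract, AbstractCorpus  # noqa: E402


def make_corpus(rows):
    """rows: iterable of (id, year, text)."""
    return AbstractCorpus([Abstract(i, y, t) for i, y, t in rows])


@pytest.fixture
def corpus_factory():
    return make_corpus
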