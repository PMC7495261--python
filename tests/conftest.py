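import pytest

from radsent.geoparse import default_gazetteer, default_population
from radsent.sentiment import DictionaryTokenizer, fixture_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return fixture_lexicon()


@pytest.fixture(scope="session")
def gazetteer():
    return default_gazetteer()


@pytest.fixture(scope="session")
def population():
    return default_population()


@pytest.fixture(scope="session")
def tokenizer(lexicon, gazetteer):
    return DictionaryTokenizer.from_resources(lexicon, gazetteer_words=gazetteer.vocabulary())
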