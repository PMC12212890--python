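import pytest

from cinemort.causes import load_lexicon
from cinemort.gender import load_name_dictionary
from cinemort.reference import load_reference
from cinemort.synth import NamePools


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture(scope="session")
def name_dictionary():
    return load_name_dictionary()


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def name_pools(name_dictionary):
    return NamePools.from_dictionary(name_dictionary)


def make_dump(pages):
    """Build a minimal MediaWiki export string from (title, wikitext) pairs."""
    from xml.sax.saxutils import escape

    parts = ["<mediawiki>"]
    for title, text in pages:
        parts.append(
            f"<page><title>{escape(title)}</title>"
            f"<revision><text>{escape(text)}</text></revision></page>"
        )
    parts.append("</mediawiki>")
    return "\n".join(parts)


@pytest.fixture
def dump_builder():
    return make_dump
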