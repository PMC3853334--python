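import pytest

from varterm.normalise import StopList
from varterm.preprocess import Corpus, RuleTagger, tag_document

#: Six-sentence toy corpus used by the hand-enumerated termhood oracle.
TOY_SENTENCES = [
    "The medial collateral ligament was intact .",
    "A medial collateral ligament sprain was noted .",
    "The collateral ligament was swollen .",
    "A sprain of collateral ligament was seen .",
    "The lateral meniscus was torn .",
    "The lateral menisci were torn .",
]


@pytest.fixture(scope="session")
def tagger():
    return RuleTagger()


@pytest.fixture(scope="session")
def stoplist():
    return StopList()


@pytest.fixture()
def toy_corpus(tagger):
    doc = tag_document(" ".join(TOY_SENTENCES), tagger, doc_id="toy.txt")
    return Corpus(documents=[doc])


def make_sentence_doc(text, tagger=None, doc_id="doc.txt"):
    """Tag a single string into a Document (helper used across tests)."""
    return tag_document(text, tagger or RuleTagger(), doc_id=doc_id)
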