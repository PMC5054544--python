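import pytest

from cidex import demo
from cidex.linguistic import SidecarParser, parse_document
from cidex.model import document_edgs


def _parsed(builder):
    doc, sidecars = builder()
    parse_document(doc, SidecarParser(sidecars))
    return doc


@pytest.fixture(scope="session")
def collection_doc():
    """'A number of ... such as sunitinib and sorafenib ... cause acute
    hemolysis' with its hand parse."""
    return _parsed(demo.collection_doc)


@pytest.fixture(scope="session")
def coreterm_doc():
    """'A case of tardive dyskinesia caused by metoclopramide'."""
    return _parsed(demo.coreterm_doc)


@pytest.fixture(scope="session")
def bow_doc():
    """Two-occurrence abstract for the window/n-gram worked example."""
    return _parsed(demo.bow_doc)


@pytest.fixture(scope="session")
def midazolam_doc():
    """One chemical, three diseases (one in-sentence, one cross-sentence,
    one unrelated) — the candidate-pair bookkeeping example."""
    return _parsed(demo.midazolam_doc)


@pytest.fixture(scope="session")
def collection_edg(collection_doc):
    return document_edgs(collection_doc)[0]


@pytest.fixture(scope="session")
def coreterm_edg(coreterm_doc):
    return document_edgs(coreterm_doc)[0]


@pytest.fixture(scope="session")
def small_corpus():
    """A 40-document synthetic corpus, parsed, shared across tests."""
    from cidex.synthetic import SyntheticConfig, generate_corpus
    corpus = generate_corpus(SyntheticConfig(n_docs=40, seed=11))
    for d in corpus.documents:
        parse_document(d, corpus.parser)
    return corpus
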