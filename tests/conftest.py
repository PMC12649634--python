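import pytest

from clinchunk.embeddings import HashEmbedder
from clinchunk.synthetic import CorpusSpec, generate_corpus
from clinchunk.text import Document


@pytest.fixture(scope="session")
def backend():
    return HashEmbedder(dim=512)


@pytest.fixture(scope="session")
def small_backend():
    return HashEmbedder(dim=64)


@pytest.fixture(scope="session")
def corpus():
    """A default synthetic corpus shared by read-only tests."""
    return generate_corpus(CorpusSpec(seed=7))


@pytest.fixture(scope="session")
def corpus_doc(corpus):
    return corpus.document


@pytest.fixture
def clinical_doc():
    """A small hand-written aftercare-style document."""
    text = (
        "Keep the splint dry at all times. The splint protects the nasal "
        "bones while they heal. Remove the splint on day 7 after your "
        "follow-up visit.\n\n"
        "Begin saline irrigation on day 8. Irrigate twice daily with sterile "
        "saline solution. Unless active bleeding occurs, continue irrigation "
        "for two weeks.\n\n"
        "Swelling peaks around day 3 and then subsides. Apply cold compresses "
        "for the first 48 hours. Call the clinic if swelling worsens suddenly."
    )
    return Document(doc_id="aftercare", text=text)
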