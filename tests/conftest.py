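import numpy as np
import pytest
from hypothesis import settings

from symptner.corpus import Document, EntitySpan, segment_sentences
from symptner.synthetic import GenConfig, generate

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_docs():
    """A dozen deterministic synthetic documents with entities."""
    return generate(GenConfig(n_docs=12, seed=7))


@pytest.fixture(scope="session")
def small_sentences(small_docs):
    return [s for d in small_docs for s in segment_sentences(d)]


@pytest.fixture()
def toy_doc():
    text = "paciente refiere tos seca desde hace dos dias. exploracion normal."
    start = text.index("tos seca")
    return Document("d1", text, [
        EntitySpan("d1", start, start + len("tos seca"), "SINTOMA", "tos seca")])
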