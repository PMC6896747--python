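import numpy as np
import pytest

from citscreen.corpus import Corpus, Document


def make_corpus(review_id, pos_texts, neg_texts):
    """Corpus from raw texts; titles empty so the text equals the abstract."""
    docs = []
    for i, text in enumerate(pos_texts):
        docs.append(Document(f"p{i}", review_id, "", text, "positive"))
    for i, text in enumerate(neg_texts):
        docs.append(Document(f"n{i}", review_id, "", text, "negative"))
    return Corpus(review_id=review_id, documents=docs)


@pytest.fixture
def tiny_corpus():
    """Separable toy corpus: positives and negatives use disjoint word sets."""
    pos = [f"topic alpha beta gamma word{i}" for i in range(6)]
    neg = [f"filler noise random other word{i} extra{i}" for i in range(30)]
    return make_corpus("toy", pos, neg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
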