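"""Synthetic citation corpora with a controllable class-separation dial.

Stands in for PubMed-derived screening corpora so the whole pipeline is
testable offline.  Negative (off-topic) documents draw every word from a
Zipf-distributed background vocabulary; positive (relevant) documents draw
each word from a disjoint, uniform topic vocabulary with probability
``separation`` and from the background otherwise.  ``separation = 0`` makes
the classes exchangeable in distribution (a null corpus); ``separation = 1``
makes them trivially separable.  Titles and abstracts have Poisson lengths.

What this emulates about the real corpora: extreme class imbalance (about
one positive per twenty negatives), per-review sizes between ~200 and ~1,700
documents, ~99%-sparse document-term matrices, and classes that are well
separated by construction (in the real study, by the search-string design).
What it does not emulate: real English morphology (words are synthetic
alphabetic strings, so stemming is a near-no-op), MeSH metadata, or citation
structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .corpus import NEGATIVE, POSITIVE, Corpus, Document
from .errors import ParameterError
from .reference import REVIEW_DOCUMENT_COUNTS
from .seeding import derive_seed

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters for one synthetic review corpus."""

    review_id: str
    n_pos: int
    n_neg: int
    vocab_background: int = 5000
    vocab_topic: int = 200
    separation: float = 0.6
    title_length_mean: float = 10.0
    abstract_length_mean: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.separation <= 1.0):
            raise ParameterError("separation must lie in [0, 1]")
        for name in ("n_pos", "n_neg", "vocab_background", "vocab_topic"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if self.title_length_mean <= 0 or self.abstract_length_mean <= 0:
            raise ParameterError("length means must be positive")


def _word(prefix: str, index: int, width: int) -> str:
    """Deterministic alphabetic word, e.g. ``bgaab``; disjoint by prefix."""
    letters = []
    for _ in range(width):
        letters.append(_ALPHABET[index % 26])
        index //= 26
    return prefix + "".join(reversed(letters))


def _vocabulary(prefix: str, size: int) -> list[str]:
    width = max(3, math.ceil(math.log(max(size, 2), 26)))
    return [_word(prefix, i, width) for i in range(size)]


def _zipf_probs(size: int, exponent: float = 1.0) -> np.ndarray:
    weights = 1.0 / np.arange(1, size + 1, dtype=float) ** exponent
    return weights / weights.sum()


def generate_corpus(spec: SyntheticSpec) -> Corpus:
    """Generate one labeled, imbalanced corpus from a spec (bit-reproducible)."""
    rng = np.random.default_rng(spec.seed)
    background = _vocabulary("bg", spec.vocab_background)
    topic = _vocabulary("tp", spec.vocab_topic)
    bg_probs = _zipf_probs(spec.vocab_background)

    def sample_words(n_words: int, positive: bool) -> list[str]:
        from_topic = (
            rng.random(n_words) < spec.separation if positive else np.zeros(n_words, bool)
        )
        n_topic = int(from_topic.sum())
        words = np.empty(n_words, dtype=object)
        if n_topic:
            idx = rng.integers(0, spec.vocab_topic, size=n_topic)
            words[from_topic] = [topic[i] for i in idx]
        n_bg = n_words - n_topic
        if n_bg:
            idx = rng.choice(spec.vocab_background, size=n_bg, p=bg_probs)
            words[~from_topic] = [background[i] for i in idx]
        return words.tolist()

    documents = []
    for label, count in ((POSITIVE, spec.n_pos), (NEGATIVE, spec.n_neg)):
        for i in range(count):
            title_len = max(1, int(rng.poisson(spec.title_length_mean)))
            abstract_len = max(1, int(rng.poisson(spec.abstract_length_mean)))
            positive = label == POSITIVE
            documents.append(
                Document(
                    doc_id=f"{spec.review_id}-{label[:3]}-{i:05d}",
                    review_id=spec.review_id,
                    title=" ".join(sample_words(title_len, positive)),
                    abstract=" ".join(sample_words(abstract_len, positive)),
                    label=label,
                )
            )
    return Corpus(review_id=spec.review_id, documents=documents)


def default_study_specs(
    scale: float = 1.0, master_seed: int = 0, **overrides
) -> list[SyntheticSpec]:
    """Fourteen specs sized like the study corpora (7,494 documents at scale 1).

    Document counts at ``scale = 1`` match the published per-review sizes
    (largest 1,675); positives are ``floor(documents / 21)`` of each review —
    at least twenty negatives per positive — with a floor of five positives
    after scaling.  ``overrides`` forward to every spec (e.g.
    ``separation=0`` for a null calibration).
    """
    if not (0.0 < scale <= 1.0):
        raise ParameterError("scale must lie in (0, 1]")
    specs = []
    for i, documents in enumerate(REVIEW_DOCUMENT_COUNTS):
        review_id = f"SR{i + 1:02d}"
        n_docs = math.floor(documents * scale)
        n_pos = max(5, math.floor(n_docs / 21))
        spec = SyntheticSpec(
            review_id=review_id,
            n_pos=n_pos,
            n_neg=n_docs - n_pos,
            seed=derive_seed(master_seed, review_id, "generate"),
        )
        specs.append(replace(spec, **overrides) if overrides else spec)
    return specs
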