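"""Labeled citation corpora: data model, I/O, and negative subsampling.

A corpus is the set of candidate citations retrieved for one systematic
review, each labeled ``positive`` (relevant: finally included in the review)
or ``negative`` (irrelevant).  Corpora are stored on disk as UTF-8 delimited
tables with header ``doc_id,review_id,title,abstract,label``, or as
JSON-lines records with the same field names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .errors import ParameterError, SchemaError, ValidationError

POSITIVE = "positive"
NEGATIVE = "negative"
REQUIRED_COLUMNS = ("doc_id", "review_id", "title", "abstract", "label")


@dataclass(frozen=True)
class Document:
    """One citation record: identifiers, free text, and a screening label."""

    doc_id: str
    review_id: str
    title: str
    abstract: str
    label: str

    def text(self) -> str:
        """Title and abstract concatenated with a single space."""
        return f"{self.title} {self.abstract}".strip()


@dataclass
class Corpus:
    """Ordered collection of labeled documents for one systematic review.

    Invariants (checked on construction): unique ``doc_id``; labels in
    {positive, negative}; at least one document of each class.
    """

    review_id: str
    documents: list[Document] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise ValidationError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)
            if doc.label not in (POSITIVE, NEGATIVE):
                raise ValidationError(
                    f"unknown label {doc.label!r} for doc_id {doc.doc_id!r}"
                )
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValidationError(
                f"corpus {self.review_id!r} needs at least one document of each "
                f"class (got {self.n_pos} positive, {self.n_neg} negative)"
            )

    def __len__(self) -> int:
        return len(self.documents)

    @property
    def n_pos(self) -> int:
        return sum(1 for d in self.documents if d.label == POSITIVE)

    @property
    def n_neg(self) -> int:
        return sum(1 for d in self.documents if d.label == NEGATIVE)

    def labels(self) -> np.ndarray:
        """Binary label vector aligned with document order (1 = positive)."""
        return np.array(
            [1 if d.label == POSITIVE else 0 for d in self.documents], dtype=np.int8
        )

    def doc_ids(self) -> list[str]:
        return [d.doc_id for d in self.documents]

    def texts(self) -> list[str]:
        return [d.text() for d in self.documents]


def _corpus_from_frame(frame: pd.DataFrame, source: str) -> Corpus:
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{source}: missing column(s) {missing}")
    frame = frame.fillna("")
    review_ids = set(frame["review_id"].astype(str))
    if len(review_ids) > 1:
        raise ValidationError(
            f"{source}: multiple review_id values {sorted(review_ids)}; "
            "one corpus file holds one review"
        )
    docs = [
        Document(
            doc_id=str(r.doc_id),
            review_id=str(r.review_id),
            title=str(r.title),
            abstract=str(r.abstract),
            label=str(r.label),
        )
        for r in frame.itertuples(index=False)
    ]
    review_id = docs[0].review_id if docs else ""
    return Corpus(review_id=review_id, documents=docs)


def read_corpus(path: str | Path, format: str = "table") -> Corpus:
    """Read a corpus from a delimited table (``table``) or JSON lines (``jsonl``).

    Document order is preserved from the file.  Raises :class:`SchemaError`
    for missing columns and :class:`ValidationError` for invariant violations
    (duplicate ids, unknown labels, a class with zero documents).
    """
    path = Path(path)
    if format == "table":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    elif format == "jsonl":
        records = [
            json.loads(line)
            for line in path.read_text(encoding="utf-8").splitlines()
            if line.strip()
        ]
        frame = pd.DataFrame.from_records(records)
        if frame.empty:
            frame = pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    else:
        raise ParameterError(f"unknown corpus format {format!r}")
    return _corpus_from_frame(frame, str(path))


def corpus_to_frame(corpus: Corpus) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "doc_id": [d.doc_id for d in corpus.documents],
            "review_id": [d.review_id for d in corpus.documents],
            "title": [d.title for d in corpus.documents],
            "abstract": [d.abstract for d in corpus.documents],
            "label": [d.label for d in corpus.documents],
        }
    )


def write_corpus(corpus: Corpus, path: str | Path, format: str = "table") -> None:
    """Write a corpus in the canonical delimited or JSON-lines dialect."""
    path = Path(path)
    frame = corpus_to_frame(corpus)
    if format == "table":
        frame.to_csv(path, index=False)
    elif format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for record in frame.to_dict(orient="records"):
                fh.write(json.dumps(record) + "\n")
    else:
        raise ParameterError(f"unknown corpus format {format!r}")


def subsample_negatives(
    corpus: Corpus, negatives_per_positive: float = 20.0, seed: int = 0
) -> Corpus:
    """Cap the number of negatives at ``n_pos * negatives_per_positive``.

    All positives are retained.  When the cap binds, negatives are a uniform
    random subset drawn without replacement; original document order is kept.
    The default of 20 mirrors screening corpora built with an at-least-1:20
    positive:negative imbalance.
    """
    if negatives_per_positive <= 0:
        raise ParameterError("negatives_per_positive must be > 0")
    neg_idx = [i for i, d in enumerate(corpus.documents) if d.label == NEGATIVE]
    target = int(corpus.n_pos * negatives_per_positive)
    if len(neg_idx) <= target:
        return Corpus(review_id=corpus.review_id, documents=list(corpus.documents))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(neg_idx), size=target, replace=False)
    keep = {neg_idx[j] for j in chosen}
    kept = [
        doc
        for i, doc in enumerate(corpus.documents)
        if doc.label == POSITIVE or i in keep
    ]
    return Corpus(review_id=corpus.review_id, documents=kept)
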