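"""TF-IDF weighting with top-fraction token retention, fitted on training data only.

The inverse document frequency of a token is the plain ``ln(N / df)`` with
``N`` training documents and ``df`` the number of them containing the token
(no smoothing, no additive shifts).  Tokens are ranked by their total TF-IDF
mass over the training documents and the top fraction (default 4%) is
retained; everything downstream — including any held-out fold — is aligned
to that fitted vocabulary, so no validation information ever enters the fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import DegenerateInputError, ParameterError
from .preprocess import WEIGHTING_TF, WEIGHTING_TFIDF, DocumentTermMatrix


@dataclass
class TfidfModel:
    """Fitted weighting model: retained vocabulary in rank order plus IDFs."""

    vocabulary: list[str]
    idf: np.ndarray
    n_training_docs: int
    retain_fraction: float


def fit_tfidf(
    training_dtm: DocumentTermMatrix, retain_fraction: float = 0.04
) -> TfidfModel:
    """Fit IDFs and select the top-ranked tokens on a TF-weighted training DTM.

    Only tokens actually present in the training rows (df >= 1) compete for
    retention; ``ceil(retain_fraction * V)`` of them are kept (minimum 1),
    ranked by summed TF-IDF mass, ties broken lexicographically.
    """
    if training_dtm.weighting != WEIGHTING_TF:
        raise ParameterError("fit_tfidf expects a TF-weighted matrix")
    if not (0.0 < retain_fraction <= 1.0):
        raise ParameterError("retain_fraction must lie in (0, 1]")
    X = training_dtm.weights
    n_docs = X.shape[0]
    df = np.asarray((X > 0).sum(axis=0)).ravel()
    present = np.flatnonzero(df > 0)
    if present.size == 0:
        raise DegenerateInputError("training matrix has no nonzero token")
    idf = np.log(n_docs / df[present])
    mass = np.asarray(X[:, present].sum(axis=0)).ravel() * idf
    tokens = [training_dtm.vocabulary[j] for j in present]
    order = sorted(range(present.size), key=lambda j: (-mass[j], tokens[j]))
    n_keep = min(present.size, max(1, math.ceil(retain_fraction * present.size)))
    keep = order[:n_keep]
    return TfidfModel(
        vocabulary=[tokens[j] for j in keep],
        idf=idf[keep].copy(),
        n_training_docs=n_docs,
        retain_fraction=retain_fraction,
    )


def align_features(
    vocabulary: list[str], dtm: DocumentTermMatrix
) -> DocumentTermMatrix:
    """Project a DTM onto a reference vocabulary, in that vocabulary's order.

    Tokens missing from the DTM become zero columns; tokens absent from the
    reference are dropped; rows are untouched.
    """
    col_of = {tok: j for j, tok in enumerate(dtm.vocabulary)}
    rows, cols = [], []
    for new_j, tok in enumerate(vocabulary):
        old_j = col_of.get(tok)
        if old_j is not None:
            rows.append(old_j)
            cols.append(new_j)
    projection = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(dtm.vocabulary), len(vocabulary)),
    )
    return DocumentTermMatrix(
        doc_ids=list(dtm.doc_ids),
        vocabulary=list(vocabulary),
        weights=sp.csr_matrix(dtm.weights @ projection),
        weighting=dtm.weighting,
        labels=dtm.labels,
    )


def apply_tfidf(model: TfidfModel, dtm: DocumentTermMatrix) -> DocumentTermMatrix:
    """Rescale a TF matrix to TF-IDF under a fitted model.

    The matrix is first aligned to the model vocabulary, then every entry is
    multiplied by the fitted IDF of its column.  IDFs are never re-estimated
    here, so held-out folds are weighted exactly as the training fold was.
    """
    if dtm.weighting != WEIGHTING_TF:
        raise ParameterError("apply_tfidf expects a TF-weighted matrix")
    aligned = align_features(model.vocabulary, dtm)
    weighted = sp.csr_matrix(aligned.weights.multiply(model.idf[np.newaxis, :]))
    return DocumentTermMatrix(
        doc_ids=aligned.doc_ids,
        vocabulary=aligned.vocabulary,
        weights=weighted,
        weighting=WEIGHTING_TFIDF,
        labels=aligned.labels,
    )


def write_tfidf_model(model: TfidfModel, path: str | Path) -> None:
    """Serialize (token, idf) pairs as a delimited table in rank order."""
    pd.DataFrame({"token": model.vocabulary, "idf": model.idf}).to_csv(
        path, index=False
    )


def read_tfidf_model(
    path: str | Path, n_training_docs: int = 0, retain_fraction: float = 0.04
) -> TfidfModel:
    frame = pd.read_csv(path)
    return TfidfModel(
        vocabulary=frame["token"].astype(str).tolist(),
        idf=frame["idf"].to_numpy(dtype=float),
        n_training_docs=n_training_docs,
        retain_fraction=retain_fraction,
    )
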