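"""Published characteristics of the 14 systematic-review screening corpora.

These are the document-term-matrix summaries reported for the PubMed-derived
training sets that this package's synthetic generator emulates: per-review
document counts, token counts, and matrix fill.  They serve as fixtures for
the cell-count arithmetic (``n_nonzero + n_zero = documents x tokens``) and
as the size template for :func:`citscreen.synthetic.default_study_specs`.

Two rows carry ``consistent=False``: their printed nonzero/zero cell counts
do not add up to documents x tokens (single-digit misprints in the source
table), so they are excluded from arithmetic-consistency checks.  Their
document counts and two-decimal sparsity values are still usable.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ReferenceDTMShape:
    review: str
    documents: int
    tokens: int
    n_nonzero: int
    n_zero: int
    sparsity_2dp: float
    consistent: bool = True


REFERENCE_DTM_SHAPES: tuple[ReferenceDTMShape, ...] = (
    ReferenceDTMShape("Yang 2014", 418, 61208, 147445, 25437499, 0.99),
    ReferenceDTMShape("Meng 2014", 209, 35821, 73977, 7412612, 0.99),
    ReferenceDTMShape("Segelov 2014", 413, 58351, 125027, 23963936, 0.99, consistent=False),
    ReferenceDTMShape("Li 2014 (a)", 206, 33851, 68826, 6904480, 0.99),
    ReferenceDTMShape("Lv 2014", 412, 57485, 138846, 23544974, 0.99),
    ReferenceDTMShape("Wang 2015", 832, 101418, 288432, 84091344, 1.00),
    ReferenceDTMShape("Zhou 2014", 209, 33389, 69854, 6908447, 0.99),
    ReferenceDTMShape("Liu 2014", 623, 88108, 219258, 54672026, 1.00),
    ReferenceDTMShape("Douxfils 2014", 413, 58133, 141721, 23869208, 0.99, consistent=False),
    ReferenceDTMShape("Kourbeti 2014", 1675, 187947, 603479, 314207746, 1.00),
    ReferenceDTMShape("Li 2014 (b)", 209, 33653, 69130, 6964347, 0.99),
    ReferenceDTMShape("Cavender 2014", 414, 59572, 141105, 24521703, 0.99),
    ReferenceDTMShape("Chatterjee 2014", 418, 54458, 130782, 22632662, 0.99),
    ReferenceDTMShape("Funakoshi 2014", 1043, 131172, 370385, 136442011, 1.00),
)

#: Per-review document counts, in the order above; total 7,494.
REVIEW_DOCUMENT_COUNTS: tuple[int, ...] = tuple(
    s.documents for s in REFERENCE_DTM_SHAPES
)
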