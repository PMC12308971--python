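"""Relevance scoring of aggregated gene/cell-type relations.

The core score balances how widely and how often a pair is mentioned:

    score_raw = log10(c_pmid) * log10(c_total)

where ``c_pmid`` is the number of distinct articles supporting the pair and
``c_total`` the total co-occurrence count across them. The double logarithm
moderates large frequency disparities so heavily studied concepts (such as
T cells) do not drown out rarer but biologically important ones. An
aggregated TF-IDF comparator is provided for contrast: TF-IDF penalises
terms that appear in many documents, which in this domain down-ranks
well-established entities — the opposite of what marker annotation needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence


@dataclass
class CorpusStats:
    """Corpus document count and per-term document frequencies."""

    n_documents: int
    doc_freq: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_documents < 1:
            raise ValueError("n_documents must be >= 1")
        for term, df in self.doc_freq.items():
            if df > self.n_documents:
                raise ValueError(f"document frequency of {term!r} exceeds corpus size")


def relevance_score(c_pmid: int, c_total: int) -> float:
    """Log-normalised relevance score of one aggregated relation.

    Returns ``log10(c_pmid) * log10(c_total)``. Requires
    ``c_total >= c_pmid >= 1`` (every supporting article contributes at
    least one co-occurrence). Strictly increasing in both arguments beyond
    1, and 0 whenever ``c_pmid == 1``.
    """
    if c_pmid < 1:
        raise ValueError("c_pmid must be >= 1")
    if c_total < c_pmid:
        raise ValueError("c_total must be >= c_pmid")
    return math.log10(c_pmid) * math.log10(c_total)


def display_score(score: float, precision: int = 2) -> float:
    """Round a score for display (round-half-to-even, default 2 decimals).

    Presentation only — ranking and serialisation use full precision.
    """
    return round(score, precision)


TfVariant = Literal["raw", "log"]
IdfVariant = Literal["plain", "smooth"]


def tfidf_aggregate(
    c_total: int,
    c_pmid: int,
    stats: CorpusStats,
    tf_variant: TfVariant = "raw",
    idf_variant: IdfVariant = "plain",
) -> float:
    """Aggregated TF-IDF for a relation, the comparator to the core score.

    Default variant: ``tf = c_total`` and ``idf = log10(D / c_pmid)`` with
    ``D`` the corpus document count, so a pair mentioned in every document
    scores 0. ``tf_variant="log"`` uses ``1 + log10(c_total)``;
    ``idf_variant="smooth"`` uses ``log10((1 + D) / (1 + c_pmid))``.
    """
    if c_pmid < 1 or c_total < c_pmid:
        raise ValueError("require c_total >= c_pmid >= 1")
    if c_pmid > stats.n_documents:
        raise ValueError("c_pmid cannot exceed the corpus document count")
    tf = float(c_total) if tf_variant == "raw" else 1.0 + math.log10(c_total)
    if idf_variant == "plain":
        idf = math.log10(stats.n_documents / c_pmid)
    else:
        idf = math.log10((1 + stats.n_documents) / (1 + c_pmid))
    return tf * idf


def normalize_scores(
    scores: Sequence[float], mode: Literal["none", "max", "minmax"] = "none"
) -> list[float]:
    """Rescale scores for presentation; rank order is preserved.

    ``none`` is the identity; ``max`` divides by the maximum; ``minmax``
    affinely maps onto [0, 1] (all-equal inputs map to 0 by convention).
    """
    values = list(scores)
    if mode == "none":
        return values
    if not values:
        raise ValueError("cannot normalise an empty score list")
    if mode == "max":
        top = max(values)
        if top == 0:
            return [0.0 for _ in values]
        return [v / top for v in values]
    if mode == "minmax":
        lo, hi = min(values), max(values)
        if hi == lo:
            return [0.0 for _ in values]
        return [(v - lo) / (hi - lo) for v in values]
    raise ValueError(f"unknown normalisation mode: {mode!r}")
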