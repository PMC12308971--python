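"""Reading and filtering per-article entity annotations.

Articles arrive pre-annotated: a named-entity recogniser has already marked
gene and cell-type mentions in each title+abstract and normalised them to
concept identifiers (CUIs). This module parses two interchange dialects —
the PubTator flat-text format and a line-delimited JSON record format — into
:class:`AnnotatedArticle` objects, and filters mentions down to those whose
concept id maps into the gene or cell-type catalogs.

Span offsets are 0-based half-open character positions into the article's
title and abstract concatenated with a single newline.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import IO, Iterable, Iterator, Mapping, Sequence


class EntityClass(str, Enum):
    """Class of an entity mention after annotation-type mapping."""

    GENE = "gene"
    CELL_TYPE = "cell_type"
    OTHER = "other"


#: Default mapping from annotator type strings (case-folded) to entity classes.
#: Anything absent from the map (cell lines, diseases, species, ...) becomes
#: ``OTHER`` and is removed by catalog filtering downstream.
DEFAULT_TYPE_MAP: Mapping[str, EntityClass] = {
    "gene": EntityClass.GENE,
    "cell_type": EntityClass.CELL_TYPE,
}


@dataclass(frozen=True)
class EntityMention:
    """One annotated span in an article's title+abstract text.

    ``concept_id`` is the normalised identifier emitted by the annotator,
    or ``None`` when the annotator could not normalise the surface form.
    """

    surface_text: str
    entity_class: EntityClass
    concept_id: str | None
    span_start: int
    span_end: int

    def __post_init__(self) -> None:
        if self.span_start >= self.span_end:
            raise ValueError(
                f"mention span must be non-empty half-open: "
                f"[{self.span_start}, {self.span_end})"
            )


@dataclass
class AnnotatedArticle:
    """One article's identifier, optional metadata, and entity mentions."""

    pmid: int
    title: str = ""
    abstract: str = ""
    journal: str | None = None
    pub_date: str | None = None
    mentions: list[EntityMention] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pmid <= 0:
            raise ValueError(f"pmid must be a positive integer, got {self.pmid}")

    @property
    def text(self) -> str:
        """Title and abstract joined by a single newline (span substrate)."""
        return f"{self.title}\n{self.abstract}" if self.abstract else self.title


class CorpusFormatError(ValueError):
    """Raised for malformed input that cannot be skipped at record level."""


def _open_lines(source: str | IO[str] | Iterable[str]) -> Iterable[str]:
    if isinstance(source, str):
        opener = gzip.open if source.endswith(".gz") else open
        with opener(source, "rt", encoding="utf-8") as handle:  # type: ignore[operator]
            yield from handle
    else:
        yield from source


def _map_type(raw: str, type_map: Mapping[str, EntityClass]) -> EntityClass:
    return type_map.get(raw.strip().casefold(), EntityClass.OTHER)


def read_pubtator(
    source: str | IO[str] | Iterable[str],
    type_map: Mapping[str, EntityClass] = DEFAULT_TYPE_MAP,
) -> list[AnnotatedArticle]:
    """Parse a PubTator-format stream into annotated articles.

    Each document block consists of ``PMID|t|title`` and ``PMID|a|abstract``
    header lines followed by tab-separated annotation lines
    ``PMID<TAB>start<TAB>end<TAB>text<TAB>type<TAB>id``; blank lines separate
    documents. Annotation type strings are mapped case-insensitively through
    ``type_map``; unmapped types become :attr:`EntityClass.OTHER`.

    Malformed annotation lines are skipped with a warning naming the line
    number; a later document block reusing an earlier PMID is rejected with
    a warning (first occurrence wins).
    """
    articles: list[AnnotatedArticle] = []
    seen: set[int] = set()
    block: list[tuple[int, str]] = []

    def flush(block_lines: list[tuple[int, str]]) -> None:
        if not block_lines:
            return
        pmid: int | None = None
        title = ""
        abstract = ""
        mentions: list[EntityMention] = []
        for lineno, line in block_lines:
            parts = line.split("|", 2)
            if len(parts) == 3 and parts[1] in ("t", "a"):
                try:
                    pmid = int(parts[0])
                except ValueError:
                    warnings.warn(f"line {lineno}: non-integer PMID in header; block skipped")
                    return
                if parts[1] == "t":
                    title = parts[2]
                else:
                    abstract = parts[2]
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                warnings.warn(f"line {lineno}: malformed annotation line skipped")
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                warnings.warn(f"line {lineno}: non-integer span offsets; line skipped")
                continue
            concept_id = fields[5].strip() if len(fields) > 5 else ""
            try:
                mentions.append(
                    EntityMention(
                        surface_text=fields[3],
                        entity_class=_map_type(fields[4], type_map),
                        concept_id=concept_id or None if concept_id != "-" else None,
                        span_start=start,
                        span_end=end,
                    )
                )
            except ValueError as exc:
                warnings.warn(f"line {lineno}: {exc}; line skipped")
        if pmid is None:
            warnings.warn("document block without header lines skipped")
            return
        if pmid in seen:
            warnings.warn(f"duplicate PMID {pmid}: later block rejected, first kept")
            return
        seen.add(pmid)
        articles.append(
            AnnotatedArticle(pmid=pmid, title=title, abstract=abstract, mentions=mentions)
        )

    for lineno, raw in enumerate(_open_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush(block)
            block = []
        else:
            block.append((lineno, line))
    flush(block)
    return articles


def write_pubtator(articles: Sequence[AnnotatedArticle], handle: IO[str]) -> None:
    """Serialise articles back to the PubTator dialect (inverse of reading)."""
    for article in articles:
        handle.write(f"{article.pmid}|t|{article.title}\n")
        handle.write(f"{article.pmid}|a|{article.abstract}\n")
        for m in article.mentions:
            concept = m.concept_id if m.concept_id is not None else "-"
            handle.write(
                f"{article.pmid}\t{m.span_start}\t{m.span_end}\t"
                f"{m.surface_text}\t{m.entity_class.value}\t{concept}\n"
            )
        handle.write("\n")


def read_annotation_records(
    source: str | IO[str] | Iterable[str],
    type_map: Mapping[str, EntityClass] = DEFAULT_TYPE_MAP,
) -> list[AnnotatedArticle]:
    """Parse line-delimited JSON records (one document object per line).

    Each record carries ``pmid``, optional ``journal``/``pub_date``/``title``/
    ``abstract``, and a ``mentions`` list of objects with ``text``, ``class``,
    optional ``id``, and ``span`` ``[start, end]``. Mentions lacking a
    normalised id are kept with ``concept_id`` absent. Records with a
    non-integer pmid are rejected with a warning; an empty stream yields an
    empty list.
    """
    articles: list[AnnotatedArticle] = []
    seen: set[int] = set()
    for lineno, raw in enumerate(_open_lines(source), start=1):
        line = raw.strip()
        if not line:
            continue
        try:
            record = json.loads(line)
        except json.JSONDecodeError:
            warnings.warn(f"line {lineno}: invalid JSON record rejected")
            continue
        try:
            pmid = int(record["pmid"])
            if pmid <= 0:
                raise ValueError
        except (KeyError, TypeError, ValueError):
            warnings.warn(f"line {lineno}: record without valid integer pmid rejected")
            continue
        if pmid in seen:
            warnings.warn(f"duplicate PMID {pmid}: later record rejected, first kept")
            continue
        mentions = []
        for m in record.get("mentions", []):
            span = m.get("span", [0, 1])
            mentions.append(
                EntityMention(
                    surface_text=m.get("text", ""),
                    entity_class=_map_type(str(m.get("class", "")), type_map),
                    concept_id=m.get("id") or None,
                    span_start=int(span[0]),
                    span_end=int(span[1]),
                )
            )
        seen.add(pmid)
        articles.append(
            AnnotatedArticle(
                pmid=pmid,
                title=record.get("title", ""),
                abstract=record.get("abstract", ""),
                journal=record.get("journal"),
                pub_date=record.get("pub_date"),
                mentions=mentions,
            )
        )
    return articles


def write_annotation_records(articles: Sequence[AnnotatedArticle], handle: IO[str]) -> None:
    """Serialise articles as line-delimited JSON records."""
    for article in articles:
        record = {
            "pmid": article.pmid,
            "title": article.title,
            "abstract": article.abstract,
            "journal": article.journal,
            "pub_date": article.pub_date,
            "mentions": [
                {
                    "text": m.surface_text,
                    "class": m.entity_class.value,
                    "id": m.concept_id,
                    "span": [m.span_start, m.span_end],
                }
                for m in article.mentions
            ],
        }
        handle.write(json.dumps(record) + "\n")


def filter_mapped_mentions(
    article: AnnotatedArticle,
    gene_ids: frozenset[str] | set[str],
    cell_ids: frozenset[str] | set[str],
) -> AnnotatedArticle:
    """Keep only mentions whose concept id maps into the matching catalog.

    A gene mention survives iff its concept id is in ``gene_ids``; a
    cell-type mention iff in ``cell_ids``; ``OTHER``-class mentions and
    mentions without a concept id are dropped. Order is preserved and the
    input article is not modified. Idempotent.
    """
    kept = [
        m
        for m in article.mentions
        if m.concept_id is not None
        and (
            (m.entity_class is EntityClass.GENE and m.concept_id in gene_ids)
            or (m.entity_class is EntityClass.CELL_TYPE and m.concept_id in cell_ids)
        )
    ]
    return replace(article, mentions=kept)
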