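"""Corpus and query-list I/O, corpus-construction filters, PubMed adapter.

Corpora are line-delimited JSON: one article record per line with fields
``article_id, title, abstract, year, reliable_label, concepts[]`` (each
concept: ``concept_id, category, confidence, is_gene_ontology,
is_disease_ontology``).  Query lists are TSV with columns
``gene, trait, label`` (label 0/1, optional).

The filters implement the corpus-construction rules used when joining a
curated association database against search-engine results: drop articles
that do not explicitly mention both the queried gene and trait, keep only
articles published before a cutoff year, and split records randomly into
train/test portions.
"""

from __future__ import annotations

import json
import logging
import random
import urllib.parse
import urllib.request
import xml.etree.ElementTree as ET
from collections.abc import Callable, Iterable, Sequence
from pathlib import Path

from .types import Article, ConceptToken, QueryCase

logger = logging.getLogger(__name__)

__all__ = [
    "read_corpus",
    "write_corpus",
    "read_queries",
    "write_queries",
    "mentions_both",
    "filter_by_year",
    "split_records",
    "pubmed_fetch",
]


class CorpusFormatError(ValueError):
    """A corpus or query file violates the documented record schema."""


def _concept_to_dict(c: ConceptToken) -> dict:
    return {
        "concept_id": c.concept_id,
        "category": c.category_index,
        "confidence": round(c.confidence, 6),
        "is_gene_ontology": c.is_gene_ontology,
        "is_disease_ontology": c.is_disease_ontology,
    }


def _concept_from_dict(d: dict) -> ConceptToken:
    return ConceptToken(
        concept_id=d["concept_id"],
        category_index=int(d.get("category", 0)),
        confidence=float(d.get("confidence", 1.0)),
        is_gene_ontology=bool(d.get("is_gene_ontology", False)),
        is_disease_ontology=bool(d.get("is_disease_ontology", False)),
    )


def article_to_dict(a: Article) -> dict:
    return {
        "article_id": a.article_id,
        "title": a.title,
        "abstract": a.abstract,
        "year": a.year,
        "reliable_label": a.reliable_label,
        "concepts": [_concept_to_dict(c) for c in a.concepts],
    }


def article_from_dict(d: dict) -> Article:
    if "article_id" not in d or not d["article_id"]:
        raise CorpusFormatError("record missing article_id")
    return Article(
        article_id=str(d["article_id"]),
        title=d.get("title", ""),
        abstract=d.get("abstract", ""),
        year=int(d["year"]) if d.get("year") is not None else None,
        concepts=[_concept_from_dict(c) for c in d.get("concepts", [])],
        reliable_label=d.get("reliable_label"),
    )


def read_corpus(path: str | Path) -> list[Article]:
    """Read a line-delimited corpus file, preserving file order.

    Raises :class:`CorpusFormatError` naming the offending line for
    malformed records, and on duplicate ``article_id``.
    """
    articles: list[Article] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
                article = article_from_dict(record)
            except (json.JSONDecodeError, CorpusFormatError, ValueError, KeyError) as exc:
                raise CorpusFormatError(f"{path}:{lineno}: malformed record: {exc}") from exc
            if article.article_id in seen:
                raise CorpusFormatError(
                    f"{path}:{lineno}: duplicate article_id {article.article_id!r}"
                )
            seen.add(article.article_id)
            articles.append(article)
    return articles


def write_corpus(articles: Iterable[Article], path: str | Path) -> None:
    """Write articles as line-delimited JSON, re-readable by :func:`read_corpus`."""
    with open(path, "w", encoding="utf-8") as fh:
        for a in articles:
            fh.write(json.dumps(article_to_dict(a), sort_keys=True) + "\n")


def read_queries(path: str | Path) -> list[QueryCase]:
    """Read a TSV query list: columns gene, trait, optional 0/1 label."""
    queries: list[QueryCase] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise CorpusFormatError(f"{path}:{lineno}: expected >=2 tab-separated fields")
            gene, trait = fields[0], fields[1]
            gold: bool | None = None
            if len(fields) >= 3 and fields[2] != "":
                gold = fields[2] in ("1", "true", "True")
            candidate_ids = fields[3].split(";") if len(fields) >= 4 and fields[3] else []
            queries.append(
                QueryCase(gene=gene, trait=trait, gold_associated=gold, candidate_ids=candidate_ids)
            )
    return queries


def write_queries(queries: Iterable[QueryCase], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for q in queries:
            label = "" if q.gold_associated is None else str(int(q.gold_associated))
            fh.write("\t".join([q.gene, q.trait, label, ";".join(q.candidate_ids)]) + "\n")


def mentions_both(article: Article, query: QueryCase, *, word_boundary: bool = False) -> bool:
    """True iff title+abstract mention both the gene and trait strings.

    Matching is case-insensitive substring by default; ``word_boundary=True``
    requires each string to appear as a whole word.
    """
    text = article.text.lower()
    terms = (query.gene.lower(), query.trait.lower())
    if not word_boundary:
        return all(t in text for t in terms)
    import re

    return all(re.search(rf"\b{re.escape(t)}\b", text) for t in terms)


def filter_by_year(articles: Iterable[Article], cutoff_year: int) -> list[Article]:
    """Keep articles with ``year < cutoff_year`` (exclusive cutoff), in order.

    Articles without a year are excluded with a logged warning.
    """
    kept = []
    for a in articles:
        if a.year is None:
            logger.warning("article %s has no year; excluded by year filter", a.article_id)
            continue
        if a.year < cutoff_year:
            kept.append(a)
    return kept


def split_records(records: Sequence, train_fraction: float, seed: int) -> tuple[list, list]:
    """Shuffled, seeded train/test split.

    ``|train| = round(train_fraction * N)`` with half-up rounding; the split
    is disjoint and exhaustive.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    items = list(records)
    rng = random.Random(seed)
    rng.shuffle(items)
    n_train = int(train_fraction * len(items) + 0.5)
    return items[:n_train], items[n_train:]


# --- PubMed E-utilities adapter (optional; never exercised live in tests) ---

_ESEARCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi"
_EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def _default_transport(url: str) -> bytes:
    with urllib.request.urlopen(url, timeout=30) as resp:
        return resp.read()


def pubmed_fetch(
    gene: str,
    trait: str,
    max_results: int = 20,
    *,
    transport: Callable[[str], bytes] | None = None,
) -> list[Article]:
    """Retrieve abstracts for the query ``gene AND trait`` via E-utilities.

    ``transport`` maps a URL to response bytes; tests inject canned XML
    payloads, real use leaves it as the default HTTP fetch. Abstracts only.
    """
    if max_results <= 0:
        return []
    fetch = transport or _default_transport

    search_url = _ESEARCH + "?" + urllib.parse.urlencode(
        {"db": "pubmed", "term": f"{gene} AND {trait}", "retmax": max_results}
    )
    try:
        root = ET.fromstring(fetch(search_url))
    except ET.ParseError as exc:
        raise CorpusFormatError(f"malformed esearch payload for {gene}/{trait}: {exc}") from exc
    pmids = [e.text for e in root.iter("Id") if e.text]
    if not pmids:
        return []

    fetch_url = _EFETCH + "?" + urllib.parse.urlencode(
        {"db": "pubmed", "id": ",".join(pmids), "retmode": "xml"}
    )
    try:
        tree = ET.fromstring(fetch(fetch_url))
    except ET.ParseError as exc:
        raise CorpusFormatError(f"malformed efetch payload for {gene}/{trait}: {exc}") from exc

    articles = []
    for art in tree.iter("PubmedArticle"):
        pmid = art.findtext(".//PMID")
        if not pmid:
            raise CorpusFormatError("efetch record without PMID")
        title = art.findtext(".//ArticleTitle") or ""
        abstract = " ".join(
            (e.text or "") for e in art.findall(".//Abstract/AbstractText")
        ).strip()
        year_text = art.findtext(".//PubDate/Year")
        year = int(year_text) if year_text and year_text.isdigit() else None
        articles.append(Article(article_id=pmid, title=title, abstract=abstract, year=year))
    return articles
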