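"""Core domain types shared across the package.

The unit of triage is the :class:`Article` — an abstract retrieved for a
gene–trait query, carrying a sequence of UMLS-style concept annotations.
A :class:`QueryCase` is one (gene, trait) pair with an optional curated
gold association label; one triage episode processes one query.
"""

from __future__ import annotations

from dataclasses import dataclass, field


N_SEMANTIC_SLOTS = 136
"""One-hot width for semantic categories.

The UMLS metathesaurus groups concepts into 133 broad semantic categories;
we allocate 136 slots: indices 0..132 for the named categories, 133 for
"unknown category", and 134/135 reserved, so annotators that emit extra
bookkeeping categories still fit the fixed input width.
"""

UNKNOWN_CATEGORY = 133


@dataclass(frozen=True)
class ConceptToken:
    """One annotated concept occurrence in an abstract.

    Parameters
    ----------
    concept_id:
        Unique concept identifier (CUI-like string).
    category_index:
        Semantic-category slot in ``[0, 136)``.
    confidence:
        Annotator confidence, normalised to ``[0, 1]``.
    is_gene_ontology, is_disease_ontology:
        Whether the concept appears in the gene / disease ontology.
    """

    concept_id: str
    category_index: int = UNKNOWN_CATEGORY
    confidence: float = 1.0
    is_gene_ontology: bool = False
    is_disease_ontology: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.category_index < N_SEMANTIC_SLOTS):
            raise ValueError(
                f"category_index {self.category_index} outside [0, {N_SEMANTIC_SLOTS})"
            )
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class Article:
    """An abstract with its concept annotation and optional reliability label.

    ``reliable_label`` distinguishes curated ("authentic") evidence articles
    from retrieved-but-uncurated ("less favorable") ones; it is the triage
    target and may be absent for unlabelled corpora.
    """

    article_id: str
    title: str = ""
    abstract: str = ""
    year: int | None = None
    concepts: list[ConceptToken] = field(default_factory=list)
    reliable_label: bool | None = None

    def __post_init__(self) -> None:
        if not self.article_id:
            raise ValueError("article_id must be non-empty")
        if self.year is not None and self.year <= 1800:
            raise ValueError(f"implausible year {self.year}")

    @property
    def text(self) -> str:
        return f"{self.title} {self.abstract}"


@dataclass
class QueryCase:
    """A gene–trait query: the unit of one triage episode."""

    gene: str
    trait: str
    gold_associated: bool | None = None
    candidate_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gene or not self.trait:
            raise ValueError("gene and trait must be non-empty")
        if len(set(self.candidate_ids)) != len(self.candidate_ids):
            raise ValueError("candidate_ids contains duplicates")
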