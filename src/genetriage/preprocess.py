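"""Concept annotation and fixed-length encoding of abstracts.

Raw text is turned into an ordered sequence of :class:`ConceptToken` by a
pluggable annotator (a dictionary-based mock for tests and synthetic data,
or a parser for MetaMap's machine-readable MMI output for real corpora).
Concept sequences are then encoded against a frequency-ranked
:class:`Vocabulary` into fixed-length integer/flag arrays for the
classifier: ``SOS + content + EOS``, truncated at the head of the abstract
and PAD-filled to exactly ``max_len`` positions (default 300).
"""

from __future__ import annotations

import re
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .types import N_SEMANTIC_SLOTS, UNKNOWN_CATEGORY, Article, ConceptToken

__all__ = [
    "Vocabulary",
    "EncodedArticle",
    "build_vocabulary",
    "annotate",
    "encode",
    "MockAnnotator",
    "MetaMapOutputParser",
]

PAD, UNK, SOS, EOS = 0, 1, 2, 3
_SPECIALS = ("<PAD>", "<UNK>", "<SOS>", "<EOS>")

DEFAULT_MAX_LEN = 300
DEFAULT_VOCAB_SIZE = 30_000


@dataclass
class Vocabulary:
    """Concept→index map: 4 reserved specials + content ranked by frequency.

    Indices 0..3 are PAD, UNK, SOS, EOS in that order; content entries
    follow, ordered by descending training-corpus frequency with
    lexicographic tie-breaking.
    """

    index: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.index) + 4

    def id_of(self, concept_id: str) -> int:
        return self.index.get(concept_id, UNK)

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for i, name in enumerate(_SPECIALS):
                fh.write(f"{i}\t{name}\n")
            for concept, i in sorted(self.index.items(), key=lambda kv: kv[1]):
                fh.write(f"{i}\t{concept}\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        index: dict[str, int] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                i_str, concept = line.rstrip("\n").split("\t")
                i = int(i_str)
                if i >= 4:
                    index[concept] = i
        return cls(index=index)


def build_vocabulary(corpus: Iterable[Article], size: int = DEFAULT_VOCAB_SIZE) -> Vocabulary:
    """Rank concepts by corpus frequency and keep the ``size`` most frequent.

    Ties are broken lexicographically so the vocabulary is a deterministic
    function of the corpus. Raises if no article carries annotations.
    """
    counts: Counter[str] = Counter()
    for article in corpus:
        counts.update(c.concept_id for c in article.concepts)
    if not counts:
        raise ValueError("corpus has no concept annotations; run an annotator first")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:size]
    return Vocabulary(index={concept: i + 4 for i, (concept, _) in enumerate(ranked)})


@dataclass
class EncodedArticle:
    """Fixed-length encoding of one abstract's concept sequence.

    ``token_ids`` has length exactly ``max_len``; ``category_idx`` holds the
    semantic-category slot per position (−1 at specials/PAD, giving an
    all-zero one-hot row); flags are 0/1 arrays aligned to positions.
    """

    token_ids: np.ndarray
    category_idx: np.ndarray
    gene_flags: np.ndarray
    disease_flags: np.ndarray
    confidences: np.ndarray
    true_length: int

    @property
    def category_onehots(self) -> np.ndarray:
        onehot = np.zeros((len(self.token_ids), N_SEMANTIC_SLOTS), dtype=np.int8)
        valid = self.category_idx >= 0
        onehot[np.nonzero(valid)[0], self.category_idx[valid]] = 1
        return onehot


def encode(
    concepts: Sequence[ConceptToken],
    vocab: Vocabulary,
    max_len: int = DEFAULT_MAX_LEN,
) -> EncodedArticle:
    """Encode a concept sequence as SOS + ids + EOS, padded to ``max_len``.

    Sequences longer than ``max_len - 2`` keep their head (abstracts
    front-load their findings); out-of-vocabulary concepts map to UNK but
    keep their category and ontology flags.
    """
    if max_len < 3:
        raise ValueError(f"max_len must be >= 3, got {max_len}")
    capacity = max_len - 2
    content = concepts[:capacity]

    token_ids = np.full(max_len, PAD, dtype=np.int32)
    category_idx = np.full(max_len, -1, dtype=np.int16)
    gene_flags = np.zeros(max_len, dtype=np.int8)
    disease_flags = np.zeros(max_len, dtype=np.int8)
    confidences = np.zeros(max_len, dtype=np.float64)

    token_ids[0] = SOS
    for j, c in enumerate(content):
        pos = 1 + j
        token_ids[pos] = vocab.id_of(c.concept_id)
        category_idx[pos] = c.category_index
        gene_flags[pos] = int(c.is_gene_ontology)
        disease_flags[pos] = int(c.is_disease_ontology)
        confidences[pos] = c.confidence
    token_ids[1 + len(content)] = EOS

    return EncodedArticle(
        token_ids=token_ids,
        category_idx=category_idx,
        gene_flags=gene_flags,
        disease_flags=disease_flags,
        confidences=confidences,
        true_length=len(content) + 2,
    )


class ConceptAnnotator:
    """Interface: map raw text to an ordered concept sequence."""

    def annotate(self, text: str) -> list[ConceptToken]:  # pragma: no cover
        raise NotImplementedError


def annotate(text: str, annotator: ConceptAnnotator) -> list[ConceptToken]:
    """Run an annotator on raw text, surfacing failures with context."""
    try:
        return annotator.annotate(text)
    except Exception as exc:
        raise RuntimeError(f"annotation failed on text {text[:60]!r}...: {exc}") from exc


class MockAnnotator(ConceptAnnotator):
    """Dictionary-based annotator: exact lower-cased word lookup.

    ``lexicon`` maps surface words to ConceptTokens (or bare concept-id
    strings). Used by all tests and by the synthetic corpus generator; it
    stands in for an external concept tagger, not for any specific tool.
    """

    def __init__(self, lexicon: Mapping[str, ConceptToken | str]):
        self.lexicon = {
            k.lower(): (v if isinstance(v, ConceptToken) else ConceptToken(concept_id=v))
            for k, v in lexicon.items()
        }

    def annotate(self, text: str) -> list[ConceptToken]:
        tokens = re.findall(r"[A-Za-z0-9_']+", text.lower())
        return [self.lexicon[t] for t in tokens if t in self.lexicon]


# Minimal semantic-type → category-slot table for the MMI parser; unknown
# semantic types fall into the UNKNOWN_CATEGORY slot. A full mapping is
# annotator configuration, supplied via the `semtype_map` argument.
_DEFAULT_SEMTYPE_MAP = {
    "dsyn": 20,   # disease or syndrome
    "neop": 21,   # neoplastic process
    "gngm": 40,   # gene or genome
    "aapp": 41,   # amino acid, peptide, protein
    "orch": 60,   # organic chemical
    "phsu": 61,   # pharmacologic substance
    "bpoc": 80,   # body part, organ
    "celf": 90,   # cell function
    "patf": 91,   # pathologic function
}

_GENE_SEMTYPES = {"gngm"}
_DISEASE_SEMTYPES = {"dsyn", "neop"}


class MetaMapOutputParser(ConceptAnnotator):
    """Parser for MetaMap's pipe-delimited machine-readable (MMI) output.

    Never invokes the MetaMap binary: it consumes already-produced output
    text.  Each ``MMI`` line contributes one concept; the raw 0–1000 score
    is normalised to a [0, 1] confidence by division by 1000.  Concepts are
    ordered by their first character offset in the source text when
    positional information is present, else by line order.
    """

    def __init__(self, semtype_map: Mapping[str, int] | None = None):
        self.semtype_map = dict(semtype_map or _DEFAULT_SEMTYPE_MAP)

    def annotate(self, text: str) -> list[ConceptToken]:
        return self.parse(text)

    def parse(self, mmi_output: str) -> list[ConceptToken]:
        entries: list[tuple[int, int, ConceptToken]] = []
        for order, line in enumerate(mmi_output.splitlines()):
            fields = line.split("|")
            if len(fields) < 6 or fields[1] != "MMI":
                continue
            score = float(fields[2])
            cui = fields[4]
            semtypes = [s.strip() for s in fields[5].strip("[]").split(",") if s.strip()]
            category = next(
                (self.semtype_map[s] for s in semtypes if s in self.semtype_map),
                UNKNOWN_CATEGORY,
            )
            offset = order
            if len(fields) >= 9:
                m = re.search(r"(\d+)", fields[8])
                if m:
                    offset = int(m.group(1))
            entries.append(
                (
                    offset,
                    order,
                    ConceptToken(
                        concept_id=cui,
                        category_index=category,
                        confidence=min(score / 1000.0, 1.0),
                        is_gene_ontology=any(s in _GENE_SEMTYPES for s in semtypes),
                        is_disease_ontology=any(s in _DISEASE_SEMTYPES for s in semtypes),
                    ),
                )
            )
        entries.sort(key=lambda e: (e[0], e[1]))
        return [tok for _, _, tok in entries]
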