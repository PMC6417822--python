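"""The curated gene–trait association knowledge base.

One row per (gene, trait) pair: the association verdict, its aggregate
confidence, the supporting article identifiers (provenance), and how many
articles were read to reach the verdict. Upserts keep prior versions in a
history so curation runs remain auditable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

__all__ = ["AssociationRecord", "KnowledgeBase", "add_record", "export_kb", "import_kb"]

_TSV_COLUMNS = [
    "gene",
    "trait",
    "associated",
    "confidence",
    "supporting_ids",
    "n_articles_read",
    "timestamp",
]


@dataclass(frozen=True)
class AssociationRecord:
    gene: str
    trait: str
    associated: bool
    confidence: float
    supporting_ids: list[str] = field(default_factory=list)
    n_articles_read: int = 0
    timestamp: str = "1970-01-01T00:00:00"

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must be a probability")
        if self.associated and self.confidence > 0 and not self.supporting_ids:
            raise ValueError("a positive association with confidence > 0 needs supporting articles")


class KnowledgeBase:
    """Upsert store keyed on (gene, trait), with per-key history."""

    def __init__(self) -> None:
        self._records: dict[tuple[str, str], AssociationRecord] = {}
        self._history: dict[tuple[str, str], list[AssociationRecord]] = {}

    def __len__(self) -> int:
        return len(self._records)

    def get(self, gene: str, trait: str) -> AssociationRecord | None:
        return self._records.get((gene, trait))

    def history(self, gene: str, trait: str) -> list[AssociationRecord]:
        return list(self._history.get((gene, trait), []))

    def records(self) -> list[AssociationRecord]:
        """Records in deterministic (gene, trait) lexicographic order."""
        return [self._records[k] for k in sorted(self._records)]

    def add(self, record: AssociationRecord) -> "KnowledgeBase":
        key = (record.gene, record.trait)
        self._history.setdefault(key, []).append(record)
        self._records[key] = record
        return self


def add_record(kb: KnowledgeBase, record: AssociationRecord) -> KnowledgeBase:
    """Upsert ``record``; the newer version replaces the older in the main
    table while the prior version stays in the history."""
    return kb.add(record)


def export_kb(kb: KnowledgeBase, path: str | Path, format: str = "tsv") -> None:
    """Write the KB sorted by (gene, trait); round-trips via :func:`import_kb`."""
    records = kb.records()
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(_TSV_COLUMNS) + "\n")
            for r in records:
                fh.write(
                    "\t".join(
                        [
                            r.gene,
                            r.trait,
                            str(int(r.associated)),
                            f"{r.confidence:.6f}",
                            ";".join(r.supporting_ids),
                            str(r.n_articles_read),
                            r.timestamp,
                        ]
                    )
                    + "\n"
                )
    elif format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump([asdict(r) for r in records], fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown export format {format!r}")


def import_kb(path: str | Path, format: str = "tsv") -> KnowledgeBase:
    kb = KnowledgeBase()
    if format == "tsv":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != _TSV_COLUMNS:
                raise ValueError(f"unexpected KB header {header}")
            for line in fh:
                f = line.rstrip("\n").split("\t")
                kb.add(
                    AssociationRecord(
                        gene=f[0],
                        trait=f[1],
                        associated=bool(int(f[2])),
                        confidence=float(f[3]),
                        supporting_ids=f[4].split(";") if f[4] else [],
                        n_articles_read=int(f[5]),
                        timestamp=f[6],
                    )
                )
    elif format == "json":
        with open(path, encoding="utf-8") as fh:
            for d in json.load(fh):
                kb.add(AssociationRecord(**d))
    else:
        raise ValueError(f"unknown export format {format!r}")
    return kb
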