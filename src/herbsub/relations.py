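"""Abstract-level co-occurrence counting and relation classification.

Entities arrive pre-normalized to concept ids (named-entity recognition and
synonym resolution are upstream concerns).  A *link weight* is the number of
abstracts in which two entities co-occur; pairs are counted once per
abstract no matter how often either entity is mentioned in it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

VALID_ENTITY_TYPES = frozenset({"drug", "disease", "herb"})

#: entity-type pairs whose co-occurrence is counted (disease vs. drug or herb)
_COUNTED_TYPE_PAIRS = frozenset({frozenset({"drug", "disease"}), frozenset({"herb", "disease"})})


class DocumentParseError(ValueError):
    """A document record could not be parsed or validated."""


@dataclass(frozen=True)
class AnnotatedDocument:
    """One abstract with its typed, de-duplicated entity mentions."""

    doc_id: str
    mentions: frozenset[tuple[str, str]]  # (concept_id, entity_type)

    def __post_init__(self) -> None:
        for concept, etype in self.mentions:
            if etype not in VALID_ENTITY_TYPES:
                raise DocumentParseError(
                    f"document {self.doc_id!r}: unknown entity type {etype!r} "
                    f"for concept {concept!r}"
                )
        # a concept id may not carry two different types within one document
        seen: dict[str, str] = {}
        for concept, etype in self.mentions:
            if seen.setdefault(concept, etype) != etype:
                raise DocumentParseError(
                    f"document {self.doc_id!r}: concept {concept!r} has conflicting types"
                )

    @classmethod
    def from_mentions(cls, doc_id: str, mentions: Iterable[tuple[str, str]]) -> "AnnotatedDocument":
        return cls(doc_id=doc_id, mentions=frozenset(mentions))


class LinkWeightTable:
    """Symmetric map from an unordered concept pair to a co-occurrence count."""

    def __init__(self) -> None:
        self._weights: dict[tuple[str, str], int] = {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def increment(self, a: str, b: str, by: int = 1) -> None:
        key = self._key(a, b)
        self._weights[key] = self._weights.get(key, 0) + by

    def get(self, a: str, b: str) -> int:
        return self._weights.get(self._key(a, b), 0)

    def items(self) -> Iterator[tuple[tuple[str, str], int]]:
        return iter(self._weights.items())

    def __len__(self) -> int:
        return len(self._weights)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LinkWeightTable):
            return NotImplemented
        return self._weights == other._weights

    def total(self) -> int:
        return sum(self._weights.values())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for (a, b), count in sorted(self._weights.items()):
                fh.write(f"{a}\t{b}\t{count}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LinkWeightTable":
        table = cls()
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise DocumentParseError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
                table.increment(parts[0], parts[1], by=int(parts[2]))
        return table


@dataclass
class RelationTables:
    """Link weights split into drug→side-effect and drug→indication tables."""

    drug_se: dict[str, dict[str, int]] = field(default_factory=dict)
    drug_ind: dict[str, dict[str, int]] = field(default_factory=dict)

    def drugs(self) -> set[str]:
        return set(self.drug_se) | set(self.drug_ind)


def extract_pairs(documents: Iterable[AnnotatedDocument]) -> LinkWeightTable:
    """Count abstract-level co-occurrences of entities with distinct types.

    Each unordered (drug, disease) and (herb, disease) pair of distinct
    concepts in a document contributes exactly 1 to its link weight.
    Same-typed pairs (drug–drug, disease–disease, herb–herb) and
    drug–herb pairs are not counted.
    """
    table = LinkWeightTable()
    for doc in documents:
        by_type: dict[str, list[str]] = {}
        for concept, etype in doc.mentions:
            by_type.setdefault(etype, []).append(concept)
        for ta, tb in (("drug", "disease"), ("herb", "disease")):
            for a, b in product(by_type.get(ta, ()), by_type.get(tb, ())):
                if a != b:
                    table.increment(a, b)
    return table


def classify_relations(
    links: LinkWeightTable,
    se_dict: Mapping[str, set[str]],
    ind_dict: Mapping[str, set[str]],
) -> RelationTables:
    """Split drug–disease links by dictionary membership.

    A link (drug, disease) is copied into the side-effect table iff the
    disease is a known side effect of the drug, and into the indication
    table iff it is a known indication; a disease present in both
    dictionaries lands in both tables.  Links matching neither are dropped.
    Counts are copied verbatim, never rescaled.
    """
    out = RelationTables()
    for (a, b), count in links.items():
        for drug, disease in ((a, b), (b, a)):
            matched = False
            if disease in se_dict.get(drug, ()):
                out.drug_se.setdefault(drug, {})[disease] = count
                matched = True
            if disease in ind_dict.get(drug, ()):
                out.drug_ind.setdefault(drug, {})[disease] = count
                matched = True
            if drug in se_dict or drug in ind_dict:
                if not matched:
                    logger.debug("dropping unmatched link (%s, %s)=%d", drug, disease, count)
    return out


def read_documents(path: str | Path) -> Iterator[AnnotatedDocument]:
    """Read line-delimited JSON document records.

    Each line is an object ``{"doc_id": ..., "mentions": [[concept, type], ...]}``.
    """
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
                doc_id = record["doc_id"]
                mentions = [(str(c), str(t)) for c, t in record["mentions"]]
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise DocumentParseError(f"{path}:{lineno}: malformed document record: {exc}") from exc
            yield AnnotatedDocument.from_mentions(doc_id, mentions)


def write_documents(documents: Iterable[AnnotatedDocument], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in documents:
            record = {"doc_id": doc.doc_id, "mentions": sorted(doc.mentions)}
            fh.write(json.dumps(record, ensure_ascii=False) + "\n")


def read_dictionary(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column tab-separated (drug_id, concept_id) dictionary."""
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DocumentParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            out.setdefault(parts[0], set()).add(parts[1])
    return out


def write_dictionary(dictionary: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for drug in sorted(dictionary):
            for concept in sorted(dictionary[drug]):
                fh.write(f"{drug}\t{concept}\n")
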