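"""Classical Chinese prescription parsing and term matching.

Doses use the traditional mass ladder 1两 (liang) = 10钱 (qian) = 100分
(fen); everything is normalized to the smallest unit, the fen.  Indication
fields are free Chinese text; concept matching is raw substring containment
after Unicode canonical composition (NFC) — no word segmentation, since
clinically meaningful terms such as 头昏 must match inside longer runs like
头昏耳鸣.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

#: conversion factors to fen, the base unit
UNIT_IN_FEN: dict[str, int] = {"两": 100, "钱": 10, "分": 1}


class ComponentParseError(ValueError):
    """A component string did not match ``<herb><quantity><unit>``."""


class UnknownUnitError(ValueError):
    """A dose unit outside 两/钱/分."""


class AbsentHerbError(KeyError):
    """The requested herb does not occur in the prescription."""


def normalize_dose(quantity: float, unit: str) -> float:
    """Convert a dose to fen (两 ×100, 钱 ×10, 分 ×1)."""
    if quantity <= 0:
        raise ValueError(f"dose quantity must be positive, got {quantity}")
    try:
        return quantity * UNIT_IN_FEN[unit]
    except KeyError:
        raise UnknownUnitError(f"unknown dose unit {unit!r} (expected 两, 钱 or 分)") from None


@dataclass(frozen=True)
class DoseComponent:
    herb: str
    quantity: float
    unit: str

    def __post_init__(self) -> None:
        if self.quantity <= 0:
            raise ValueError(f"component {self.herb!r}: quantity must be positive")
        if self.unit not in UNIT_IN_FEN:
            raise UnknownUnitError(f"component {self.herb!r}: unknown unit {self.unit!r}")

    @property
    def dose_fen(self) -> float:
        return normalize_dose(self.quantity, self.unit)


_COMPONENT_RE = re.compile(r"^(?P<herb>.+?)(?P<qty>\d+(?:\.\d+)?)(?P<unit>[两钱分])$")


def parse_component(text: str) -> DoseComponent:
    """Parse a component string like ``白芍3钱`` into (herb, quantity, unit)."""
    stripped = unicodedata.normalize("NFC", text.strip())
    match = _COMPONENT_RE.match(stripped)
    if match is None:
        raise ComponentParseError(f"cannot parse prescription component {text!r}")
    return DoseComponent(
        herb=match.group("herb").strip(),
        quantity=float(match.group("qty")),
        unit=match.group("unit"),
    )


@dataclass
class Prescription:
    """One prescription: dosed components plus a free-text indication field."""

    rx_id: str
    components: list[DoseComponent]
    indication_text: str
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError(f"prescription {self.rx_id!r} has no components")
        self.indication_text = unicodedata.normalize("NFC", self.indication_text)

    @classmethod
    def parse(
        cls,
        rx_id: str,
        component_texts: Iterable[str],
        indication_text: str,
        source: str | None = None,
    ) -> "Prescription":
        return cls(rx_id, [parse_component(t) for t in component_texts], indication_text, source)

    def herbs(self) -> set[str]:
        return {c.herb for c in self.components}

    def total_dose_fen(self) -> float:
        return sum(c.dose_fen for c in self.components)

    def herb_dose_fen(self, herb: str) -> float:
        # duplicate entries for one herb are summed before proportions
        doses = [c.dose_fen for c in self.components if c.herb == herb]
        if not doses:
            raise AbsentHerbError(f"herb {herb!r} not in prescription {self.rx_id!r}")
        return sum(doses)


def dosage_proportion(rx: Prescription, herb: str) -> float:
    """Fraction of the prescription's total dose contributed by ``herb``."""
    return rx.herb_dose_fen(herb) / rx.total_dose_fen()


@dataclass
class ConceptLexicon:
    """Bilingual concept lexicon: concept id → (English name, Chinese synonyms).

    Synonym lists may legitimately be richer than any printed source; the
    lexicon is always an explicit input, never hard-coded into matching.
    """

    entries: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized = {}
        for concept, (english, synonyms) in self.entries.items():
            cleaned = [unicodedata.normalize("NFC", s) for s in synonyms if s.strip()]
            if not cleaned:
                raise ValueError(f"concept {concept!r} has no nonempty synonyms")
            normalized[concept] = (english, cleaned)
        self.entries = normalized

    def concepts(self) -> set[str]:
        return set(self.entries)

    def synonyms(self, concept: str) -> list[str]:
        return self.entries[concept][1]

    def subset(self, concepts: Iterable[str]) -> "ConceptLexicon":
        keep = set(concepts)
        return ConceptLexicon({c: v for c, v in self.entries.items() if c in keep})

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for concept in sorted(self.entries):
                english, synonyms = self.entries[concept]
                for syn in synonyms:
                    fh.write(f"{concept}\t{english}\t{syn}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConceptLexicon":
        entries: dict[str, tuple[str, list[str]]] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
                concept, english, syn = parts
                entry = entries.setdefault(concept, (english, []))
                if syn not in entry[1]:
                    entry[1].append(syn)
        return cls(entries)


def match_concept(synonyms: Iterable[str], text: str) -> bool:
    """True iff any synonym occurs as a contiguous substring of the text."""
    normalized = unicodedata.normalize("NFC", text)
    return any(unicodedata.normalize("NFC", syn) in normalized for syn in synonyms)


def intersection_count(lexicon: ConceptLexicon, indication_text: str) -> int:
    """Number of lexicon concepts with at least one synonym in the text.

    A concept counts once however many of its synonyms match.
    """
    text = unicodedata.normalize("NFC", indication_text)
    return sum(1 for _, (_, syns) in lexicon.entries.items() if match_concept(syns, text))


COMPONENT_JOIN = "、"


def write_prescriptions(rxs: Iterable[Prescription], path: str | Path) -> None:
    """Write a tab-separated prescription table (components joined by 、)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rx_id\tcomponents\tindication_text\tsource\n")
        for rx in rxs:
            comps = COMPONENT_JOIN.join(
                f"{c.herb}{c.quantity:g}{c.unit}" for c in rx.components
            )
            fh.write(f"{rx.rx_id}\t{comps}\t{rx.indication_text}\t{rx.source or ''}\n")


def read_prescriptions(path: str | Path) -> list[Prescription]:
    rxs = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("rx_id\t"):
            raise ValueError(f"{path}: missing prescription table header")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            rx_id, comps, indication, source = parts
            rxs.append(
                Prescription.parse(
                    rx_id, comps.split(COMPONENT_JOIN), indication, source or None
                )
            )
    return rxs
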