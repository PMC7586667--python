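"""Seeded synthetic corpora and prescription databases with planted structure.

The generator emulates the pipeline's seven inputs at desk scale.  There is
no generative model to copy for literature co-occurrence, so pair counts
are drawn as 1 + Poisson around a configurable mean and documents are then
materialized so that the realized link weights equal the drawn matrix
exactly — the drawn matrix doubles as the ground truth for oracle tests.

Planted structure drives recovery tests: one drug whose side-effect link
weights sit at a chosen multiple of each side effect's cross-drug mean
while its indication link sits below the mean (it should earn a replaceable
score above 1 and rank first), and one herb given a boosted dosage share in
indication-matching prescriptions whose texts are seeded with the drug's
side-effect synonyms (it should top the substitutability ranking).

Chinese strings for synthetic concepts come from fixed CJK alphabets so
that Unicode handling is exercised; side-effect synonyms and filler
vocabulary use disjoint alphabets, so a zero seeding rate really means zero
intersections.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from herbsub.prescriptions import UNIT_IN_FEN, ConceptLexicon, DoseComponent, Prescription
from herbsub.relations import AnnotatedDocument, LinkWeightTable

# disjoint CJK alphabets: side-effect synonyms vs filler indication text
_SE_ALPHABET = "疼痛眩晕呕吐烦躁惊悸忧惧燥渴汗喘咳嗽悸"
_FILLER_ALPHABET = "肝郁气滞血瘀脾虚湿热风寒表里阴阳虚实经络"
_HERB_ALPHABET = "芍药芎归苓术草参芪柴夏皮仁花叶根"


class SynthConfigError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass
class SynthConfig:
    """Configuration for the synthetic corpus and prescription generators.

    ``base_link_rate`` is the mean pair co-occurrence frequency;
    ``planted_se_multiplier``/``planted_ind_multiplier`` scale the planted
    drug's side-effect and indication links relative to the cross-drug
    mean; ``planted_dose_boost`` multiplies the planted herb's drawn dose;
    ``synonym_seeding_rate`` is the per-concept probability that one of the
    drug's side-effect synonyms is written into a prescription's indication
    text.
    """

    seed: int = 0
    n_drugs: int = 20
    n_side_effects: int = 8
    n_indications: int = 1
    n_docs: int = 0  # 0: derived from the drawn pair counts
    n_herbs: int = 12
    n_prescriptions: int = 30
    planted_drug: str = "drug_P"
    planted_se_multiplier: float = 3.0
    planted_ind_multiplier: float = 0.5
    planted_herb_boost: float = 2.0
    synonym_seeding_rate: float = 0.5
    base_link_rate: float = 10.0

    def __post_init__(self) -> None:
        counts = (self.n_drugs, self.n_side_effects, self.n_indications,
                  self.n_herbs, self.n_prescriptions)
        if any(c < 1 for c in counts):
            raise SynthConfigError("all entity counts must be >= 1")
        if min(self.planted_se_multiplier, self.planted_ind_multiplier,
               self.planted_herb_boost) <= 0:
            raise SynthConfigError("planted multipliers must be > 0")
        if not 0.0 <= self.synonym_seeding_rate <= 1.0:
            raise SynthConfigError("synonym_seeding_rate must lie in [0, 1]")
        if self.base_link_rate <= 0:
            raise SynthConfigError("base_link_rate must be > 0")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class SyntheticCorpus:
    documents: list[AnnotatedDocument]
    se_dict: dict[str, set[str]]
    ind_dict: dict[str, set[str]]
    true_links: LinkWeightTable
    planted_drug: str
    target_indication: str = "ind_0"


def _draw_count(rng: np.random.Generator, mean: float) -> int:
    return 1 + int(rng.poisson(max(mean - 1.0, 0.0)))


def generate_corpus(cfg: SynthConfig) -> SyntheticCorpus:
    """Draw a drug–disease link-weight matrix and materialize documents for it.

    Every drug is linked to every side effect and to the single target
    indication.  The planted drug's side-effect counts are set to the
    multiplier times each side effect's mean over the other drugs, and its
    indication count to the indication multiplier times the mean (floored
    at 1), so recovery tests have a known signal.
    """
    rng = np.random.default_rng(cfg.seed)
    drugs = [f"drug_{i:02d}" for i in range(cfg.n_drugs - 1)] + [cfg.planted_drug]
    side_effects = [f"se_{i}" for i in range(cfg.n_side_effects)]
    indications = [f"ind_{i}" for i in range(cfg.n_indications)]
    target_ind = indications[0]

    others = [d for d in drugs if d != cfg.planted_drug]
    links = LinkWeightTable()
    for se in side_effects:
        base = {d: _draw_count(rng, cfg.base_link_rate) for d in others}
        planted = max(1, round(cfg.planted_se_multiplier * float(np.mean(list(base.values())))))
        for d, c in base.items():
            links.increment(d, se, by=c)
        links.increment(cfg.planted_drug, se, by=planted)
    for ind in indications:
        base = {d: _draw_count(rng, cfg.base_link_rate) for d in others}
        if ind == target_ind:
            planted = max(1, round(cfg.planted_ind_multiplier * float(np.mean(list(base.values())))))
        else:
            planted = _draw_count(rng, cfg.base_link_rate)
        for d, c in base.items():
            links.increment(d, ind, by=c)
        links.increment(cfg.planted_drug, ind, by=planted)

    se_dict = {d: set(side_effects) for d in drugs}
    ind_dict = {d: set(indications) for d in drugs}

    # materialize: drug d appears in max-count documents; document j of drug d
    # carries every disease whose remaining count exceeds j
    documents: list[AnnotatedDocument] = []
    for d in drugs:
        disease_counts = {
            x: links.get(d, x) for x in side_effects + indications if links.get(d, x) > 0
        }
        for j in range(max(disease_counts.values(), default=0)):
            mentions = [(d, "drug")] + [
                (x, "disease") for x, c in sorted(disease_counts.items()) if c > j
            ]
            documents.append(AnnotatedDocument.from_mentions(f"{d}_doc{j:03d}", mentions))
    # pad with singleton documents (no countable pair) up to a requested size
    for j in range(len(documents), cfg.n_docs):
        documents.append(AnnotatedDocument.from_mentions(f"pad_doc{j:05d}", [("se_0", "disease")]))

    return SyntheticCorpus(
        documents=documents,
        se_dict=se_dict,
        ind_dict=ind_dict,
        true_links=links,
        planted_drug=cfg.planted_drug,
        target_indication=target_ind,
    )


def _token(rng: np.random.Generator, alphabet: str, length: int = 2) -> str:
    return "".join(rng.choice(list(alphabet)) for _ in range(length))


def generate_se_lexicon(cfg: SynthConfig, n_concepts: int = 10) -> ConceptLexicon:
    """Side-effect lexicon with 1–2 Chinese synonyms per concept."""
    rng = np.random.default_rng(cfg.seed + 1)
    entries = {}
    for i in range(n_concepts):
        n_syn = int(rng.integers(1, 3))
        synonyms = list({_token(rng, _SE_ALPHABET, 2) for _ in range(n_syn)})
        entries[f"sec_{i}"] = (f"side_effect_{i}", synonyms)
    return ConceptLexicon(entries)


@dataclass
class SyntheticPrescriptions:
    prescriptions: list[Prescription]
    herbs: list[str]
    planted_herb: str
    indication_synonym: str


def generate_prescriptions(
    cfg: SynthConfig, lexicon: ConceptLexicon
) -> SyntheticPrescriptions:
    """Prescription database with one dose-boosted, synonym-seeded herb.

    Half of the prescriptions carry the target-indication synonym in their
    indication text (the direct pool); the planted herb appears in every
    one of those with a dose boosted by ``planted_herb_boost``, and their
    texts include each side-effect concept with probability
    ``synonym_seeding_rate``.  Other text is filler drawn from an alphabet
    disjoint from the side-effect synonyms.
    """
    if not lexicon.entries:
        raise SynthConfigError("lexicon must be nonempty")
    rng = np.random.default_rng(cfg.seed + 2)
    herbs = []
    while len(herbs) < cfg.n_herbs:
        name = _token(rng, _HERB_ALPHABET, 2)
        if name not in herbs:
            herbs.append(name)
    planted = herbs[0]
    # the last herb is reserved for non-indication prescriptions so the
    # indirect scoring path always has at least one herb to exercise
    reserved = herbs[-1]
    indication_syn = _token(rng, _FILLER_ALPHABET, 3)
    units = ["两", "钱", "分"]

    rxs: list[Prescription] = []
    for i in range(cfg.n_prescriptions):
        is_direct = i % 2 == 0
        pool = [h for h in herbs[1:-1]]
        n_comp = int(rng.integers(4, min(8, len(pool)) + 1))
        chosen = list(rng.choice(pool, size=n_comp, replace=False))
        if not is_direct:
            chosen.append(reserved)
        components = []
        # draw comparable fen-equivalent doses, then express each in a
        # random unit (0.2两 = 2钱 = 20分) so all three units appear
        doses_fen = [float(rng.integers(1, 5)) * 10.0 for _ in chosen]
        for h, dose in zip(chosen, doses_fen):
            unit = units[int(rng.integers(0, 3))]
            components.append(DoseComponent(h, round(dose / UNIT_IN_FEN[unit], 2), unit))
        if is_direct:
            qty = round(cfg.planted_herb_boost * float(np.mean(doses_fen)), 2)
            components.insert(0, DoseComponent(planted, qty, "分"))

        tokens = [_token(rng, _FILLER_ALPHABET, 4) for _ in range(3)]
        if is_direct:
            tokens.insert(0, indication_syn)
            for concept in sorted(lexicon.entries):
                if rng.random() < cfg.synonym_seeding_rate:
                    tokens.append(lexicon.synonyms(concept)[0])
        text = "，".join(tokens) + "。"
        rxs.append(Prescription(f"rx_{i:03d}", components, text, source="synthetic"))
    return SyntheticPrescriptions(
        prescriptions=rxs,
        herbs=herbs,
        planted_herb=planted,
        indication_synonym=indication_syn,
    )


def write_manifest(cfg: SynthConfig, out_dir: str | Path) -> Path:
    """Record the seed and config hash next to generated outputs."""
    path = Path(out_dir) / "manifest.json"
    payload = {"seed": cfg.seed, "config_hash": cfg.config_hash(), "config": asdict(cfg)}
    path.write_text(json.dumps(payload, indent=2, ensure_ascii=False), encoding="utf-8")
    return path
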