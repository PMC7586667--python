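"""Drug scoring and candidate selection.

A drug's *side-effect score* for one side effect is its link weight divided
by that side effect's mean link weight across all drugs linked to it; the
cross-drug normalization keeps side effects that are common to many drugs
(headache, nausea) from inflating every drug's profile.  The *indication
score* is the analogous quantity on the indication table.  ``Rate_se`` is
the mean of a drug's side-effect scores over its observed side effects, and
the *replaceable score* for an indication is ``Rate_se`` divided by the
indication score: above 1, the drug's side-effect presence in the
literature outweighs its indication presence and an alternative is worth
looking for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from statistics import fmean

from herbsub.relations import RelationTables

logger = logging.getLogger(__name__)


class UndefinedScoreError(ValueError):
    """Raised when a score's denominator is empty or zero."""


def _cross_drug_mean(table: dict[str, dict[str, int]], concept: str) -> float:
    weights = [row[concept] for row in table.values() if concept in row]
    if not weights:
        raise UndefinedScoreError(f"concept {concept!r} is not linked to any drug")
    return fmean(weights)


def side_effect_score(drug: str, se: str, relations: RelationTables) -> float:
    """Link weight of (drug, se) over the side effect's cross-drug mean weight."""
    try:
        f_s = relations.drug_se[drug][se]
    except KeyError:
        raise UndefinedScoreError(f"no side-effect link ({drug!r}, {se!r})") from None
    return f_s / _cross_drug_mean(relations.drug_se, se)


def indication_score(drug: str, ind: str, relations: RelationTables) -> float:
    """Link weight of (drug, ind) over the indication's cross-drug mean weight."""
    try:
        f_i = relations.drug_ind[drug][ind]
    except KeyError:
        raise UndefinedScoreError(f"no indication link ({drug!r}, {ind!r})") from None
    return f_i / _cross_drug_mean(relations.drug_ind, ind)


@dataclass
class DrugScoreCard:
    """Per-drug normalized scores and derived ratios.

    ``se_scores`` maps each of the drug's observed side effects to its
    normalized score; ``rate_se`` is their arithmetic mean (the number of
    observed side effects plays the role of α).  ``replaceable`` maps each
    indication to ``rate_se / indication score``; indications with a zero
    score are omitted.
    """

    drug: str
    se_scores: dict[str, float] = field(default_factory=dict)
    ind_scores: dict[str, float] = field(default_factory=dict)

    @property
    def rate_se(self) -> float:
        if not self.se_scores:
            raise UndefinedScoreError(f"drug {self.drug!r} has no side-effect scores")
        return fmean(self.se_scores.values())

    @property
    def replaceable(self) -> dict[str, float]:
        rate = self.rate_se
        return {ind: rate / s for ind, s in self.ind_scores.items() if s > 0}


def rate_se(card: DrugScoreCard) -> float:
    """Mean side-effect score over the drug's observed side effects."""
    return card.rate_se


def replaceable_score(rate: float, ind_score: float) -> float:
    """Mean side-effect score divided by the indication score."""
    if ind_score <= 0:
        raise UndefinedScoreError(f"indication score must be positive, got {ind_score}")
    return rate / ind_score


def build_score_cards(relations: RelationTables) -> list[DrugScoreCard]:
    """Score every drug with at least one observed side-effect link."""
    cards = []
    for drug in sorted(relations.drugs()):
        ses = relations.drug_se.get(drug, {})
        if not ses:
            logger.debug("drug %s has no side-effect links; skipped", drug)
            continue
        card = DrugScoreCard(
            drug=drug,
            se_scores={se: side_effect_score(drug, se, relations) for se in ses},
            ind_scores={
                ind: indication_score(drug, ind, relations)
                for ind in relations.drug_ind.get(drug, {})
            },
        )
        cards.append(card)
    return cards


def select_candidates(
    cards: list[DrugScoreCard], indication: str, threshold: float = 1.0
) -> list[tuple[str, float]]:
    """Drugs whose replaceable score for ``indication`` strictly exceeds the threshold.

    Returns (drug, score) pairs sorted by descending score, ties broken
    lexicographically by drug id.  Drugs with no observed link to the
    indication are excluded (logged), not given an infinite score.
    """
    scored = []
    for card in cards:
        rep = card.replaceable.get(indication)
        if rep is None:
            logger.debug("drug %s has no usable link to indication %s; excluded", card.drug, indication)
            continue
        if rep > threshold:
            scored.append((card.drug, rep))
    scored.sort(key=lambda item: (-item[1], item[0]))
    return scored


def write_score_cards(
    cards: list[DrugScoreCard], indication: str, path: str | Path
) -> None:
    """Export cards as a tab-separated table for one target indication."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug\tside_effect_score\tindication\tindication_score\treplaceable_score\n")
        for card in cards:
            ind_score = card.ind_scores.get(indication)
            if ind_score is None or ind_score <= 0:
                continue
            fh.write(
                f"{card.drug}\t{card.rate_se:.7f}\t{indication}\t"
                f"{ind_score:.7f}\t{card.rate_se / ind_score:.7f}\n"
            )
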