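"""Herb substitutability scoring.

For a drug with a target indication, the substitutability of a herb is
``D × N``: the herb's mean dosage proportion across qualifying
prescriptions times the mean number of the drug's side-effect concepts
found in those prescriptions' indication texts.

A herb is *direct* when at least one prescription both contains it and
names the target indication; direct herbs get ``N = mean intersection + 1``
(the shared indication itself counts as one point of overlap).  Any other
herb in the database is *indirect*: its dosage proportion is propagated
from the direct herbs it co-occurs with — for each direct herb ``h``,
``(F_c / F_h) × D[h]`` where ``F_c`` is the number of prescriptions
containing both herbs and ``F_h`` the number containing the indirect herb —
summed over direct herbs; its ``N`` is the mean intersection count over all
prescriptions containing it, without the +1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from statistics import fmean
from typing import Iterable, Mapping, Sequence

from herbsub.prescriptions import (
    ConceptLexicon,
    Prescription,
    dosage_proportion,
    intersection_count,
    match_concept,
)


class NotDirectError(ValueError):
    """No qualifying prescription exists for the herb on the direct path."""


class UnknownHerbError(KeyError):
    """The herb does not occur anywhere in the prescription database."""


@dataclass(frozen=True)
class SubstitutabilityRecord:
    drug: str
    herb: str
    D: float
    N: float
    score: float
    mode: str  # "direct" | "indirect"
    n_prescriptions: int


def direct_substitutability(
    drug: str,
    drug_lexicon: ConceptLexicon,
    herb: str,
    rxs: Sequence[Prescription],
) -> SubstitutabilityRecord:
    """Score a direct herb over its qualifying prescriptions.

    ``rxs`` must be the prescriptions that contain the herb and whose
    indication text names the target indication; D and N are unweighted
    means over them.
    """
    if not rxs:
        raise NotDirectError(f"herb {herb!r} has no qualifying prescriptions for {drug!r}")
    D = fmean(dosage_proportion(rx, herb) for rx in rxs)
    N = fmean(intersection_count(drug_lexicon, rx.indication_text) for rx in rxs) + 1.0
    return SubstitutabilityRecord(
        drug=drug, herb=herb, D=D, N=N, score=D * N, mode="direct", n_prescriptions=len(rxs)
    )


def indirect_dosage(
    herb_ind: str,
    direct_D: Mapping[str, float],
    ctpd: Sequence[Prescription],
) -> float:
    """Propagate dosage proportion to an indirect herb.

    Sum over direct herbs of the co-occurrence fraction times the direct
    herb's dosage proportion.  Presence is at prescription level: a herb
    listed twice in one prescription counts once.
    """
    containing = [rx for rx in ctpd if herb_ind in rx.herbs()]
    f_h = len(containing)
    if f_h == 0:
        raise UnknownHerbError(f"herb {herb_ind!r} occurs in no prescription")
    total = 0.0
    for herb, D in direct_D.items():
        f_c = sum(1 for rx in containing if herb in rx.herbs())
        total += (f_c / f_h) * D
    return total


def indirect_substitutability(
    drug: str,
    drug_lexicon: ConceptLexicon,
    herb_ind: str,
    direct_D: Mapping[str, float],
    ctpd: Sequence[Prescription],
) -> SubstitutabilityRecord:
    """Score an indirect herb: propagated D times the mean intersection count."""
    containing = [rx for rx in ctpd if herb_ind in rx.herbs()]
    D = indirect_dosage(herb_ind, direct_D, ctpd)
    N = fmean(intersection_count(drug_lexicon, rx.indication_text) for rx in containing)
    return SubstitutabilityRecord(
        drug=drug,
        herb=herb_ind,
        D=D,
        N=N,
        score=D * N,
        mode="indirect",
        n_prescriptions=len(containing),
    )


def rank_alternatives(
    records: Iterable[SubstitutabilityRecord], k: int = 10
) -> list[SubstitutabilityRecord]:
    """Top-k records by descending score; ties broken by herb code-point order."""
    return sorted(records, key=lambda r: (-r.score, r.herb))[:k]


def rank_herbs_for_drug(
    drug: str,
    drug_lexicon: ConceptLexicon,
    indication_synonyms: Sequence[str],
    ctpd: Sequence[Prescription],
    k: int = 10,
) -> list[SubstitutabilityRecord]:
    """Score every herb in the database for one drug and return the top k.

    Prescriptions whose indication text names the target indication define
    the direct herbs; every other herb present in the database is scored
    indirectly.  A herb qualifying as direct is never also scored
    indirectly.
    """
    indicated = [rx for rx in ctpd if match_concept(indication_synonyms, rx.indication_text)]
    direct_rxs: dict[str, list[Prescription]] = {}
    for rx in indicated:
        for herb in rx.herbs():
            direct_rxs.setdefault(herb, []).append(rx)

    records = [
        direct_substitutability(drug, drug_lexicon, herb, rxs)
        for herb, rxs in direct_rxs.items()
    ]
    direct_D = {r.herb: r.D for r in records}

    all_herbs = set().union(*(rx.herbs() for rx in ctpd)) if ctpd else set()
    for herb in sorted(all_herbs - set(direct_rxs)):
        records.append(indirect_substitutability(drug, drug_lexicon, herb, direct_D, ctpd))
    return rank_alternatives(records, k=k)


def write_records(records: Iterable[SubstitutabilityRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug\therb\tmode\tD\tN\tscore\tn_prescriptions\n")
        for r in records:
            fh.write(
                f"{r.drug}\t{r.herb}\t{r.mode}\t{r.D:.6f}\t{r.N:.6f}\t"
                f"{r.score:.6f}\t{r.n_prescriptions}\n"
            )
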