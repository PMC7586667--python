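"""Bundled antidepressant case-study data.

A small, fully worked example used throughout the documentation and tests:
two classical prescriptions containing 白芍 (white peony root), the
mirtazapine side-effect lexicon used to count term intersections in their
indication texts, a 12-drug antidepressant score table (mean side-effect
score and depression indication score per drug, with DrugBank-style
toxicity and half-life text fields), and the group-mean toxicity/half-life
summary for selected versus unselected drugs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from herbsub.prescriptions import ConceptLexicon, Prescription
from herbsub.validation import DrugProfile

#: the case study's target indication (major depression), with the Chinese
#: synonym appearing in classical indication texts
DEPRESSION = ("depression", ["抑郁", "抑郁症"])


def load_example_prescriptions() -> list[Prescription]:
    """Two classical prescriptions containing 白芍, indicated for depression."""
    rx1 = Prescription.parse(
        "rx1",
        ["当归2钱", "白芍3钱", "柴胡2钱", "茯苓3钱", "薄荷1钱", "丹皮2钱",
         "山栀仁2钱", "白术3钱", "泽兰叶4钱", "郁金2钱", "甘草1钱"],
        "经闭气郁证, 肝郁气滞, 经闭不行, 面色青黄, 精神抑郁, 烦躁性急, "
        "头昏耳鸣, 胸胁作胀, 食少嗳气, 舌尖红, 口燥, 脉弦数或弦紧。",
    )
    rx2 = Prescription.parse(
        "rx2",
        ["当归1钱", "白芍1钱", "茯苓1钱", "白术1钱", "贝母1钱", "熟地1钱",
         "山栀1钱", "半夏6分", "人参6分", "柴胡6分", "丹皮6分", "陈皮6分",
         "香附6分", "川芎6分", "甘草4分"],
        "暴怒伤肝, 抑郁忧思, 致肝火妄动, 发为鬓疽, 头眩, 痛彻太阳, "
        "胸膈痞连两胁, 呕酸水。",
    )
    return [rx1, rx2]


def load_mirtazapine_lexicon() -> ConceptLexicon:
    """Mirtazapine side-effect concepts with their Chinese synonyms.

    Concepts with no classical Chinese equivalent (bradycardia,
    orthostatic hypotension) carry only an English placeholder synonym and
    can never match classical indication text.
    """
    return ConceptLexicon({
        "insomnia": ("insomnia", ["不寐"]),
        "agitation": ("agitation", ["烦躁"]),
        "anxiety": ("anxiety", ["忧"]),
        "erectile_dysfunction": ("erectile dysfunction", ["经隧失职"]),
        "nausea": ("nausea", ["恶心"]),
        "vomiting": ("vomiting", ["呕", "吐"]),
        "arrhythmia": ("arrhythmia", ["心悸"]),
        "bradycardia": ("bradycardia", ["bradycardia"]),
        "dizziness": ("dizziness", ["头昏", "头眩"]),
        "dry_mouth": ("dry mouth", ["口燥"]),
        "orthostatic_hypotension": ("orthostatic hypotension", ["orthostatic hypotension"]),
        "hallucination": ("hallucination", ["妄见"]),
        "tachycardia": ("tachycardia", ["心跳过速"]),
    })


@dataclass(frozen=True)
class AntidepressantRow:
    drug: str
    se_score: float  # mean side-effect score (Rate_se)
    ind_score: float  # depression indication score
    toxicity_text: str = ""
    half_life_text: str = ""


#: 12 antidepressants with their mean side-effect score and depression
#: indication score; the first 7 have replaceable score above 1
ANTIDEPRESSANT_SCORES: list[AntidepressantRow] = [
    AntidepressantRow(
        "Nefazodone", 0.33333, 0.0794702,
        "Cases of life-threatening hepatic failure have been reported in "
        "patients treated with nefazodone.", "2–4 h"),
    AntidepressantRow("Milnacipran", 0.62295879, 0.1589404,
                      "Oral LD50 rat: 213 mg/kg", "6–8 h"),
    AntidepressantRow("Mianserin", 0.34600026, 0.1192,
                      "Oral LD50 rat: 780 mg/kg", "10–17 h"),
    AntidepressantRow("Trazodone", 0.81612163, 0.31788079,
                      "Oral LD50 rat: 690 mg/kg", "7.3 +/− 0.8 h."),
    AntidepressantRow("Nortriptyline", 0.3283245, 0.1589404,
                      "Oral LD50 rat: 405 mg/kg", "26 h"),
    AntidepressantRow(
        "Duloxetine", 0.99170246, 0.91390728,
        "Fatalities have been reported with doses of 1000 mg involving "
        "both mixed drugs as well as duloxetine alone", "12 h"),
    AntidepressantRow(
        "Clomipramine", 0.41045464, 0.39735099,
        "One death involved a patient suspected of ingesting a dose of "
        "7000 mg. The second death involved a patient suspected of "
        "ingesting a dose of 5750 mg.", "32 h"),
    AntidepressantRow("Reboxetine", 0.36668174, 0.47682119,
                      "Reports of seizures (rare) have been reported", "12.5 h"),
    AntidepressantRow("Mirtazapine", 0.59422385, 0.95364238,
                      "Oral LD50 rat: 830 mg/kg in male Swiss mice", "20–40 h"),
    AntidepressantRow(
        "Venlafaxine", 0.81547802, 1.43046358,
        "Overdose of venlafaxine is typically associated with mild symptoms", "5 h"),
    AntidepressantRow("Citalopram", 0.92540653, 1.82781457,
                      "Oral LD50 rat:179 mg/kg", "35 h"),
    AntidepressantRow(
        "Fluoxetine", 0.86558296, 5.16556291,
        "In a report that included 234 fluoxetine overdose cases, it was "
        "concluded that symptoms resulting from fluoxetine overdose were "
        "generally minor and short in duration", "1–3 days"),
]


#: group-mean toxicity (oral LD50 rat, mg/kg) and half-life (hours) for the
#: selected (obvious side-effect) and unselected drug groups
GROUP_MEANS = {
    "selected": {"toxicity": 1667.57, "half_life": 10.87},
    "unselected": {"toxicity": 2609.07, "half_life": 12.58},
}


def load_antidepressant_profiles() -> list[DrugProfile]:
    """The 12 antidepressants' toxicity/half-life text fields as profiles."""
    return [
        DrugProfile(drug=row.drug, ld50_text=row.toxicity_text,
                    half_life_text=row.half_life_text)
        for row in ANTIDEPRESSANT_SCORES
    ]


@dataclass
class CaseStudyBundle:
    prescriptions: list[Prescription] = field(default_factory=load_example_prescriptions)
    mirtazapine_lexicon: ConceptLexicon = field(default_factory=load_mirtazapine_lexicon)
    antidepressants: list[AntidepressantRow] = field(
        default_factory=lambda: list(ANTIDEPRESSANT_SCORES)
    )
    group_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in GROUP_MEANS.items()}
    )


def load_case_study() -> CaseStudyBundle:
    """The full antidepressant worked-example bundle."""
    return CaseStudyBundle()
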