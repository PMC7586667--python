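# herbsub

Cross-lingual literature-based discovery of herbal alternatives for drugs
with obvious side effects.

`herbsub` is for researchers mining biomedical literature across English
and Chinese sources. It answers two questions:

1. **Which drugs most need an alternative?** From abstract-level
   co-occurrence counts (*link weights* `f`), each drug–side-effect pair
   gets a score `f_s / mean(f_s across drugs)`, each drug–indication pair
   analogously. With `Rate_se` the mean of a drug's side-effect scores,
   the **replaceable score** for an indication is
   `Rate_se / indication_score`; above 1, the drug's side-effect footprint
   in the literature outweighs its indication footprint.
2. **Which herbs could substitute?** For a candidate drug, herbs from a
   classical prescription database are scored by **substitutability**
   `D × N`: the herb's mean dosage proportion (doses normalized on the
   1两 = 10钱 = 100分 ladder) times the mean number of the drug's
   side-effect concepts found in the prescriptions' Chinese indication
   texts (+1 for herbs directly co-prescribed with the target indication;
   herbs never co-prescribed with it get a dosage proportion propagated
   through co-occurring direct herbs instead).

Candidate selections can be sanity-checked against oral LD50 / half-life
profiles, and herb mechanisms inspected through an OB/DL-filtered
herb–ingredient–target–disease graph. See `docs/methods.md` for the full
model.

## Worked example

The package bundles a small antidepressant case study: two classical
prescriptions containing 白芍 (white peony root) and the side-effect
lexicon of mirtazapine.

```python
from herbsub.datasets import load_case_study
from herbsub.prescriptions import dosage_proportion, intersection_count
from herbsub.substitutability import direct_substitutability
from herbsub.ranking import replaceable_score

bundle = load_case_study()
rx1, rx2 = bundle.prescriptions
lex = bundle.mirtazapine_lexicon
for rx in (rx1, rx2):
    print(f"{rx.rx_id}: proportion={dosage_proportion(rx, '白芍'):.3f} "
          f"intersections={intersection_count(lex, rx.indication_text)}")
rec = direct_substitutability("mirtazapine", lex, "白芍", [rx1, rx2])
print(f"D={rec.D:.3f}  N={rec.N:.0f}  substitutability={rec.score:.3f}")
row = bundle.antidepressants[0]
print(f"{row.drug}: replaceable={replaceable_score(row.se_score, row.ind_score):.7f}")
```

prints

```
rx1: proportion=0.120 intersections=3
rx2: proportion=0.086 intersections=3
D=0.103  N=4  substitutability=0.412
Nefazodone: replaceable=4.1944024
```

白芍 contributes 3 of 25 钱 to prescription 1 (0.12) and 10 of 116 分 to
prescription 2 (0.086); three mirtazapine side-effect concepts (烦躁,
头昏, 口燥 in one text; 忧, 呕, 头眩 in the other) appear in each
indication text. Averaging and adding 1 for the shared depression
indication gives substitutability (3 + 1) × 0.103 ≈ 0.412. Nefazodone's
replaceable score of ≈ 4.19 makes it the strongest candidate for
replacement among the twelve bundled antidepressants.

## Command line

The same pipeline is exposed as subcommands:

```sh
herbsub simulate --seed 1 --out-dir synthetic/      # seeded synthetic inputs
herbsub score-drugs --documents synthetic/documents.jsonl \
    --se-dict synthetic/se_dict.tsv --ind-dict synthetic/ind_dict.tsv \
    --target-indication ind_0 --out-dir out/
herbsub rank-herbs --drug drug_P --lexicon synthetic/se_lexicon.tsv \
    --indication-synonyms 抑郁 --prescriptions synthetic/prescriptions.tsv \
    --out-dir out/
herbsub evaluate --selected sel.tsv --unselected unsel.tsv --out-dir out/
herbsub hitd-graph --herb-ingredients hi.tsv --ingredient-targets it.tsv \
    --target-diseases td.tsv --drug-diseases dd.txt --out-dir out/
```

All I/O is UTF-8 tab-separated text (documents are JSON lines).

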