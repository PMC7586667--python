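# Methods

## Problem and model

`herbsub` implements a cross-lingual literature-based-discovery pipeline
that (a) flags Western drugs whose side effects are disproportionately
visible in the literature relative to their indications, and (b) ranks
traditional Chinese medicine (TCM) herbs as candidate alternatives for a
flagged drug using classical prescription databases.

**Link weights.** Entities (drugs, herbs, diseases) are linked when they
co-occur in a single abstract; the link weight `f` is the number of
abstracts containing both. Co-occurrence is at abstract granularity: a pair
counts once per abstract regardless of mention multiplicity. Only
drug–disease and herb–disease pairs are counted. Drug–disease links are
split into side-effect relations (disease is in the drug's SIDER-style
side-effect set) and indication relations (TTD-style indication set); a
disease in both sets for the same drug is kept in both tables, since
dropping either would silently bias the scores.

**Drug scoring.** For drug *d* and side effect *s* with link weight
`f_s(d)`,

    se_score(d, s) = f_s(d) / mean_{d'} f_s(d')

where the mean runs over all drugs linked to *s*. The cross-drug
denominator is deliberate: a side effect common to many drugs (headache,
nausea) has a large mean and cannot inflate any single drug's profile.
The indication score is defined identically on the indication table.
With α the number of the drug's observed side effects,

    Rate_se(d)        = (1/α) Σ_s se_score(d, s)
    replaceable(d, i) = Rate_se(d) / ind_score(d, i)

A drug whose replaceable score for the target indication strictly exceeds
1 is a candidate for replacement; candidates are ranked descending, ties
broken lexicographically by drug id. By construction the per-concept mean
of scores across its drugs is exactly 1 (the normalization identity
asserted in the property suite). Drugs with no observed link to the target
indication are excluded from the ranking (logged), not given an infinite
score. α counts side effects observed in the corpus, not the dictionary's
full list.

**Substitutability.** Doses use the traditional mass ladder 1两 = 10钱 =
100分 and are normalized to fen. For a prescription, a herb's dosage
proportion is its (duplicate-summed) fen dose over the prescription total.
A herb is *direct* for a drug's target indication if at least one
prescription both contains the herb and names the indication in its
free-text indication field. Over those qualifying prescriptions,

    D = mean dosage proportion
    N = mean |SE_Chinese ∩ indication text| + 1
    substitutability = D × N

The +1 credits the shared indication itself. The intersection counts
side-effect *concepts* (a concept with several matching synonyms counts
once); matching is raw substring containment after Unicode NFC
normalization, with no word segmentation — clinically meaningful terms
like 头昏 must match inside longer runs such as 头昏耳鸣.

Herbs present in the database but never co-prescribed with the indication
are *indirect*: their dosage proportion is propagated from the direct
herbs they co-occur with,

    D_indirect = Σ_h (F_c(h) / F_h) × D(h)

summed over direct herbs *h*, where `F_h` is the number of prescriptions
containing the indirect herb and `F_c(h)` the number containing both
(prescription-level presence; a herb listed twice counts once). Their N is
the mean intersection count over all prescriptions containing them, with
no +1. A herb qualifying as direct is never also scored indirectly. The
top-k ranking (default 10) is descending by score with ties broken by herb
code-point order, so output is deterministic.

**Validation.** Selected versus unselected drugs are compared on DrugBank
style free-text fields: oral LD50 in rat (mg/kg) and elimination
half-life (hours). Bucketed values ("2–4 h") take the midpoint — the
median rule is applied uniformly to toxicity and half-life ranges for
symmetry — "x +/− y" forms take the central value, day units are
multiplied by 24, and en-dash, hyphen and "to" are all accepted range
separators. A toxicity figure must carry the mg/kg unit; narrative case
reports therefore parse to "absent" and are excluded from the group mean
rather than defaulted. The headline statistic is the ratio of unselected
to selected mean LD50 (above 1 means the selected drugs are on average
more toxic). The herb–ingredient–target–disease (HITD) graph admits an
ingredient only under the standard TCMSP filters, oral bioavailability
strictly > 30% and drug-likeness strictly > 0.18 (boundary values are
excluded), keeps only diseases in the focal drug's side-effect/indication
set, and drops nodes left without edges.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `replaceable_threshold` | 1.0 | — | strict cut for candidate drugs |
| `top_k` | 10 | herbs | alternatives reported per drug |
| `ob_threshold` | 30 | % | strict oral-bioavailability filter |
| `dl_threshold` | 0.18 | — | strict drug-likeness filter |
| base dose unit | 分 (fen) | mass | 1两 = 10钱 = 100分 |

## Synthetic data

The generator (`herbsub.synthetic`) emulates all seven pipeline inputs at
desk scale. Pair counts are drawn as `1 + Poisson(base_link_rate − 1)`
(default mean 10, a realistic abstract-level co-occurrence frequency at
which relative Poisson noise is small); documents are then materialized so
that the realized link weights equal the drawn matrix exactly, which makes
the drawn matrix a ground-truth oracle. One planted drug's side-effect
links are set to a chosen multiple (default 3×) of each side effect's
cross-drug mean and its indication link to 0.5× the mean, so it should
earn a replaceable score above 1 and rank first. One planted herb appears
in every indication-matching prescription with a dose equal to a boost
(default 2×) times the mean component dose; indication texts are seeded
with side-effect synonyms at a configurable rate. Side-effect synonyms and
filler vocabulary come from disjoint CJK alphabets, so a zero seeding rate
guarantees zero intersections; component doses are drawn as fen-equivalent
magnitudes rendered in a random unit (0.2两 = 2钱 = 20分) so all three
units are exercised without unit choice dominating proportions; the last
herb is reserved for non-indication prescriptions so the indirect path
always has something to score. Default study conditions: 20 drugs, 8 side
effects, 1 indication, 12 herbs, 30 prescriptions — small enough that the
full property suite (including 20-seed recovery runs) completes in
seconds.

What the generator does **not** emulate: named-entity recognition noise,
synonym-resolution errors, citation dynamics, realistic MeSH/CTPD
vocabularies, correlated side-effect profiles, and dose-form or
non-mass-unit variation. Passing recovery tests therefore shows that the
statistics recover planted structure under clean annotation, not that the
pipeline is robust to upstream extraction error.

## Numerical choices

- Scores are carried at full float precision; exports round to 7 decimals
  (score card) or 6 (substitutability records).
- All selection comparisons are strict (`> 1`, `> 30`, `> 0.18`).
- All rankings have total, deterministic orders (score descending, then
  lexicographic / code-point tie-break).
- Unicode NFC normalization is applied to all Chinese text before
  containment tests; comma variants and whitespace are left in place.
- Fractional dose quantities (e.g. 0.5两) are accepted and convert
  exactly for decimal inputs.
- Degenerate inputs raise typed errors rather than returning sentinel
  values: empty qualifying prescription sets (`NotDirectError`, callers
  fall back to the indirect path), unknown units, herbs absent from a
  prescription, concepts linked to no drug, zero indication scores,
  groups with no parseable toxicity value.

## Limitations

- The indirect dosage proportion is a sum over direct herbs and is not
  bounded by 1; it is a propagation score, not a fraction.
- The indirect intersection mean runs over all prescriptions containing
  the herb, not only those co-containing a direct herb.
- Substring matching cannot distinguish negated or historical mentions in
  indication text, and single-character synonyms (忧, 呕) will match
  inside unrelated compounds.
- Bilingual lexicons are inputs; the package performs no translation, and
  ranking quality is bounded by lexicon coverage.
- Full-corpus quantities (tens of thousands of abstracts, complete
  SIDER/TTD/TCMSP snapshots) are out of desk scale; properties asserted on
  synthetic data stand in for them.
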