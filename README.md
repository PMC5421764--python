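# sobrenome

Surname-ancestry classification for population rosters.

Census surveys in Brazil record colour/race in five broad categories but no
ancestry. Because the major immigrant groups that arrived after 1872 —
Iberian, Italian, German, Japanese and East European — left distinctive
surname orthographies, the ancestry *of a surname* can be inferred from its
spelling and from historical immigrant registers. `sobrenome` implements
that inference end to end, for demographers, epidemiologists and economists
who need an ancestry signal at individual or municipal scale:

1. **Reference building** — merge conflicting historical surname→ancestry
   source lists under three auditable rules: keep a surname within a source
   only when more than 90% of its registrations agree on one ancestry; drop
   surnames occurring fewer than 8 times in noisy census-type sources; let a
   designated priority source win cross-source conflicts.
2. **Fuzzy matching** — Optimal String Alignment (OSA) distance, the
   restricted Damerau–Levenshtein metric with unit-cost insertions,
   deletions, substitutions and adjacent transpositions. Matching is
   exact-first with a conservative cap *d* = 1 and refuses ambiguous
   equidistant candidates. Example: OSA(MUELLER, MILLER) = 2, so the pair
   matches at *d* = 2 but not at *d* = 1.
3. **n-gram classifiers** for surnames the matcher cannot place:
   Cavnar–Trenkle rank-profile categorization over padded character
   trigrams (profiles of the 1,250 most frequent trigrams per class,
   out-of-place distance Σ|rank displacement| with a maximum penalty for
   absent trigrams), and multinomial Naive Bayes,
   ĉ = argmax_y log P(y) + Σ_g log P(g | y), with add-α smoothing.
4. **Evaluation** — seeded train/test splits, row-normalized confusion
   matrices, overall accuracy and Cohen's κ = (p_o − p_e)/(1 − p_e).
5. **Population pipeline** — the exact → fuzzy → trigram cascade over a
   roster, the census colour/race override (black/mixed/native take
   precedence over the surname class), the immigrant-ancestry index
   (0 = exclusively Iberian surnames, 0.5 = one of two non-Iberian,
   1 = exclusively non-Iberian) and its aggregation by region as
   rate = Σ index / n.
6. **Synthetic data** — Markov or disjoint-alphabet surname generators,
   Zipf-skewed surname popularity calibrated so the five most common
   surnames cover ≈45% of roster occurrences, two surnames per person,
   and single-edit typo injection — so the whole cascade is testable
   without access to restricted administrative rosters.

## Worked example

```sh
sobrenome --seed 42 simulate --out-dir demo --roster-size 5000 --surnames-per-class 400
sobrenome train    --reference demo/reference.csv --out demo/ct.json
sobrenome --seed 42 evaluate --reference demo/reference.csv --out demo/eval.json
sobrenome classify --reference demo/reference.csv --model demo/ct.json \
                   --roster demo/roster.csv --out demo/labeled.csv
sobrenome index    --labeled demo/labeled.csv --out demo/regions.csv
```

prints

```
wrote 1995 reference surnames and 5000 persons to demo
ct model -> demo/ct.json
accuracy=0.892 kappa=0.865 (n_test=399)
stage counts (surname occurrences): ct=146, exact=8999, fuzzy=855
8 regions -> demo/regions.csv (0 persons without region)
```

Reading the output: a synthetic reference of 1,995 surnames (five Markov
classes) trains a trigram model whose held-out accuracy on 399 test
surnames is 89.2% (κ = 0.865, far above the 20% five-class chance level).
Of the 10,000 surname occurrences in the 5,000-person roster, 90.0% resolve
by exact lookup, 8.6% by fuzzy matching at *d* = 1 (the generator corrupted
10% of occurrences with single-edit typos, some of which collide back into
the reference) and 1.5% fall through to the trigram classifier. The final
CSV aggregates the ancestry index by region, e.g. region R00 holds 611
persons with mean index 0.139.

The same flow is available as a library:

```python
from sobrenome import ancestry_index, osa_distance, AncestryLabel as A

osa_distance("MUELLER", "MILLER")      # 2
ancestry_index([A.IBR, A.GER])         # 0.5
```

## Layout

| module | contents |
| --- | --- |
| `sobrenome.reference` | source parsing, the three resolution rules, build log |
| `sobrenome.normalize` | diacritic folding, particle removal, first-name splitting |
| `sobrenome.matching` | OSA distance, symmetric-deletion index, conservative matcher |
| `sobrenome.classifiers` | trigram machinery, Cavnar–Trenkle, Naive Bayes, JSON models |
| `sobrenome.evaluation` | splits, confusion matrix, accuracy, Cohen's kappa |
| `sobrenome.pipeline` | cascade, colour override, ancestry index, regional rates |
| `sobrenome.synthetic` | Markov/disjoint generators, Zipf calibration, typo injection |
| `sobrenome.cli` | `simulate`, `build-ref`, `train`, `evaluate`, `classify`, `index` |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
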