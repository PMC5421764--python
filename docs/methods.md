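# Methods

This note documents the models and procedures implemented in `sobrenome`,
the defaults they ship with, and what the synthetic-data experiments do and
do not demonstrate.

## Problem setting

Given (a) several historical lists associating surnames with one of five
ancestry classes — Iberian (IBR), Italian (ITA), German (GER), Japanese
(JPN), East European (EAS) — and (b) a contemporary roster in which each
person carries up to two inherited surnames, assign an ancestry to every
surname and derive person-level quantities: a combined ancestry/colour
category and an immigrant-ancestry index. The surname, not the person, is
the unit of inference: populations that historically adopted Iberian
surnames are deliberately captured through the census colour/race override,
not through spelling.

## Reference construction

Sources disagree, so the builder applies three rules, in order:

1. **Within-source agreement.** For each surname within one source, let
   *f* be the share of registrations carried by the modal ancestry. The
   surname is kept (with the modal label and summed count) only when
   *f* strictly exceeds `agreement_threshold` (default 0.90). The
   strictness matters at the boundary: 9 of 10 registrations is dropped.
2. **Minimum counts.** Per-source minimum total occurrences
   (`min_count_sources`), meant for noisy high-volume sources such as
   census micro-data, where the conventional minimum is 8: counts 1–7 are
   removed, 8 is kept. Sources without a configured minimum use 1. Pure
   name lists without counts get an implicit count of 1 per row.
3. **Cross-source merge.** Identical labels merge. In a conflict, a
   configured `priority_source` wins whenever it carries the surname;
   otherwise the label with the larger summed count wins and exact ties
   are dropped. Dropping ties is the conservative choice: the matcher
   downstream refuses uncertain assignments, and the builder behaves the
   same way. The 90% rule is not re-applied after merging — each surviving
   surname has exactly one record per source by then, so re-application
   would change nothing.

Every drop (ambiguous, under-count, tie) is recorded in a build log
written beside the table; cleaning is auditable by design.

## Normalization

Matching and n-gram statistics require one canonical alphabet. Tokens are
NFKD-decomposed, stripped of combining marks, uppercased, and reduced to
A–Z; hyphenated surnames concatenate into a single token (one token per
inherited surname). Connective particles (DA, DE, DOS, VON, VAN, DI, …)
are removed as full-token matches; the set is a plain-text resource and
configurable. Given names are separated by greedy left-to-right
consumption against a bundled given-name lexicon; a multi-token name
always surrenders at least its leading token (roster rows begin with a
given name by construction, whether or not the lexicon knows it), and a
single token is treated as a unique surname only when the lexicon does
not claim it. Names with nothing left after consumption are flagged "no
surname", excluded downstream and counted — never silently dropped. The
lexicon-based splitter is a documented heuristic; the lexicon is a
swappable resource file.

## Fuzzy matching

The distance is Optimal String Alignment (OSA): unit-cost insertions,
deletions, substitutions and adjacent transpositions, no substring edited
twice. OSA violates the triangle inequality (CA→AC = 1 yet CA→ABC = 3 >
CA→AC→ABC), so no metric pruning is used. Candidate generation uses a
symmetric-deletion index (all variants of reference surnames with up to
*d* characters deleted); every candidate is verified with the exact
dynamic program, and the test suite asserts bit-identical results against
exhaustive search.

Matching is exact-first. Among fuzzy candidates within the cap the
smallest distance is preferred; equidistant candidates must agree
unanimously on ancestry, otherwise the query stays unmatched. The default
cap `max_distance=1` is the conservative production value: single typing
errors are recovered, anything farther is left to the classifier.

## Trigram classifiers

Surnames are expanded to character n-grams (default n = 3) after padding
with n−1 underscores per side, so boundary information survives: LIMA →
__L, _LI, LIM, IMA, MA_, A__ (L+n−1 grams for a length-L surname).

**Cavnar–Trenkle.** Each class keeps its `profile_size` (default 1,250)
most frequent trigrams, ranked count-descending with lexicographic
tie-break for determinism. A query surname's own trigrams are ranked the
same way (within-surname frequency, ties lexicographic). The out-of-place
distance sums |query rank − profile rank|, charging `profile_size` for
grams absent from the profile — the convention of the original method;
a `profile_rank` mode (charge the profile rank alone) is available behind
a flag because the verbal description of the measure admits both
readings. Classification is the argmin over classes, ties broken in the
fixed order IBR, ITA, GER, JPN, EAS and flagged. The defaults n = 3 /
1,250 were originally chosen by accuracy search; `grid_search_ct`
reproduces that search on any training set.

**Naive Bayes.** Multinomial over trigram tokens: priors are class shares
of training surnames; likelihoods use add-α smoothing (α = 1) over the
union vocabulary plus one unseen slot, so every gram has strictly
positive probability in every class. Scoring is MAP in log space,
argmax_y log P(y) + Σ_g log P(g|y), with posteriors normalized by
log-sum-exp. The event model and smoothing are standard choices; nothing
in the procedure's published description constrains them.

Both models serialize to JSON losslessly (profiles as ordered arrays,
likelihoods as log-probability maps).

## Evaluation

`split_train_test` draws a seeded uniform split (round(N·f) test items,
f = 0.2 by default); a stratified variant exists behind a flag since the
original protocol does not state stratification. The confusion matrix is
stored as raw counts, rows = observed, columns = predicted, classes in
the fixed order EAS, GER, IBR, ITA, JPN; the row-normalized view is
rounded to two decimals in reports only. Accuracy is trace/total; Cohen's
κ = (p_o − p_e)/(1 − p_e) with p_e from the margins, the degenerate
p_e = 1 case defined as 0 with a warning. κ is cross-checked against
scikit-learn in the tests.

## Population pipeline

Each distinct roster surname is resolved once through the cascade exact →
fuzzy (d ≤ 1) → Cavnar–Trenkle; the trigram stage always returns a label,
so coverage is total. Per-stage counts are reported both per distinct
surname and per occurrence. The combined 8-way category uses the LAST (or
unique) surname's ancestry, overridden to BLK/MXD/NAT when the registered
colour/race is black, mixed or native (white and yellow never override).
The ancestry index counts the non-Iberian fraction of the (up to two)
surnames: 0, 0.5 or 1, order-irrelevant; single-surname individuals score
0 or 1. Regional aggregation reports n, Σ index and rate = Σ index / n
per region; region codes are opaque strings, no geometry is needed.
Population shares are exposed as two deliberately separate statistics:
the share with any non-Iberian surname (index > 0) and the share whose
last/unique surname is non-Iberian.

## Synthetic data

The generator emulates the features of real rosters the method depends
on, with defaults fixed to the study conditions it mirrors:

* **Class structure.** Order-1 character Markov chains (states ^, A–Z, $;
  add-0.1 smoothing) fitted to bundled stylized seed lists of a few dozen
  well-known surnames per ancestry. The seed lists only parameterize the
  chains — enough structure for a trigram classifier to learn, with
  realistic overlap between classes; they claim nothing about real
  populations. A `disjoint` mode assigns each class a private 5-letter
  alphabet, making classes separable by construction (useful for
  exactness tests: no trigram, and no single-edit corruption, can cross
  classes).
* **Skewed popularity.** Surname occurrences follow a per-class Zipf law
  whose exponent is calibrated by bisection on the analytic coverage
  formula so that the five globally most frequent surnames cover 45% of
  occurrences (the hallmark concentration of the roster being emulated);
  the empirical coverage at n = 10⁵ occurrences lands within ±3 points.
* **Mixture.** Per-surname class weights default to heavily Iberian
  population shares (.881/.072/.032/.008/.007); both surnames of a person
  are drawn independently.
* **Noise.** Each surname occurrence is corrupted with probability
  `typo_rate` (default 0.10) by exactly one uniformly chosen edit
  (insert/delete/substitute/adjacent-transpose, resampled within type so
  the result always differs and types stay equiprobable); every
  corruption is at OSA distance exactly 1 from its source.
* **Bookkeeping.** True classes, corruption flags and
  reference-membership of every observed string are emitted per person,
  so cascade stage counts and recovery rates can be scored exactly.
* **Reproducibility.** One master seed feeds named substreams
  (reference / roster / typos / regions), so each component is
  independently reproducible.

Default sizes — 600 surnames per class, 10⁴-person rosters — keep every
experiment at desk scale (the full suite runs in well under a minute).

What passing synthetic tests shows: the cascade's logic is correct — 100%
recovery under disjoint alphabets with 10% typos, exact stage accounting,
classifier accuracy far above the 20% chance level on overlapping Markov
classes (≈90% held-out at the defaults). What it does not show: accuracy
on real surnames, which depends on the orthographic proximity of actual
languages (e.g. Iberian/Italian confusion) and on reference coverage;
published applications of this cascade to real rosters report held-out
trigram accuracy near 80% and fuzzy-matching coverage above 96% of
individuals, figures that require the restricted reference and roster
data and are not reproducible here.

## Numerical and degenerate-input conventions

* All classifier tie-breaks are deterministic (fixed class order) and
  flagged in the prediction objects.
* Profile ranking ties are lexicographic; retraining on permuted input
  yields identical models.
* Empty surnames are rejected by the n-gram builder; rosters with no
  usable surname rows raise; persons lacking a region are excluded from
  aggregation but counted.
* κ with chance agreement 1 returns 0 with a warning rather than NaN.
* Priors must sum to 1 within 1e-12; posteriors normalize within 1e-9.

## Known limitations

* The first-name splitter is a greedy lexicon heuristic; rare surnames
  that double as given names (and vice versa) can be mis-split.
* Marriage-driven surname changes and matrilineal loss are not modelled.
* The synthetic generators produce no phonetically realistic orthography;
  they exercise the machinery, not any language.
* Fuzzy matching is untuned for weighted edit costs or phonetic codes
  (Soundex/Metaphone) by design — conservatism over recall.
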