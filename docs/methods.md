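# Methods

## The scoring model

`sbarscore` scores short free-text clinical handover answers (SBAR format:
Situation, Background, Assessment, Recommendation, administered as exam
parts 3–6) by word presence, not by sentence understanding. The pipeline:

1. **Normalization.** Responses, lexicon surfaces and accept strings are all
   mapped into one character space: NFKC compatibility composition (folding
   full-width Latin/digits to half-width and half-width katakana to
   full-width), lowercasing, and whitespace-run collapse. Normalization is
   idempotent, so it is safe to apply at every boundary.
2. **Segmentation.** Japanese has no inter-word spaces, so the text is tiled
   by a minimum-cost lattice: at each character position the candidate arcs
   are every dictionary entry whose surface prefix-matches there plus a
   single-character unknown arc, and the cheapest total tiling wins. Each
   arc carries the entry's *standard form* (canonical citation form), which
   is what all downstream matching compares; conjugated verb surfaces
   registered in a user dictionary therefore unify onto one canonical form.
3. **Answer-key compilation.** Each question's accept strings are enlarged
   by a fixed notation-variant table (Arabic ↔ Roman ↔ Chinese ↔ full-width
   numerals, values 0–20, substituted per maximal numeral run), normalized,
   tokenized with the same merged lexicon, and deduplicated into sets of
   standard-form token sequences.
4. **Matching and scoring.** A question earns its single binary point iff
   any of its compiled accept sequences occurs as a contiguous subsequence
   of the tokenized response for that part. Matching is exact: misspelled
   and out-of-list words never match, by design — the answers exist to
   transfer information reliably, so near-misses are treated as wrong.
5. **Evaluation.** Machine and human score sheets are compared cell-by-cell
   with the human as reference (false positive = machine credited, human
   did not), summarized as accuracy, recall, precision and F1, and the
   score distributions are compared with a Mann-Whitney U test reported
   with Z and the effect size r = Z/√(n₁+n₂).

## Parameters that matter

| parameter | default | why |
|---|---|---|
| unknown-character arc cost | 1000 | any dictionary analysis of a span must beat spelling it out character by character; the exact value is irrelevant as long as it dominates entry costs |
| base dictionary entry cost | 10 (fixture lexicons) | an arbitrary mid-scale unit; only relative order against user entries matters |
| user dictionary entry cost | 1 | a registered compound or verb+particle form must always beat any multi-piece division of the same span (1 < 10+10) |
| numeral variant table | values 0–20 | exam answers reference small ordinals (heart-sound components, counts); larger numbers (ages, years) are matched literally |
| report rounding | 3 decimals, half-up | matches the precision agreement metrics are conventionally reported at; raw values are retained alongside |

Tie-breaking in the lattice is deterministic: equal-cost tilings prefer
fewer tokens, then the longer first token recursively, then lexicographic
(standard form, part-of-speech) order among equal-length arcs. Spans are
0-based half-open intervals. There are no part-of-speech connection costs:
unigram costs fully determine division, which is all word-presence scoring
needs.

## The rank test

Integer scores in 0–18 over a few dozen subjects are heavy with ties, so
the default p-value uses the tie-corrected normal approximation of U
without continuity correction; completely tied inputs give Z = 0, r = 0,
p = 1 rather than an error. For tie-free samples with pooled size ≤ 16 the
p-value instead comes from exact enumeration of all C(n₁+n₂, n₁) rank
assignments, two-sided as min(1, 2·min(P(U≤u), P(U≥u))) — at those sizes
the normal approximation is meaningfully wrong and the enumeration is
cheap. Z (hence r) always comes from the normal standardization. The n in
r = Z/√n is the pooled sample size n₁+n₂, the standard convention for this
effect size.

## What the synthetic generator emulates — and what it does not

`generate_corpus` reproduces the *structure* of the study data: 39 subjects
(default), four parts per subject, 18 scorable concepts, roughly 31% of
concepts present per answer, and the known failure taxonomy injected at
rates matching the observed discrepancy tallies (≈5% of credited concepts
perturbed into machine misses, split across out-of-list synonyms,
single-character misspellings and fused/conjugated forms; a ≈1.4% human
flip rate on credited cells). Ground-truth machine and human sheets are
computed at generation time by construction — the distractor vocabulary is
verifiably disjoint from every accept variant, misspellings are re-drawn
until they escape every accept string of their part, and fused forms
truncate every word before fusing so no accept survives as a substring.
That makes the truth sheets an exact oracle for the scorer, which the test
suite exploits.

The generator deliberately does **not** produce linguistically realistic
Japanese: responses are space-separated romanized word lists, there is no
examinee-ability model, no word-order variation, no hiragana/kanji
interchange, and sentence-form answers exist only as fixed analogues in the
regression fixture. Passing tests therefore demonstrate that the pipeline's
mechanics (division, matching, bookkeeping, agreement statistics) are
correct, not that the method generalizes to free natural-language input —
on real data, accuracy is bounded by the curation quality of the word lists
and dictionaries, exactly the calibration loop the discrepancy table is
designed to support.

The regression fixture (`regression_fixture`) encodes one deterministic
analogue of each discrepancy category observed when machine scoring was
compared with human scoring: out-of-list synonym, sentence-form answer,
under-specified term ("echo" without a modality), unnoticed misspelling,
over-divided fused form, and plain human error, plus clean and both-wrong
controls. Its expected machine and human points are documented
cell-by-cell in its docstring and asserted in tests.

## Numerical and degenerate-input choices

* Undefined metric ratios (zero denominator) are NaN, never silently 0; an
  all-zero confusion matrix is an error.
* An empty response, or a missing part, scores zero on that part without
  error; an empty corpus filters to an empty kept list.
* Accept strings that tokenize entirely to unknown characters compile with
  a warning (they still match a response containing the identical string,
  since both sides degrade identically).
* The variant-expansion closure substitutes only maximal numeral runs that
  exactly equal a table form, so roman "II" is always read as the value
  two, never as two ones; this keeps the closure finite and makes
  re-expansion a fixpoint.
* Lexicon merging is a multiset union — duplicate surfaces coexist and the
  path search resolves preference through cost, mirroring how a general
  dictionary, a medical dictionary and a user dictionary are stacked
  without any explicit conflict policy.

## Problem sizes

Test and acceptance runs use the study-sized corpus (39 subjects, 702
point cells) for end-to-end checks and smaller corpora (6–40 subjects) for
property sweeps; the exhaustive segmentation oracle enumerates all tilings
of strings up to 8 characters against randomized 5-entry lexicons (≥1000
cases), and the exact rank-test oracle enumerates rank assignments up to
pooled size 8. These sizes give stable statistics while keeping the whole
suite within a few seconds.

## Known limitations

* No negation or context detection: "no heart murmur" still credits the
  murmur concept. This is inherent to word-presence scoring.
* Exact matching means every acceptable synonym and notation must be
  curated into the word list; the discrepancy table (token-wise edit
  distance to the nearest accept sequence) is the supported triage tool.
* The built-in lattice uses unigram costs only and a four-tag
  part-of-speech set; it is a reference segmenter for this scoring task,
  not a general morphological analyzer, though any external analyzer can
  be plugged in by producing the same segmentation-result shape.
* Question 4-3 ("the state when he lost consciousness") is structurally
  unscorable by word lists — its concept only exists as a sentence — and
  is excluded from every sheet, capping totals at 18.
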