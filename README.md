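# sbarscore

Machine scoring of free-text clinical case-presentation answers.

Postgraduate in-training exams increasingly ask residents to *write* a
structured patient handover (SBAR: Situation, Background, Assessment,
Recommendation) after watching a simulated consultation, instead of picking
a multiple-choice option. Human scoring of such free-text answers is the
bottleneck: minutes per question, thousands of examinees. Because these
answers are graded for the *presence of concepts* — a name, a tentative
diagnosis, a physical finding, a recommended test — a deliberately simple
model suffices: segment the answer into canonical words and check each
question's correct-word list against the word sequence.

`sbarscore` implements that model end to end, for exam writers and
medical-education researchers who need reproducible, auditable machine
scores plus the statistics to validate them against human raters:

* **lexicon** — 4-column TSV dictionaries (`surface, standard form, POS,
  cost`), multiset merging of base + user dictionaries, and notation-variant
  expansion of accept strings (Arabic ↔ Roman ↔ Chinese ↔ full-width
  numerals, e.g. the heart-sound component "2p" ↔ "IIp" ↔ "Ⅱp").
* **tokenizer** — text normalization (NFKC width folding, lowercasing,
  whitespace collapse) and minimum-cost lattice segmentation with
  per-character unknown arcs; a cost-1 user-dictionary entry rescues
  compounds the base dictionary over-divides ("ultrasound" → "ultra"+"sound").
* **scoring** — response filtering (ongoing / nonresponse exclusion),
  answer-key compilation into standard-form token sequences, and binary
  point award: a question scores 1 iff any accept sequence occurs
  contiguously in the tokenized answer, at most once per question.
* **evaluation** — human-vs-machine confusion matrix (human as reference),
  accuracy / recall / precision / F1, Mann-Whitney U with tie-corrected Z
  and effect size r = Z/√(n₁+n₂), and a per-disagreement table with
  token-wise edit distance to the nearest accept sequence for calibration.
* **synth** — a synthetic-corpus generator with exact paired machine/human
  ground truth, injecting the known discrepancy taxonomy (out-of-list
  synonyms, misspellings, fused/over-divided forms, human error) at
  configurable rates, plus a deterministic regression fixture.

The scoring core in standard notation: given response tokens
w₁…w_m (standard forms) and compiled accept set A_q for question q,

    point(q) = 1  iff  ∃ a ∈ A_q, ∃ i :  (w_i, …, w_{i+|a|-1}) = a

with part subtotals over parts 3–6 (maxima 5/3/5/5) and total ∈ [0, 18].

## Worked example

Generate a study-shaped synthetic corpus (39 subjects, default perturbation
rates), score it, and evaluate against the emulated human rater:

```sh
sbarscore synth --seed 1 --out demo
sbarscore score --responses demo/responses.csv --key demo/answer_key.json \
    --lexicon demo/base.lex.tsv --user-lexicon demo/user.lex.tsv --out demo/run
sbarscore evaluate --human demo/truth/human.tsv --machine demo/run/score_sheet.tsv \
    --responses demo/responses.csv --key demo/answer_key.json \
    --lexicon demo/base.lex.tsv --user-lexicon demo/user.lex.tsv --out demo/eval
```

The last command prints

```
{"accuracy": 0.98, "recall": 0.96, "precision": 0.977, "f1": 0.968}
```

and `demo/eval/metrics.json` holds the full report, beginning

```json
{
  "confusion": {"tp": 214, "fn": 9, "fp": 5, "tn": 474, "total": 702}
```

Reading: of 702 point-level cells (39 subjects × 18 scorable questions),
machine and human agreed on 688; 9 cells were credited by the human but
missed by the machine (synonyms, misspellings, over-divided compounds) and
5 were credited by the machine while the human erred — 14 discrepancies,
2.0% of cells. Accuracy is the share of agreeing cells; recall and
precision treat the human score as the reference truth. The report also
carries Mann-Whitney results per part and total (here p = 0.77 on totals:
no evidence the two raters' score distributions differ).

The scored sheet in `demo/run/score_sheet.tsv` matches the generator's
`demo/truth/machine.tsv` byte for byte — on a corpus whose ground truth is
known by construction, the pipeline reproduces it exactly.

Segmentation behavior is directly inspectable:

```sh
$ printf 'ultrasound\n' | sbarscore tokenize --lexicon demo/base.lex.tsv -
ultra	sound
$ printf 'ultrasound\n' | sbarscore tokenize --lexicon demo/base.lex.tsv \
      --user-lexicon demo/user.lex.tsv -
ultrasound
```

Everything the CLI does is also a library call; see `docs/methods.md` for
the model, its assumptions and its limits.

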