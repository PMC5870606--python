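# Methods

## Problem

A *mutation mention* is a text span reporting a sequence variant. Mentions
range from standard nomenclature (**ST**: "E6V", "c.76delA", "rs206437",
"D17S250"), through semi-standard fragments (**SST**: "Gly 18 to Lys",
"codon 92, TAC–>TAT"), to natural-language descriptions (**NL**: "glutamic
acid was substituted by valine at residue 6"). The package does
named-entity recognition and form classification only; mapping a mention
to a database sequence (normalization) is out of scope throughout, and
that exclusion shapes several definitions below.

## Mention classification

Classification is an ordered, deterministic if-else chain:

1. **ST** if the whitespace-trimmed mention *fully* matches any named
   regex in the pattern inventory (`data/st_patterns.tsv`). Anchoring
   matters: "3992-9g–>a mutation" contains an ST-like substring but is not
   an ST mention, so patterns never fire on substrings.
2. **NL** if the mention has ≥ 5 words or ≥ 2 dictionary words.
3. **SST** if it has exactly 1 dictionary word.
4. **ST** otherwise (opaque strings like "TAC–>TAT").

A *word* is a whitespace-delimited chunk containing at least one letter —
positions ("18") and arrows do not count, which keeps short nomenclature
fragments out of the NL branch. Dictionary words are alphanumeric chunks
whose lowercase form is in the shipped word list.

**Dictionary.** `data/english_words.txt` is a curated lowercase word list
(~320 entries): general English plus the vocabulary of variant
descriptions. Deliberately excluded: single letters, amino-acid
three-letter codes and full names, nucleotide triplets, and the
preposition "of" — all of which occur routinely *inside*
standard/semi-standard nomenclature fragments ("Gly 18 to Lys",
"abrogated loss of Chr19") and would otherwise push them into the NL
branch. Membership was validated against the package's reference example
set of 21 classified mentions (`tests/test_classify.py`), which is the
binding contract for classifier + dictionary + regex inventory; the list
itself is replaceable by the user.

**Thresholds** (5 words, 2 dictionary words for NL, 1 for SST) are exposed
in `ClassifierConfig`.

## Tokenizer

Offset-preserving, rule-based: whitespace separates tokens; every
punctuation/symbol character (including Greek letters, needed for
"TP73Δex2/3") is a single-character token; splits at letter↔digit
boundaries and at lowercase→uppercase case changes ("delPhe" → "del" +
"Phe"). One exception: case-change splits are suppressed in the leading
run of a sentence-initial word, so "The" stays one token. Sentence starts
come from a deterministic rule (text start, or `[.!?]` + whitespace + a
non-lowercase character); no external sentence splitter is used. The
suppression applies only until the first split inside a word — this keeps
tokenization idempotent (re-tokenizing the space-joined token surfaces
reproduces the tokens), a property the test suite checks with random
strings. Offsets count Unicode code points, 0-based and half-open.

## BIEO labeling

Mentions are projected onto token label sequences: **B** first token,
**I** continuing, **E** last, **O** outside. Choices where the scheme is
underdetermined:

- single-token mentions are labeled **B** (no singleton label in BIEO; B
  round-trips cleanly);
- decoding is *lenient*: an I/E run without an opening B still becomes a
  mention starting at the run's first token, so label noise does not
  silently drop predictions;
- gold spans not aligned to token boundaries snap outward to the
  overlapped tokens, with a logged warning;
- overlapping gold annotations are an error (the corpora this models do
  not contain them).

Encode∘decode and decode∘encode are identities on well-formed input
(property-tested).

## CRF tagger

A linear-chain CRF over per-sentence token sequences (sentence-level
sequences are standard practice and bound the cost of inference).
Potentials: tied (feature, label) weights for named observation features,
a 4×4 label-transition matrix, and start/end label scores. Training
maximizes the conditional log-likelihood with an L2 penalty (`c2 = 0.1`
default, `max_iter = 100`) using scipy's L-BFGS-B; the forward–backward
recursions run batched over all padded sequences in log space. L1
regularization is not offered: scipy has no OWL-QN and a smooth objective
keeps the optimizer a vetted library routine; the `c1` field exists in
`Hyperparams` for config compatibility but must be 0. Training is
deterministic — the feature index is built in first-seen order and no
randomness enters the objective — so two trainings on the same input give
identical models, which the tests assert.

Handcrafted features per token (and each neighbour within a ±2 window,
offset-prefixed): Porter stem (own implementation of the classic
algorithm), word shape (A/a/0 for Latin letters and digits, other
characters kept) plus its run-collapsed form, prefixes/suffixes of length
1–3, has-digit and is-symbol flags, and membership in term dictionaries
(amino-acid codes and names, nucleotides, mutation-type words). Window
size and affix lengths are package defaults, exposed in `FeatureConfig`.

**Word-embedding features.** A CBOW model (own numpy implementation:
negative sampling, k = 5, linearly decaying learning rate, single-threaded
and seed-deterministic) is trained on raw text with window = 10,
D = 100, tokens normalized to lowercase with every digit → 0. At feature
time the centre token's vector becomes 100 real-valued features
`word_embedding[i]`; out-of-vocabulary tokens contribute *no* embedding
features (a zero vector would pull CRF weights toward fake evidence).
Embedding features can be switched off (`use_embeddings=False`), which
provably removes every `word_embedding[*]` name from the feature space.

**Post-processing.** (1) Boundary fix: trim flanking whitespace and absorb
an immediately preceding `+`/`-`/`−` sign onto a leading digit
("+1858C > T"); only this sign-prefix case is implemented — the fix never
fires when the sign follows an alphanumeric character. (2) Two optional
regex filters, on by default: dropping rsid predictions (`rs[0-9]+`) and
genetic-marker predictions (`D[0-9]{1,2}S[0-9]+`), matched against the
whole trimmed surface. Filters only remove or extend spans, never
fabricate them, and every output annotation is re-validated against the
text.

**Document selection.** For corpus construction, `select_nl_documents`
keeps documents where any of a high-recall pattern list
(`data/nl_recall_patterns.txt`) matches; given a trained model, matches
lying inside predictions classified ST are discounted, so selection
favours documents offering more than already-captured standard mentions.

## Evaluation protocol

- **Matching.** Exact = identical offsets; partial = any overlap of the
  half-open spans (adjacent spans do not overlap). Each gold mention
  matched by ≥ 1 prediction counts once as tp; unmatched predictions are
  fp; unmatched gold are fn. In exact mode a prediction satisfies at most
  one gold mention; in partial mode a prediction overlapping two gold
  mentions satisfies both but is never counted as fp. This keeps
  tp + fn = #gold in every mode.
- **Per-class scoring.** tp/fn are attributed by the *gold* mention's
  class (a gold mention of class X is correct if any prediction matched
  it). False positives carry no gold class, so fp — and hence precision —
  are reported only at the "all" scope; per-class rows are recall-bearing.
- **P/R/F** by the standard formulas; degenerate denominators give 0 with
  an explicit flag rather than NaN.
- **Within-corpus StdErr.** 1000 subsamples, each 15% of the test
  *documents* drawn without replacement; the metric is recomputed on each;
  subsamples on which it is undefined (no gold drawn) are redrawn and
  logged. The reported StdErr is the sample standard deviation σ of the
  subsample distribution (default). A literal σ/√n estimator is also
  available by config; the two differ by exactly √n and the printed
  definition of this statistic is ambiguous between them, so neither is
  silently promoted — the choice is part of the report's config.
- **Cross-corpus aggregation.** Unweighted means of P/R/F; StdErr of the
  mean = sample std across corpora / √(#corpora); a single corpus has no
  StdErr.
- **Exclusive detection.** Pool = unique (document, surface) gold mentions
  correctly detected by ≥ 1 of the compared methods (repetitions within a
  document collapse); per method, the percentage of the pool detected by
  it alone; repeated for the NL-class subset. Percentages over one pool
  sum to ≤ 100.

## Corpus statistics

Counts are reported with repetitions (every occurrence) and unique
(case-sensitive exact surface match within one document — the most
conservative uniqueness notion; the alternative, case-folded matching, is
not used because nomenclature is case-sensitive: "e6v" ≠ "E6V").
The "NL-only" fractions count documents holding ≥ 1 NL/SST mention and
*no* ST mention at all — deciding whether an NL and an ST mention describe
the *same* variant would require normalization, which is out of scope, so
absence of any ST mention is the implemented approximation. NL density =
NL mentions per token; the abstract/full-text ratio is flagged infinite
when full texts contain no NL mention.

## Synthetic corpus generator

The generator emulates the statistical shape of an NL-enriched abstract
corpus: default class mix 52% ST / 8% SST / 40% NL, 9% mention-free
documents (to probe precision on genuinely negative text), 1–3 mentions
per document, mentions embedded in carrier sentences and padded with
filler sentences from a neutral biomedical phrase bank containing no
mutation-like strings. Positions are drawn uniformly from 1–2000, residues
from the 20 amino acids, nucleotides from ACGT — pure test scaffolding,
not a generative model of text. Every template instantiation is validated
against the mention classifier at bank-load time (a template whose
rendering misclassifies is rejected with a diagnostic), and the whole
corpus is byte-deterministic given the seed.

**What passing the synthetic benchmark shows — and what it does not.**
The benchmark (train 200 / test 50, partial-mode F) verifies that the
pipeline is wired correctly end to end: offsets survive tokenization,
encoding, decoding and post-processing, and the CRF learns separable
patterns to near-perfect F. It does *not* estimate performance on real
abstracts: real NL mentions have unbounded phrasing variety, vague and
cross-sentence positions, and annotation ambiguity, none of which the
template bank models. The word-embedding ablation on the synthetic
NL-heavy benchmark is likewise a direction check (embedding features must
not hurt NL F), not a measurement of their real-world contribution: with
templated text the handcrafted features already near-saturate the task.
Reproducing published-scale F-measures would require the released
annotated corpora and embeddings trained on a literature-scale text
collection.

## Reproduction recipe (full-scale, requires the released corpora)

To mirror the original operating point on real data: train the final model
solely on the NL-enriched training corpus (not the broader
unbiased-sampling corpus — NL mentions are learned much better that way,
and a small ST gain does not justify maintaining two models), evaluate on
the held-out known-gene and new-discoveries sets, toggle the rsid and
genetic-marker filters per target corpus's annotation guidelines, and use
embeddings trained on a PubMed-scale corpus. The trainer itself is
agnostic: it trains on whatever corpus it is given.

## Known limitations

- The ST regex inventory is a reconstruction covering the documented
  example forms; it is not byte-identical to any external tool's pattern
  file. Classifier behaviour on mentions outside the reference set depends
  on it and on the shipped dictionary.
- The sentence detector is deliberately simple; abbreviation-heavy full
  text will over-split, which only shortens CRF sequences.
- The CBOW trainer is desk-scale (pure numpy); training on corpora beyond
  a few million tokens calls for a dedicated embedding toolkit, and the
  text-table model format is interoperable with one.
- Exact-mode matching of multi-token NL mentions is sensitive to the
  boundary conventions of gold annotations; partial mode is the primary
  metric for NL, by design.
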