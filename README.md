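# mutmention

Named-entity recognition of **sequence-variant mentions** in biomedical
text. Most extraction tools target standard nomenclature ("E6V",
"c.76delA", "rs206437"), but a large share of the variants reported in the
literature appear only as prose — *"glutamic acid was substituted by valine
at residue 6"*. `mutmention` is for text-mining and curation pipelines that
need those natural-language mentions too: it tags mentions of all forms,
classifies them, and scores taggers with the full evaluation protocol used
in mutation-NER benchmarking.

## What is inside

- **Mention classifier** — a deterministic if-else chain over a candidate
  mention *m*: if *m* fully matches a standard-nomenclature regex → **ST**;
  else if *m* has ≥ 5 words or ≥ 2 English-dictionary words → **NL**; else
  if it has exactly 1 dictionary word → **SST**; else **ST**. The regex
  inventory and dictionary ship as editable plain-text data.
- **CRF tagger** — a linear-chain CRF over sentence token sequences with
  **BIEO** labels (Begin/Inside/End/Outside of a mention). Per-token
  features: Porter stems, word-shape patterns, prefix/suffix characters,
  digit flags and term-dictionary membership for a ±2 token window, plus
  optional **word-embedding features**: each token's CBOW vector
  (window = 10, D = 100, tokens lowercased with digits → 0) enters as 100
  real-valued features `word_embedding[i]`. Training maximizes the
  L2-regularized conditional log-likelihood with L-BFGS; decoding is
  Viterbi. Post-processing fixes boundary slips ("+1858C > T", not
  "1858C > T") and can optionally drop rsid / genetic-marker predictions.
- **Evaluation protocol** — exact (identical offsets) and partial (overlap)
  matching; P = tp/(tp+fp), R = tp/(tp+fn), F = 2PR/(P+R); per-class
  scoring by the gold mention's class; within-corpus StdErr from 1000
  bootstrap subsamples of 15% of the test documents; unweighted
  cross-corpus means; and an exclusive-detection comparison (share of
  correctly found unique mentions found by one method only).
- **Synthetic corpus generator** — seeded abstracts with gold offsets,
  a configurable ST/SST/NL mix (default 52/8/40) and mention-free
  documents (default 9%) to probe precision, so the entire stack is
  testable without any download.

## Worked example

```python
from mutmention import (Document, FeatureConfig, SynthConfig,
                        generate_corpus, predict, train)

train_docs, train_gold = generate_corpus(SynthConfig(n_documents=100, seed=1))
model = train(train_docs, train_gold,
              feature_config=FeatureConfig(use_embeddings=False))

abstract = Document(doc_id="example", parts=[("s1",
    "Samples were collected after informed consent. Sequencing revealed "
    "p.Asp117Gly in two unrelated patients. Analysis confirmed that "
    "glutamine was replaced by proline at residue 115 in all affected "
    "individuals.")])
for ann in predict(model, abstract):
    print(f"({ann.start:3d},{ann.end:3d})  {ann.surface}")
```

prints

```
( 67, 78)  p.Asp117Gly
(125,178)  that glutamine was replaced by proline at residue 115
```

— one line per predicted mention with its 0-based half-open character span:
the HGVS-style mention is recovered exactly, the prose mention with a
one-word boundary slip (which partial-overlap evaluation scores as a hit;
see `examples/evaluate_predictions.py` for the scoring side).

More narrative scripts live in `examples/`; the same functionality is also
exposed as a CLI (`mutmention synth | train | predict | evaluate |
classify | tokenize | stats | nl-only | cv | compare`), reading and writing
brat standoff and a JSON standoff dialect.

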