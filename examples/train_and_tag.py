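"""Train the CRF tagger on a synthetic corpus and tag a new abstract.

Generates 100 seeded synthetic abstracts with gold mention offsets, trains
the sentence-level BIEO CRF (handcrafted features only), and prints the
mentions it finds in a held-out document with their character spans.
"""

from mutmention import (Document, FeatureConfig, SynthConfig, generate_corpus,
                        predict, train)

train_docs, train_gold = generate_corpus(SynthConfig(n_documents=100, seed=1))
model = train(train_docs, train_gold,
              feature_config=FeatureConfig(use_embeddings=False))

abstract = Document(
    doc_id="example",
    parts=[("s1",
            "Samples were collected after informed consent. Sequencing "
            "revealed p.Asp117Gly in two unrelated patients. Analysis "
            "confirmed that glutamine was replaced by proline at residue 115 "
            "in all affected individuals.")],
)
for ann in predict(model, abstract):
    print(f"({ann.start:3d},{ann.end:3d})  {ann.surface}")

# Each line is one predicted mutation mention with its 0-based half-open
# character span in the abstract; both the HGVS-style and the prose
# description should be recovered.  Boundaries of prose mentions can be
# off by a function word on unseen phrasings — the reason the evaluation
# protocol also scores partial (overlap) matches.
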