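"""Tagger pipeline: training contracts, post-processing, CV, selection."""

import dataclasses

import pytest

from mutmention import (Document, FeatureConfig, MentionAnnotation,
                        PostProcessConfig, crossvalidate, filter_special,
                        fix_boundaries, predict, select_nl_documents, train)
from mutmention.tagger import Hyperparams, TaggerModel, split_sentences


def _ann(doc, part, start, end, surface):
    return MentionAnnotation(doc, part, start, end, surface)


def test_train_rejects_empty_corpus():
    with pytest.raises(ValueError):
        train([], [])
    doc = Document(doc_id="d", parts=[("s1", "no mentions here.")])
    with pytest.raises(ValueError):
        train([doc], [])


def test_hyperparams_reject_l1():
    with pytest.raises(ValueError):
        Hyperparams(c1=0.5)


def test_self_fit_recovers_training_mention(small_corpus, small_model):
    docs, gold = small_corpus
    target_doc = next(d for d in docs if any(g.doc_id == d.doc_id for g in gold))
    expected = sorted(
        (g.start, g.end) for g in gold if g.doc_id == target_doc.doc_id
    )
    preds = predict(small_model, target_doc)
    assert sorted((p.start, p.end) for p in preds) == expected


def test_prediction_deterministic(small_corpus, small_model):
    docs, _gold = small_corpus
    a = predict(small_model, docs[0])
    b = predict(small_model, docs[0])
    assert a == b


def test_two_trainings_identical_predictions(small_corpus):
    docs, gold = small_corpus
    fc = FeatureConfig(use_embeddings=False)
    hp = Hyperparams(max_iter=30)
    m1 = train(docs[:20], [g for g in gold if g.doc_id in {d.doc_id for d in docs[:20]}],
               feature_config=fc, hyperparams=hp)
    m2 = train(docs[:20], [g for g in gold if g.doc_id in {d.doc_id for d in docs[:20]}],
               feature_config=fc, hyperparams=hp)
    held_out = docs[25]
    assert predict(m1, held_out) == predict(m2, held_out)


def test_document_without_mutations_predicts_nothing(small_model):
    doc = Document(
        doc_id="neg",
        parts=[("s1", "Samples were collected after informed consent. "
                       "Expression levels were measured by quantitative PCR.")],
    )
    assert predict(small_model, doc) == []


def test_model_save_load_round_trip(tmp_path, small_corpus, small_model):
    docs, _ = small_corpus
    path = tmp_path / "model.json"
    small_model.save(path)
    loaded = TaggerModel.load(path)
    assert predict(loaded, docs[0]) == predict(small_model, docs[0])


# ------------------------------------------------------------ post-processing

def test_fix_boundaries_absorbs_sign_prefix():
    text = "carriers of the +1858C > T variant were typed."
    start = text.index("1858C")
    ann = _ann("d", "s1", start, start + len("1858C > T"), "1858C > T")
    fixed = fix_boundaries(text, ann)
    assert fixed.surface == "+1858C > T"
    assert fixed.start == start - 1


def test_fix_boundaries_identity_and_trim():
    text = "the E6V variant"
    ann = _ann("d", "s1", 4, 7, "E6V")
    assert fix_boundaries(text, ann) is ann
    padded = _ann("d", "s1", 3, 8, " E6V ")
    fixed = fix_boundaries(text, padded)
    assert (fixed.start, fixed.end, fixed.surface) == (4, 7, "E6V")


def test_fix_boundaries_no_absorb_inside_identifier():
    text = "allele A-1858C > T variant"  # "-" follows an alphanumeric char
    start = text.index("1858C")
    ann = _ann("d", "s1", start, start + len("1858C > T"), "1858C > T")
    assert fix_boundaries(text, ann) is ann


def test_filter_special_rsids_and_markers():
    text = "rs206437 E6V D17S250"
    anns = [
        _ann("d", "s1", 0, 8, "rs206437"),
        _ann("d", "s1", 9, 12, "E6V"),
        _ann("d", "s1", 13, 20, "D17S250"),
    ]
    keep_all = filter_special(anns, PostProcessConfig())
    assert keep_all == anns  # both flags default on -> identity
    no_rsids = filter_special(anns, PostProcessConfig(annotate_rsids=False))
    assert [a.surface for a in no_rsids] == ["E6V", "D17S250"]
    no_markers = filter_special(
        anns, PostProcessConfig(annotate_genetic_markers=False)
    )
    assert [a.surface for a in no_markers] == ["rs206437", "E6V"]


# ---------------------------------------------------------------- CV & misc

def test_crossvalidate_rejects_bad_k(small_corpus):
    docs, gold = small_corpus
    with pytest.raises(ValueError):
        crossvalidate(docs, gold, k=1)
    with pytest.raises(ValueError):
        crossvalidate(docs[:3], gold, k=5)


def test_crossvalidate_folds_partition_documents(small_corpus):
    import numpy as np

    docs, _ = small_corpus
    rng = np.random.default_rng(0)
    order = rng.permutation(len(docs))
    folds = [sorted(order[i::5]) for i in range(5)]
    flat = sorted(i for fold in folds for i in fold)
    assert flat == list(range(len(docs)))
    assert all(set(a) & set(b) == set() for i, a in enumerate(folds)
               for b in folds[i + 1:])


def test_crossvalidate_runs_and_scores_well(small_corpus):
    docs, gold = small_corpus
    folds, mean = crossvalidate(
        docs, gold, k=3, seed=0,
        feature_config=FeatureConfig(use_embeddings=False),
        hyperparams=Hyperparams(max_iter=40),
    )
    assert len(folds) == 3
    assert mean.f1 > 0.7


def test_split_sentences_covers_text():
    text = "First sentence here. Second one follows! Third?"
    spans = split_sentences(text)
    assert spans[0][0] == 0 and spans[-1][1] == len(text)
    assert [text[s:e].strip()[:5] for s, e in spans] == ["First", "Secon", "Third"]


def test_select_nl_documents():
    nl_doc = Document(
        doc_id="nl",
        parts=[("s1", "glutamic acid was substituted by valine at residue 6.")],
    )
    st_doc = Document(doc_id="st", parts=[("s1", "Only E6V appears here.")])
    selected = select_nl_documents([nl_doc, st_doc])
    assert [d.doc_id for d in selected] == ["nl"]
    assert select_nl_documents([]) == []
    with pytest.raises(ValueError):
        select_nl_documents([nl_doc], nl_recall_regexes=[])
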