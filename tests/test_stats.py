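"""Corpus statistics: repeated vs unique counts, NL-only shares, densities."""

import math

import pytest

from mutmention import (Document, MentionAnnotation, MentionClass,
                        corpus_stats, nl_density_ratio, nl_only_fractions)


def _doc(doc_id, text):
    return Document(doc_id=doc_id, parts=[("s1", text)])


def _ann(doc_id, text, surface, occurrence=0):
    start = -1
    for _ in range(occurrence + 1):
        start = text.index(surface, start + 1)
    return MentionAnnotation(doc_id, "s1", start, start + len(surface), surface)


def test_repeated_vs_unique_counts():
    text = "E6V was seen and E6V again."
    doc = _doc("d1", text)
    anns = [_ann("d1", text, "E6V", 0), _ann("d1", text, "E6V", 1)]
    s = corpus_stats([doc], anns)
    assert s.per_class[MentionClass.ST] == 2
    assert s.per_class_unique[MentionClass.ST] == 1
    assert s.n_mentions == 2 and s.n_mentions_unique == 1


def test_same_surface_in_different_documents_not_collapsed():
    t = "E6V found."
    docs = [_doc("d1", t), _doc("d2", t)]
    anns = [_ann("d1", t, "E6V"), _ann("d2", t, "E6V")]
    s = corpus_stats(docs, anns)
    assert s.n_mentions_unique == 2  # uniqueness is per document


def test_empty_corpus_all_zero():
    s = corpus_stats([], [])
    assert s.n_documents == 0 and s.n_mentions == 0 and s.n_tokens == 0


def test_stats_match_hand_count_on_mixed_corpus():
    texts = {
        "d1": "E6V and Gly 18 to Lys appeared.",
        "d2": "glycine was substituted by lysine at residue 18 here.",
        "d3": "rs206437 then rs206437 again.",
        "d4": "Nothing relevant.",
        "d5": "Q115P only.",
    }
    docs = [_doc(k, v) for k, v in texts.items()]
    anns = [
        _ann("d1", texts["d1"], "E6V"),
        _ann("d1", texts["d1"], "Gly 18 to Lys"),
        _ann("d2", texts["d2"], "glycine was substituted by lysine at residue 18"),
        _ann("d3", texts["d3"], "rs206437", 0),
        _ann("d3", texts["d3"], "rs206437", 1),
        _ann("d5", texts["d5"], "Q115P"),
    ]
    s = corpus_stats(docs, anns)
    assert s.n_documents == 5
    assert s.per_class[MentionClass.ST] == 4  # E6V, rs206437 x2, Q115P
    assert s.per_class_unique[MentionClass.ST] == 3
    assert s.per_class[MentionClass.SST] == 1
    assert s.per_class[MentionClass.NL] == 1
    assert s.n_docs_nl_only == 1  # only d2 lacks an ST mention


def test_nl_only_fractions_definition():
    t1 = "glycine to arginine substitution at codon 20 seen."
    t2 = "E6V found."
    docs = [_doc("d1", t1), _doc("d2", t2)]
    anns = [
        _ann("d1", t1, "glycine to arginine substitution at codon 20"),
        _ann("d2", t2, "E6V"),
    ]
    doc_frac, mention_frac = nl_only_fractions(docs, anns)
    assert doc_frac == 0.5
    assert mention_frac == 0.5


def test_nl_only_all_st_is_zero_and_empty_rejected():
    t = "E6V found."
    docs = [_doc("d1", t)]
    anns = [_ann("d1", t, "E6V")]
    assert nl_only_fractions(docs, anns) == (0.0, 0.0)
    with pytest.raises(ValueError):
        nl_only_fractions([], [])


def test_nl_density_ratio_hand_check():
    nl = "glycine was substituted by lysine at residue 18"
    abs_text = f"{nl} in our study."
    full_text = f"{nl} somewhere. " + "Padding sentence with words. " * 10
    a_docs = [_doc("a1", abs_text)]
    a_anns = [_ann("a1", abs_text, nl)]
    f_docs = [_doc("f1", full_text)]
    f_anns = [_ann("f1", full_text, nl)]
    from mutmention import tokenize

    expected = (1 / len(tokenize(abs_text))) / (1 / len(tokenize(full_text)))
    assert nl_density_ratio((a_docs, a_anns), (f_docs, f_anns)) == pytest.approx(
        expected
    )
    # equal corpora -> ratio 1
    assert nl_density_ratio((a_docs, a_anns), (a_docs, a_anns)) == pytest.approx(1.0)
    # no NL in full texts -> flagged infinite
    st_text = "E6V found."
    s_docs, s_anns = [_doc("f2", st_text)], [_ann("f2", st_text, "E6V")]
    assert math.isinf(nl_density_ratio((a_docs, a_anns), (s_docs, s_anns)))
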