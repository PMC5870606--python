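"""Evaluation protocol: matching, P/R/F, bootstrap StdErr, comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mutmention import (BootstrapConfig, ConfusionCounts, MentionAnnotation,
                        MentionClass, bootstrap_stderr, corpus_counts,
                        cross_corpus_mean, evaluate, exclusive_detection,
                        match, prf, subclass_counts)
from mutmention.evaluation import DegenerateMetric, EvalReport


def _ann(start, end, doc="d", part="s1", cls=None, surface=None):
    return MentionAnnotation(doc, part, start, end,
                             surface or "x" * (end - start),
                             mention_class=cls)


# ---------------------------------------------------------------- matching

def test_exact_match_identical_offsets():
    counts, pairs = match([_ann(10, 20)], [_ann(10, 20)], "exact")
    assert (counts.tp, counts.fp, counts.fn) == (1, 0, 0)
    assert len(pairs) == 1


def test_partial_match_bracketed_words_case():
    """A prediction lacking leading context words still counts in partial mode."""
    text = "[changed conserved] glutamine at 115 to proline"
    gold = [_ann(0, len(text), surface=text)]
    pred = [_ann(20, len(text), surface=text[20:])]
    exact, _ = match(gold, pred, "exact")
    partial, _ = match(gold, pred, "partial")
    assert (exact.tp, exact.fp, exact.fn) == (0, 1, 1)
    assert (partial.tp, partial.fp, partial.fn) == (1, 0, 0)


def test_half_open_adjacency_is_no_overlap():
    counts, _ = match([_ann(10, 20)], [_ann(20, 25)], "partial")
    assert (counts.tp, counts.fp, counts.fn) == (0, 1, 1)


def test_match_rejects_mixed_documents():
    with pytest.raises(ValueError):
        match([_ann(0, 2, doc="a")], [_ann(0, 2, doc="b")], "exact")


@given(
    st.lists(st.tuples(st.integers(0, 30), st.integers(1, 6)), max_size=6),
    st.lists(st.tuples(st.integers(0, 30), st.integers(1, 6)), max_size=6),
)
def test_partial_match_against_brute_force(gold_raw, pred_raw):
    gold = [_ann(s, s + w) for s, w in gold_raw]
    pred = [_ann(s, s + w) for s, w in pred_raw]
    counts, _ = match(gold, pred, "partial")
    # brute-force all-pairs overlap oracle
    tp = sum(
        1 for g in gold if any(g.start < p.end and p.start < g.end for p in pred)
    )
    fp = sum(
        1 for p in pred if not any(g.start < p.end and p.start < g.end for g in gold)
    )
    assert (counts.tp, counts.fp, counts.fn) == (tp, fp, len(gold) - tp)
    # partial tp >= exact tp on the same pair of sets
    exact, _ = match(gold, pred, "exact")
    assert counts.tp >= exact.tp
    # tp + fn == #gold in both modes
    assert counts.tp + counts.fn == len(gold) == exact.tp + exact.fn


def test_subclass_attribution_and_additivity():
    gold = [
        _ann(0, 5, cls=MentionClass.NL),
        _ann(10, 15, cls=MentionClass.ST),
        _ann(20, 25, cls=MentionClass.SST),
    ]
    pred = [_ann(2, 4), _ann(10, 15)]  # NL partially hit, ST exactly hit
    per_class = subclass_counts(gold, pred, "partial")
    assert per_class[MentionClass.NL].tp == 1
    assert per_class[MentionClass.ST].tp == 1
    assert per_class[MentionClass.SST].fn == 1
    # with no predictions, per-class fn equals per-class gold counts
    none = subclass_counts(gold, [], "partial")
    assert all(c.tp == 0 for c in none.values())
    assert none[MentionClass.NL].fn == 1
    # tp+fn over classes equals number of gold mentions
    total = sum(c.tp + c.fn for c in per_class.values())
    assert total == len(gold)


def test_subclass_requires_classes():
    with pytest.raises(ValueError):
        subclass_counts([_ann(0, 3)], [], "partial")


def test_counts_additive_over_documents():
    gold = [_ann(0, 3, doc="a"), _ann(0, 3, doc="b")]
    pred = [_ann(0, 3, doc="a"), _ann(5, 8, doc="b")]
    total = corpus_counts(gold, pred, "exact")
    a = match([gold[0]], [pred[0]], "exact")[0]
    b = match([gold[1]], [pred[1]], "exact")[0]
    assert (total.tp, total.fp, total.fn) == (
        a.tp + b.tp, a.fp + b.fp, a.fn + b.fn
    )


# -------------------------------------------------------------------- P/R/F

@pytest.mark.parametrize(
    "tp,fp,fn,expected",
    [
        (1, 0, 0, (1.0, 1.0, 1.0)),
        (2, 1, 2, (2 / 3, 1 / 2, 4 / 7)),
        (0, 0, 0, (0.0, 0.0, 0.0)),
    ],
)
def test_prf_formulas(tp, fp, fn, expected):
    m = prf(ConfusionCounts(tp, fp, fn))
    assert (m.precision, m.recall, m.f1) == pytest.approx(expected)
    if tp + fp == 0 or tp + fn == 0:
        assert m.degenerate


# ---------------------------------------------------------------- bootstrap

def test_bootstrap_constant_metric_zero_stderr():
    se = bootstrap_stderr(list(range(20)), lambda s: 0.75,
                          BootstrapConfig(n_samples=50, seed=1))
    assert se == 0.0


def test_bootstrap_two_point_closed_form():
    """Subsamples of one item from {0, 1} give a Bernoulli(1/2) spread."""
    items = [0.0, 1.0]
    cfg = BootstrapConfig(n_samples=1000, fraction=0.5, seed=2)
    se = bootstrap_stderr(items, lambda s: s[0], cfg)
    # closed form: sample std of n Bernoulli(1/2) draws -> sqrt(p(1-p)) = 0.5
    assert se == pytest.approx(0.5, abs=0.05)
    # exact relation between the two estimators
    cfg2 = BootstrapConfig(n_samples=1000, fraction=0.5, seed=2,
                           estimator="sigma_over_sqrt_n")
    assert bootstrap_stderr(items, lambda s: s[0], cfg2) == pytest.approx(
        se / math.sqrt(1000)
    )


def test_bootstrap_deterministic_and_resamples_degenerate():
    items = list(range(10))

    def metric(subset):
        if all(i % 2 for i in subset):
            raise DegenerateMetric
        return float(np.mean(subset))

    cfg = BootstrapConfig(n_samples=30, seed=5)
    assert bootstrap_stderr(items, metric, cfg) == bootstrap_stderr(
        items, metric, cfg
    )


# ------------------------------------------------------- cross-corpus mean

def test_cross_corpus_mean_and_stderr():
    def rep(p, r, f):
        return EvalReport("partial", "all", ConfusionCounts(1, 1, 1), p, r, f)

    mean = cross_corpus_mean([rep(0.8, 0.6, 0.7), rep(0.9, 0.8, 0.8)])
    assert mean.precision == pytest.approx(0.85)
    assert mean.f1 == pytest.approx(0.75)
    assert mean.stderr == pytest.approx(np.std([0.7, 0.8], ddof=1) / math.sqrt(2))
    # four corpora against a hand computation
    reports = [rep(0.8, 0.8, 0.80), rep(0.9, 0.9, 0.90),
               rep(0.7, 0.7, 0.70), rep(0.6, 0.6, 0.60)]
    mean4 = cross_corpus_mean(reports)
    assert mean4.f1 == pytest.approx(0.75)
    assert mean4.stderr == pytest.approx(
        np.std([0.8, 0.9, 0.7, 0.6], ddof=1) / 2
    )
    single = rep(0.5, 0.5, 0.5)
    assert cross_corpus_mean([single]).stderr is None


# ------------------------------------------------- exclusive detection

def _gold_for(doc, surface, start, cls=MentionClass.ST):
    return MentionAnnotation(doc, "s1", start, start + len(surface), surface,
                             mention_class=cls)


def test_exclusive_detection_identical_methods_zero():
    gold = [_gold_for("d1", "E6V", 0)]
    pred = [_ann(0, 3, doc="d1")]
    out = exclusive_detection(gold, {"a": pred, "b": list(pred)}, "exact")
    assert out["all"] == {"a": 0.0, "b": 0.0}


def test_exclusive_detection_simple_split():
    gold = [_gold_for("d1", "E6V", 0), _gold_for("d1", "Q115P", 10)]
    pa = [_ann(0, 3, doc="d1"), _ann(10, 15, doc="d1")]
    pb = [_ann(0, 3, doc="d1")]
    out = exclusive_detection(gold, {"A": pa, "B": pb}, "exact")
    assert out["all"] == {"A": 50.0, "B": 0.0}


def test_exclusive_detection_three_methods_vs_set_algebra():
    surfaces = ["E6V", "Q115P", "rs206437", "D17S250", "c.76delA"]
    gold, offset = [], 0
    for s in surfaces:
        gold.append(_gold_for("d1", s, offset,
                              cls=MentionClass.NL if s == "E6V" else MentionClass.ST))
        offset += len(s) + 1
    span = {g.surface: (g.start, g.end) for g in gold}

    def preds(names):
        return [_ann(*span[n], doc="d1") for n in names]

    by_method = {
        "m1": preds(["E6V", "Q115P", "rs206437"]),
        "m2": preds(["Q115P", "D17S250"]),
        "m3": preds(["Q115P"]),
    }
    out = exclusive_detection(gold, by_method, "exact")
    # brute-force set algebra
    detected = {"m1": {"E6V", "Q115P", "rs206437"},
                "m2": {"Q115P", "D17S250"}, "m3": {"Q115P"}}
    pool = set().union(*detected.values())
    for m in detected:
        others = set().union(*(v for k, v in detected.items() if k != m))
        assert out["all"][m] == pytest.approx(
            100 * len(detected[m] - others) / len(pool)
        )
    assert sum(out["all"].values()) <= 100.0
    # NL scope: only E6V is NL; m1 alone finds it
    assert out["NL"] == {"m1": 100.0, "m2": 0.0, "m3": 0.0}


def test_exclusive_detection_needs_two_methods_and_nonempty_pool():
    gold = [_gold_for("d1", "E6V", 0)]
    with pytest.raises(ValueError):
        exclusive_detection(gold, {"only": []})
    with pytest.raises(ValueError):
        exclusive_detection(gold, {"a": [], "b": []})


def test_evaluate_reports_scopes():
    gold = [_gold_for("d1", "E6V", 0), _gold_for("d1", "Q115P", 10,
                                                 cls=MentionClass.NL)]
    pred = [_ann(0, 3, doc="d1")]
    reports = evaluate(gold, pred, "exact")
    assert reports["all"].counts.tp == 1
    assert reports["ST"].recall == 1.0
    assert reports["NL"].recall == 0.0
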