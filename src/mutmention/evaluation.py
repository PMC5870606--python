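"""Evaluation protocol for mention-level NER.

A gold mention is a true positive when a predicted mention matches it:
*exact* matching requires identical character offsets, *partial* matching
any overlap (half-open interval intersection).  Each gold mention matched
by at least one prediction counts once as tp; predictions matching no gold
are fp; unmatched gold are fn.  Subclass (ST/SST/NL) scoring attributes
tp/fn by the gold mention's class — a gold mention of class X is correct
if *any* prediction matched it — while fp are only defined at the "all"
scope (a spurious prediction has no gold class).

P = tp/(tp+fp), R = tp/(tp+fn), F = 2PR/(P+R); degenerate denominators
yield 0 with a flag.  The within-corpus StdErr is the spread of the metric
over bootstrap subsamples of the test documents: ``n_samples`` draws of
``fraction`` of the documents without replacement, metric recomputed each
time.  Both the sigma of that distribution (default) and the literal
sigma/sqrt(n) reading are available; they differ by an exact factor
sqrt(n).  Across corpora, means of P/R/F are unweighted and the StdErr of
the mean is the sample std over corpora divided by sqrt(#corpora).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .types import MentionAnnotation, MentionClass


class DegenerateMetric(Exception):
    """Raised by a metric when it is undefined on a subsample (no gold)."""


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn
        )


@dataclass
class PRF:
    precision: float
    recall: float
    f1: float
    degenerate: bool = False


@dataclass
class EvalReport:
    mode: str
    scope: str
    counts: ConfusionCounts
    precision: float
    recall: float
    f1: float
    stderr: float | None = None
    degenerate: bool = False


def prf(counts: ConfusionCounts) -> PRF:
    """Precision, recall and F-measure; degenerate denominators -> 0 + flag."""
    degenerate = False
    if counts.tp + counts.fp == 0:
        p, degenerate = 0.0, True
    else:
        p = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        r, degenerate = 0.0, True
    else:
        r = counts.tp / (counts.tp + counts.fn)
    if p + r == 0:
        return PRF(p, r, 0.0, True)
    return PRF(p, r, 2 * p * r / (p + r), degenerate)


def _overlap(a: MentionAnnotation, b: MentionAnnotation) -> bool:
    return a.start < b.end and b.start < a.end


def match(
    gold: Sequence[MentionAnnotation],
    predicted: Sequence[MentionAnnotation],
    mode: str = "partial",
) -> tuple[ConfusionCounts, list[tuple[MentionAnnotation, MentionAnnotation]]]:
    """Match predictions against gold within one document part.

    Exact mode pairs each prediction with at most one gold mention
    (identical offsets); partial mode lets one prediction satisfy every
    gold mention it overlaps, counting it once.
    """
    if mode not in ("exact", "partial"):
        raise ValueError(f"unknown matching mode {mode!r}")
    keys = {(a.doc_id, a.part_id) for a in (*gold, *predicted)}
    if len(keys) > 1:
        raise ValueError(f"annotations span multiple document parts: {keys}")
    pairs: list[tuple[MentionAnnotation, MentionAnnotation]] = []
    if mode == "exact":
        used = [False] * len(predicted)
        matched_gold = 0
        for g in gold:
            for i, p in enumerate(predicted):
                if not used[i] and (p.start, p.end) == (g.start, g.end):
                    used[i] = True
                    matched_gold += 1
                    pairs.append((g, p))
                    break
        fp = used.count(False)
        counts = ConfusionCounts(matched_gold, fp, len(gold) - matched_gold)
    else:
        matched_gold = 0
        for g in gold:
            hits = [p for p in predicted if _overlap(g, p)]
            if hits:
                matched_gold += 1
                pairs.extend((g, p) for p in hits)
        fp = sum(1 for p in predicted if not any(_overlap(g, p) for g in gold))
        counts = ConfusionCounts(matched_gold, fp, len(gold) - matched_gold)
    return counts, pairs


def _group(
    anns: Sequence[MentionAnnotation],
) -> dict[tuple[str, str], list[MentionAnnotation]]:
    out: dict[tuple[str, str], list[MentionAnnotation]] = {}
    for a in anns:
        out.setdefault((a.doc_id, a.part_id), []).append(a)
    return out


def corpus_counts(
    gold: Sequence[MentionAnnotation],
    predicted: Sequence[MentionAnnotation],
    mode: str = "partial",
) -> ConfusionCounts:
    """Aggregate tp/fp/fn over all document parts (additive)."""
    g_by, p_by = _group(gold), _group(predicted)
    total = ConfusionCounts()
    for key in set(g_by) | set(p_by):
        counts, _ = match(g_by.get(key, []), p_by.get(key, []), mode)
        total = total + counts
    return total


def subclass_counts(
    gold: Sequence[MentionAnnotation],
    predicted: Sequence[MentionAnnotation],
    mode: str = "partial",
) -> dict[MentionClass, ConfusionCounts]:
    """Per-class tp/fn attribution by the gold mention's class (fp stays 0)."""
    for g in gold:
        if g.mention_class is None:
            raise ValueError(f"gold mention without class: {g.surface!r}")
    g_by, p_by = _group(gold), _group(predicted)
    out = {cls: ConfusionCounts() for cls in MentionClass}
    for key, g_list in g_by.items():
        _, pairs = match(g_list, p_by.get(key, []), mode)
        matched = {id(g) for g, _p in pairs}
        for g in g_list:
            if id(g) in matched:
                out[g.mention_class] = out[g.mention_class] + ConfusionCounts(tp=1)
            else:
                out[g.mention_class] = out[g.mention_class] + ConfusionCounts(fn=1)
    return out


def evaluate(
    gold: Sequence[MentionAnnotation],
    predicted: Sequence[MentionAnnotation],
    mode: str = "partial",
) -> dict[str, EvalReport]:
    """Reports for the "all" scope and each mention class."""
    reports: dict[str, EvalReport] = {}
    counts = corpus_counts(gold, predicted, mode)
    m = prf(counts)
    reports["all"] = EvalReport(mode, "all", counts, m.precision, m.recall,
                                m.f1, degenerate=m.degenerate)
    if all(g.mention_class is not None for g in gold):
        for cls, c in subclass_counts(gold, predicted, mode).items():
            m = prf(c)
            reports[cls.value] = EvalReport(mode, cls.value, c, m.precision,
                                            m.recall, m.f1, degenerate=m.degenerate)
    return reports


@dataclass
class BootstrapConfig:
    n_samples: int = 1000
    fraction: float = 0.15
    seed: int = 0
    estimator: str = "sigma"  # or "sigma_over_sqrt_n"

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.estimator not in ("sigma", "sigma_over_sqrt_n"):
            raise ValueError(f"unknown estimator {self.estimator!r}")


def bootstrap_stderr(
    per_item_inputs: Sequence,
    metric: Callable[[Sequence], float],
    config: BootstrapConfig | None = None,
) -> float:
    """Spread of ``metric`` over subsamples of the test items (documents).

    Each of ``n_samples`` draws selects ``ceil(fraction * N)`` items
    without replacement and recomputes the metric.  A draw on which the
    metric is undefined (raises :class:`DegenerateMetric`) is redrawn.
    """
    config = config or BootstrapConfig()
    items = list(per_item_inputs)
    if len(items) < 2:
        raise ValueError("need at least 2 items to bootstrap")
    m = math.ceil(config.fraction * len(items))
    rng = np.random.default_rng(config.seed)
    values: list[float] = []
    attempts = 0
    max_attempts = config.n_samples * 50
    while len(values) < config.n_samples:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("metric undefined on nearly all subsamples")
        chosen = rng.choice(len(items), size=m, replace=False)
        try:
            values.append(metric([items[i] for i in chosen]))
        except DegenerateMetric:
            continue
    sigma = float(np.std(values, ddof=1))
    if config.estimator == "sigma_over_sqrt_n":
        return sigma / math.sqrt(config.n_samples)
    return sigma


def cross_corpus_mean(reports: Sequence[EvalReport]) -> EvalReport:
    """Unweighted mean of P/R/F across corpora; StdErr of the mean on F."""
    if not reports:
        raise ValueError("need at least one report")
    if len(reports) == 1:
        return reports[0]
    p = float(np.mean([r.precision for r in reports]))
    r_ = float(np.mean([r.recall for r in reports]))
    f = float(np.mean([r.f1 for r in reports]))
    stderr = float(np.std([r.f1 for r in reports], ddof=1) / math.sqrt(len(reports)))
    counts = ConfusionCounts()
    for rep in reports:
        counts = counts + rep.counts
    return EvalReport(reports[0].mode, reports[0].scope, counts, p, r_, f, stderr)


def exclusive_detection(
    gold: Sequence[MentionAnnotation],
    predictions_by_method: Mapping[str, Sequence[MentionAnnotation]],
    mode: str = "partial",
) -> dict[str, dict[str, float]]:
    """Percent of correctly-detected unique mentions found by one method only.

    The pool is the set of unique ``(doc_id, surface)`` gold mentions
    correctly detected by at least one method (repetitions within a
    publication collapse).  Returned as ``{"all": {...}, "NL": {...}}``
    with per-method percentages; percentages within a scope sum to <= 100.
    """
    if len(predictions_by_method) < 2:
        raise ValueError("need >= 2 methods to compare")
    detected: dict[str, set[tuple[str, str]]] = {}
    for method, preds in predictions_by_method.items():
        g_by, p_by = _group(gold), _group(preds)
        hits: set[tuple[str, str]] = set()
        for key, g_list in g_by.items():
            _, pairs = match(g_list, p_by.get(key, []), mode)
            hits.update((g.doc_id, g.surface) for g, _p in pairs)
        detected[method] = hits

    def exclusive(keys_filter: Callable[[tuple[str, str]], bool]) -> dict[str, float]:
        pool = {k for hits in detected.values() for k in hits if keys_filter(k)}
        if not pool:
            raise ValueError("empty detection pool")
        out = {}
        for method, hits in detected.items():
            others = set().union(
                *(h for m2, h in detected.items() if m2 != method)
            )
            only = {k for k in hits if keys_filter(k)} - others
            out[method] = 100.0 * len(only) / len(pool)
        return out

    result = {"all": exclusive(lambda k: True)}
    nl_keys = {
        (g.doc_id, g.surface)
        for g in gold
        if g.mention_class == MentionClass.NL
    }
    if nl_keys:
        result["NL"] = exclusive(lambda k: k in nl_keys)
    return result
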