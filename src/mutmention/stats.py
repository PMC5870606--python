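"""Corpus-level statistics over gold mutation mentions.

Counts are reported both *with repetitions* (every occurrence counts) and
*unique* (identical surface strings within one document collapse to one).
Uniqueness is case-sensitive exact string match — the most conservative
reading; see docs/methods.md.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .classify import ClassifierConfig, classify
from .tokenizer import tokenize
from .types import Document, MentionAnnotation, MentionClass

Classifier = Callable[[str], MentionClass]


def make_classifier(config: ClassifierConfig | None = None) -> Classifier:
    return lambda mention: classify(mention, config)


def _classed(
    anns: Iterable[MentionAnnotation], classifier: Classifier
) -> list[MentionAnnotation]:
    """Attach a class to every annotation that lacks one."""
    return [
        a if a.mention_class is not None else a.with_class(classifier(a.surface))
        for a in anns
    ]


@dataclass
class CorpusStats:
    n_documents: int = 0
    n_tokens: int = 0
    n_mentions: int = 0
    n_mentions_unique: int = 0
    per_class: Counter = field(default_factory=Counter)
    per_class_unique: Counter = field(default_factory=Counter)
    n_docs_nl_only: int = 0  # docs whose mentions are all NL/SST (no ST)

    def validate(self) -> None:
        assert sum(self.per_class.values()) == self.n_mentions
        assert sum(self.per_class_unique.values()) == self.n_mentions_unique
        for cls in MentionClass:
            assert self.per_class_unique[cls] <= self.per_class[cls]


def corpus_stats(
    docs: Sequence[Document],
    anns: Sequence[MentionAnnotation],
    classifier: Classifier | None = None,
) -> CorpusStats:
    """Aggregate mention counts (repeated and unique) and token totals."""
    classifier = classifier or make_classifier()
    anns = _classed(anns, classifier)
    stats = CorpusStats(n_documents=len(docs))
    for doc in docs:
        for _pid, text in doc.iter_parts():
            stats.n_tokens += len(tokenize(text))
    by_doc: dict[str, list[MentionAnnotation]] = {}
    for a in anns:
        by_doc.setdefault(a.doc_id, []).append(a)
    for doc_anns in by_doc.values():
        seen: set[tuple[str, MentionClass]] = set()
        classes = set()
        for a in doc_anns:
            stats.n_mentions += 1
            stats.per_class[a.mention_class] += 1
            classes.add(a.mention_class)
            key = (a.surface, a.mention_class)
            if key not in seen:
                seen.add(key)
                stats.n_mentions_unique += 1
                stats.per_class_unique[a.mention_class] += 1
        if classes and MentionClass.ST not in classes:
            stats.n_docs_nl_only += 1
    stats.validate()
    return stats


def nl_only_fractions(
    docs: Sequence[Document],
    anns: Sequence[MentionAnnotation],
    classifier: Classifier | None = None,
) -> tuple[float, float]:
    """Share of documents / mentions with NL-or-SST info not also in ST form.

    A document counts when it holds >=1 NL or SST mention and *no* ST
    mention at all; the mention fraction counts NL/SST mentions living in
    such documents, over all mentions.  (Matching NL and ST mentions that
    describe the *same* variant would require normalization, which is out
    of scope; absence of any ST mention is the stated approximation.)
    """
    if not docs:
        raise ValueError("empty corpus")
    classifier = classifier or make_classifier()
    anns = _classed(anns, classifier)
    by_doc: dict[str, list[MentionAnnotation]] = {d.doc_id: [] for d in docs}
    for a in anns:
        by_doc.setdefault(a.doc_id, []).append(a)
    n_docs_hit = 0
    n_mentions_hit = 0
    for doc_anns in by_doc.values():
        classes = {a.mention_class for a in doc_anns}
        has_nl_sst = bool(classes & {MentionClass.NL, MentionClass.SST})
        if has_nl_sst and MentionClass.ST not in classes:
            n_docs_hit += 1
            n_mentions_hit += sum(
                a.mention_class in (MentionClass.NL, MentionClass.SST)
                for a in doc_anns
            )
    doc_fraction = n_docs_hit / len(docs)
    mention_fraction = n_mentions_hit / len(anns) if anns else 0.0
    return doc_fraction, mention_fraction


def nl_density_ratio(
    abstracts: tuple[Sequence[Document], Sequence[MentionAnnotation]],
    fulltexts: tuple[Sequence[Document], Sequence[MentionAnnotation]],
    classifier: Classifier | None = None,
) -> float:
    """(NL mentions per token in abstracts) / (NL mentions per token in full texts).

    Returns ``inf`` (flagged by the caller as such) when the full-text
    corpus has no NL mentions.
    """
    classifier = classifier or make_classifier()

    def density(docs: Sequence[Document], anns: Sequence[MentionAnnotation]) -> float:
        if not docs:
            raise ValueError("empty corpus")
        n_tok = sum(len(tokenize(t)) for d in docs for _p, t in d.iter_parts())
        n_nl = sum(
            a.mention_class == MentionClass.NL for a in _classed(anns, classifier)
        )
        return n_nl / n_tok

    d_abs = density(*abstracts)
    d_full = density(*fulltexts)
    if d_full == 0.0:
        return float("inf")
    return d_abs / d_full
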