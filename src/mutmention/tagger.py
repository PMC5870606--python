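"""CRF tagger: training, prediction and post-processing.

The CRF unit is the sentence: each document part is tokenized once (offsets
preserved), split into sentences by the rule-based detector, and every
sentence becomes one label sequence.  Post-processing fixes small boundary
problems (absorbing a sign prefix, trimming whitespace) and optionally
filters rsid and genetic-marker predictions — both filters are user
switches, defaulting to keeping everything.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

from .bieo import decode_bieo, encode_bieo
from .classify import classify
from .crf import LinearChainCRF
from .embeddings import EmbeddingModel
from .features import FeatureConfig, sequence_features
from .tokenizer import detect_sentence_starts, tokenize
from .types import Document, MentionAnnotation, MentionClass, Token, validate_annotations

RSID_RE = re.compile(r"rs[0-9]+")
GENETIC_MARKER_RE = re.compile(r"D[0-9]{1,2}S[0-9]+")


@dataclass
class PostProcessConfig:
    annotate_rsids: bool = True
    annotate_genetic_markers: bool = True
    boundary_fix_enabled: bool = True


@dataclass
class Hyperparams:
    c1: float = 0.0  # L1 not supported by the L-BFGS optimizer; must stay 0
    c2: float = 0.1
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.c1 != 0.0:
            raise ValueError("L1 regularization (c1) is not supported; set c1=0")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Sentence spans (start, end) covering the text, by the rule detector."""
    starts = sorted(detect_sentence_starts(text))
    if not starts:
        return [(0, len(text))] if text else []
    spans = []
    for i, s in enumerate(starts):
        e = starts[i + 1] if i + 1 < len(starts) else len(text)
        spans.append((s, e))
    if starts[0] > 0:
        spans[0] = (0, spans[0][1])
    return spans


def sentence_token_groups(text: str) -> list[list[Token]]:
    tokens = tokenize(text)
    groups: list[list[Token]] = []
    for s, e in split_sentences(text):
        group = [t for t in tokens if s <= t.start < e]
        if group:
            groups.append(group)
    return groups


@dataclass
class TaggerModel:
    crf: LinearChainCRF
    feature_config: FeatureConfig
    embedding_model: EmbeddingModel | None = None
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    metadata: dict = field(default_factory=dict)

    def check_config(self, feature_config: FeatureConfig | None) -> FeatureConfig:
        if feature_config is None:
            return self.feature_config
        if feature_config != self.feature_config:
            raise ValueError(
                "feature config differs from the one used at training time"
            )
        return feature_config

    def save(self, path: str | Path) -> None:
        path = Path(path)
        obj = {
            "crf": self.crf.to_dict(),
            "feature_config": {
                "context_window": self.feature_config.context_window,
                "affix_lengths": list(self.feature_config.affix_lengths),
                "dictionaries": {
                    k: sorted(v) for k, v in self.feature_config.dictionaries.items()
                },
                "use_embeddings": self.feature_config.use_embeddings,
            },
            "hyperparams": asdict(self.hyperparams),
            "metadata": self.metadata,
            "has_embeddings": self.embedding_model is not None,
        }
        path.write_text(json.dumps(obj))
        if self.embedding_model is not None:
            self.embedding_model.save(path.with_suffix(".embeddings.txt"))

    @classmethod
    def load(cls, path: str | Path) -> "TaggerModel":
        path = Path(path)
        obj = json.loads(path.read_text())
        fc = obj["feature_config"]
        feature_config = FeatureConfig(
            context_window=fc["context_window"],
            affix_lengths=tuple(fc["affix_lengths"]),
            dictionaries={k: frozenset(v) for k, v in fc["dictionaries"].items()},
            use_embeddings=fc["use_embeddings"],
        )
        emb = None
        if obj.get("has_embeddings"):
            emb = EmbeddingModel.load(path.with_suffix(".embeddings.txt"))
        return cls(
            crf=LinearChainCRF.from_dict(obj["crf"]),
            feature_config=feature_config,
            embedding_model=emb,
            hyperparams=Hyperparams(**obj["hyperparams"]),
            metadata=obj.get("metadata", {}),
        )


def _training_sequences(
    documents: Sequence[Document],
    gold: Sequence[MentionAnnotation],
    feature_config: FeatureConfig,
    embedding_model: EmbeddingModel | None,
) -> tuple[list, list]:
    by_part: dict[tuple[str, str], list[MentionAnnotation]] = {}
    for a in gold:
        by_part.setdefault((a.doc_id, a.part_id), []).append(a)
    X, y = [], []
    emb = embedding_model if feature_config.use_embeddings else None
    for doc in documents:
        for part_id, text in doc.iter_parts():
            part_anns = by_part.get((doc.doc_id, part_id), [])
            for group in sentence_token_groups(text):
                s, e = group[0].start, group[-1].end
                sent_anns = [a for a in part_anns if a.start < e and a.end > s]
                X.append(sequence_features(group, feature_config, emb))
                y.append(encode_bieo(group, sent_anns))
    return X, y


def train(
    documents: Sequence[Document],
    gold_annotations: Sequence[MentionAnnotation],
    feature_config: FeatureConfig | None = None,
    embedding_model: EmbeddingModel | None = None,
    hyperparams: Hyperparams | None = None,
    seed: int = 0,
) -> TaggerModel:
    """Train a CRF tagger on BIEO-encoded sentences of ``documents``.

    Training itself is deterministic; ``seed`` is recorded in the model
    metadata (and matters only upstream, e.g. for embedding training).
    """
    if not documents:
        raise ValueError("cannot train on an empty corpus")
    if not gold_annotations:
        raise ValueError("cannot train without any gold annotation")
    for doc in documents:
        validate_annotations(
            doc, [a for a in gold_annotations if a.doc_id == doc.doc_id]
        )
    feature_config = feature_config or FeatureConfig()
    hyperparams = hyperparams or Hyperparams()
    X, y = _training_sequences(
        documents, gold_annotations, feature_config, embedding_model
    )
    crf = LinearChainCRF(c2=hyperparams.c2, max_iter=hyperparams.max_iter)
    crf.fit(X, y)
    return TaggerModel(
        crf=crf,
        feature_config=feature_config,
        embedding_model=embedding_model,
        hyperparams=hyperparams,
        metadata={
            "n_documents": len(documents),
            "n_annotations": len(gold_annotations),
            "seed": seed,
        },
    )


def fix_boundaries(
    part_text: str, annotation: MentionAnnotation
) -> MentionAnnotation:
    """Trim flanking whitespace and absorb a sign prefix on a leading digit.

    The canonical case: a prediction on ``1858C > T`` inside the text
    ``the +1858C > T variant`` is extended to cover ``+1858C > T``.
    """
    start, end = annotation.start, annotation.end
    while start < end and part_text[start].isspace():
        start += 1
    while end > start and part_text[end - 1].isspace():
        end -= 1
    if start == end:
        return annotation
    if (
        start > 0
        and part_text[start - 1] in "+-−"
        and part_text[start].isdigit()
        and (start < 2 or not part_text[start - 2].isalnum())
    ):
        start -= 1
    if (start, end) == (annotation.start, annotation.end):
        return annotation
    fixed = replace(
        annotation, start=start, end=end, surface=part_text[start:end]
    )
    fixed.validate_against(part_text)
    return fixed


def filter_special(
    annotations: Sequence[MentionAnnotation],
    postprocess_config: PostProcessConfig | None = None,
) -> list[MentionAnnotation]:
    """Optionally drop rsid and genetic-marker predictions (never add any)."""
    cfg = postprocess_config or PostProcessConfig()
    out = []
    for a in annotations:
        surface = a.surface.strip()
        if not cfg.annotate_rsids and RSID_RE.fullmatch(surface):
            continue
        if not cfg.annotate_genetic_markers and GENETIC_MARKER_RE.fullmatch(surface):
            continue
        out.append(a)
    return out


def predict(
    model: TaggerModel,
    document: Document,
    postprocess_config: PostProcessConfig | None = None,
) -> list[MentionAnnotation]:
    """Viterbi-decode mentions in every sentence of ``document``."""
    if not model.crf.is_fitted:
        raise RuntimeError("model is not trained")
    cfg = postprocess_config or PostProcessConfig()
    emb = model.embedding_model if model.feature_config.use_embeddings else None
    anns: list[MentionAnnotation] = []
    for part_id, text in document.iter_parts():
        groups = sentence_token_groups(text)
        if not groups:
            continue
        X = [sequence_features(g, model.feature_config, emb) for g in groups]
        label_seqs = model.crf.predict(X)
        for group, labels in zip(groups, label_seqs):
            decoded = decode_bieo(
                group, labels, text, doc_id=document.doc_id, part_id=part_id
            )
            if cfg.boundary_fix_enabled:
                decoded = [fix_boundaries(text, a) for a in decoded]
            anns.extend(decoded)
    anns = filter_special(anns, cfg)
    validate_annotations(document, anns)
    return anns


def crossvalidate(
    documents: Sequence[Document],
    gold: Sequence[MentionAnnotation],
    k: int = 5,
    seed: int = 0,
    feature_config: FeatureConfig | None = None,
    embedding_model: EmbeddingModel | None = None,
    hyperparams: Hyperparams | None = None,
    mode: str = "partial",
    postprocess_config: PostProcessConfig | None = None,
):
    """Document-level k-fold cross-validation; returns per-fold and mean reports."""
    from .evaluation import EvalReport, cross_corpus_mean, evaluate

    if k < 2:
        raise ValueError("k must be >= 2 (k=1 leaves no held-out data)")
    if len(documents) < k:
        raise ValueError(f"fewer documents ({len(documents)}) than folds ({k})")
    import numpy as np

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(documents))
    folds = [sorted(order[i::k]) for i in range(k)]
    fold_reports: list[EvalReport] = []
    for fold in folds:
        test_ids = {documents[i].doc_id for i in fold}
        train_docs = [d for d in documents if d.doc_id not in test_ids]
        test_docs = [d for d in documents if d.doc_id in test_ids]
        train_gold = [a for a in gold if a.doc_id not in test_ids]
        test_gold = [a for a in gold if a.doc_id in test_ids]
        model = train(train_docs, train_gold, feature_config, embedding_model,
                      hyperparams, seed)
        preds = [
            p for doc in test_docs for p in predict(model, doc, postprocess_config)
        ]
        fold_reports.append(evaluate(test_gold, preds, mode)["all"])
    return fold_reports, cross_corpus_mean(fold_reports)


def load_nl_recall_patterns(text: str | None = None) -> list[re.Pattern]:
    if text is None:
        text = (
            resources.files("mutmention.data")
            .joinpath("nl_recall_patterns.txt")
            .read_text()
        )
    return [
        re.compile(line.strip(), re.IGNORECASE)
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


def select_nl_documents(
    documents: Sequence[Document],
    model: TaggerModel | None = None,
    nl_recall_regexes: Sequence[re.Pattern] | None = None,
) -> list[Document]:
    """Keep documents likely to contain non-standard (NL) mentions.

    A document is selected when any high-recall regex matches its text;
    when a tagger model is supplied, matches falling inside predictions
    classified ST are discounted (the document must offer something beyond
    already-captured standard mentions).
    """
    patterns = list(nl_recall_regexes) if nl_recall_regexes is not None else (
        load_nl_recall_patterns()
    )
    if not patterns:
        raise ValueError("need at least one recall regex")
    selected = []
    for doc in documents:
        st_spans: dict[str, list[tuple[int, int]]] = {}
        if model is not None:
            for p in predict(model, doc):
                if classify(p.surface) == MentionClass.ST:
                    st_spans.setdefault(p.part_id, []).append((p.start, p.end))
        hit = False
        for part_id, text in doc.iter_parts():
            spans = st_spans.get(part_id, [])
            for pattern in patterns:
                for m in pattern.finditer(text):
                    inside_st = any(
                        m.start() >= s and m.end() <= e for s, e in spans
                    )
                    if not inside_st:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                break
        if hit:
            selected.append(doc)
    return selected
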