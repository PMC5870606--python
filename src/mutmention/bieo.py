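"""BIEO label encoding/decoding between token sequences and mention spans.

B marks the beginning token of a mention, I a continuing token, E the final
token, O everything outside.  Single-token mentions are labeled B (BIEO has
no singleton label; B round-trips cleanly).  Decoding is lenient: an I/E
run with no opening B still becomes a mention starting at the run's first
token, so minor label noise from the tagger does not drop predictions.
"""

from __future__ import annotations

import logging
from typing import Sequence

from .types import MentionAnnotation, Token

logger = logging.getLogger(__name__)

LABELS = ("B", "I", "E", "O")


def encode_bieo(
    tokens: Sequence[Token], annotations: Sequence[MentionAnnotation]
) -> list[str]:
    """Label ``tokens`` with B/I/E/O according to gold ``annotations``.

    Annotations not aligned to token boundaries are snapped outward to the
    overlapped tokens (with a logged warning).  Overlapping annotations are
    rejected with an error naming the pair.
    """
    anns = sorted(annotations, key=lambda a: (a.start, a.end))
    for prev, cur in zip(anns, anns[1:]):
        if cur.start < prev.end:
            raise ValueError(
                f"overlapping gold annotations: ({prev.start},{prev.end}) "
                f"{prev.surface!r} and ({cur.start},{cur.end}) {cur.surface!r}"
            )
    labels = ["O"] * len(tokens)
    for ann in anns:
        idx = [
            i
            for i, t in enumerate(tokens)
            if t.start < ann.end and t.end > ann.start  # overlap, half-open
        ]
        if not idx:
            logger.warning("annotation (%d,%d) %r overlaps no token; skipped",
                           ann.start, ann.end, ann.surface)
            continue
        first, last = idx[0], idx[-1]
        tok_span = (tokens[first].start, tokens[last].end)
        if tok_span != (ann.start, ann.end):
            logger.warning(
                "annotation (%d,%d) %r snapped to token span (%d,%d)",
                ann.start, ann.end, ann.surface, *tok_span)
        labels[first] = "B"
        if last > first:
            labels[last] = "E"
            for i in range(first + 1, last):
                labels[i] = "I"
    return labels


def decode_bieo(
    tokens: Sequence[Token],
    labels: Sequence[str],
    text: str,
    doc_id: str = "doc",
    part_id: str = "s1",
    source: str = "predicted:crf",
) -> list[MentionAnnotation]:
    """Turn a BIEO label sequence back into mention annotations.

    ``text`` is the part text the token offsets refer to; surfaces are
    sliced from it so inner whitespace/punctuation is preserved exactly.
    """
    if len(tokens) != len(labels):
        raise ValueError("labels and tokens differ in length")
    anns: list[MentionAnnotation] = []
    run: list[int] = []

    def close_run() -> None:
        if run:
            start = tokens[run[0]].start
            end = tokens[run[-1]].end
            anns.append(
                MentionAnnotation(
                    doc_id=doc_id, part_id=part_id, start=start, end=end,
                    surface=text[start:end], source=source,
                )
            )
            run.clear()

    for i, label in enumerate(labels):
        if label == "O":
            close_run()
        elif label == "B":
            close_run()
            run.append(i)
        elif label == "I":
            run.append(i)  # lenient: I with no B opens a mention
        elif label == "E":
            run.append(i)
            close_run()
        else:
            raise ValueError(f"unknown label {label!r}")
    close_run()
    return anns
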