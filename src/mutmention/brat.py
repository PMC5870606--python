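"""Reading and writing brat standoff and the JSON standoff dialect.

brat standoff stores a document as a ``.txt`` file plus a ``.ann`` file of
tab-separated entity lines ``Tn<TAB>Label start end<TAB>surface``.  brat has
no notion of document parts, so on export a multi-part document is written
as the parts joined by single newlines with annotation offsets converted to
that joined text; reading yields a single-part document.  Round trips are
therefore bit-exact for single-part documents (the common case: abstracts)
and text/offset-exact otherwise.  The JSON dialect preserves parts and is
the canonical lossless fixture format::

    {"doc_id": "...", "is_full_text": false,
     "parts": [{"id": "s1", "text": "..."}],
     "annotations": [{"part_id": "s1", "start": 0, "end": 3,
                      "surface": "E6V", "class": "ST", "source": "gold"}]}
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

from .types import Document, MentionAnnotation, MentionClass, validate_annotations

logger = logging.getLogger(__name__)

DEFAULT_LABELS = frozenset({"Mutation"})

_T_LINE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")


def read_brat(
    txt_content: str,
    ann_content: str,
    doc_id: str = "doc",
    labels: frozenset[str] = DEFAULT_LABELS,
    part_id: str = "s1",
) -> tuple[Document, list[MentionAnnotation]]:
    """Parse a brat ``.txt``/``.ann`` pair into a single-part document.

    Malformed entity lines and lines whose surface does not match the text
    slice are rejected individually (with a logged diagnostic); the document
    itself is always loaded.
    """
    doc = Document(doc_id=doc_id, parts=[(part_id, txt_content)])
    anns: list[MentionAnnotation] = []
    for lineno, line in enumerate(ann_content.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith("T"):
            continue  # relations/attributes/notes are out of scope
        m = _T_LINE.match(line)
        if m is None:
            logger.warning("%s ann line %d: malformed T-line rejected: %r",
                           doc_id, lineno, line)
            continue
        _tid, label, start_s, end_s, surface = m.groups()
        if label not in labels:
            continue
        start, end = int(start_s), int(end_s)
        if not (0 <= start < end <= len(txt_content)):
            logger.warning("%s ann line %d: offsets (%d,%d) outside text",
                           doc_id, lineno, start, end)
            continue
        if txt_content[start:end] != surface:
            logger.warning(
                "%s ann line %d: surface %r != text slice %r; line rejected",
                doc_id, lineno, surface, txt_content[start:end])
            continue
        anns.append(MentionAnnotation(doc_id=doc_id, part_id=part_id,
                                      start=start, end=end, surface=surface))
    return doc, anns


def write_brat(
    doc: Document, anns: Sequence[MentionAnnotation], label: str = "Mutation"
) -> tuple[str, str]:
    """Serialize to a brat ``(.txt content, .ann content)`` pair.

    Raises ``ValueError`` naming the offending annotation if any violates
    the span/surface invariants.
    """
    validate_annotations(doc, anns)
    part_base: dict[str, int] = {}
    pieces: list[str] = []
    offset = 0
    for part_id, text in doc.iter_parts():
        part_base[part_id] = offset
        pieces.append(text)
        offset += len(text) + 1  # joining newline
    txt_content = "\n".join(pieces)
    ann_lines = []
    for i, ann in enumerate(anns, start=1):
        base = part_base[ann.part_id]
        ann_lines.append(
            f"T{i}\t{label} {base + ann.start} {base + ann.end}\t{ann.surface}"
        )
    ann_content = "".join(line + "\n" for line in ann_lines)
    return txt_content, ann_content


def to_json(doc: Document, anns: Sequence[MentionAnnotation]) -> str:
    validate_annotations(doc, anns)
    obj = {
        "doc_id": doc.doc_id,
        "is_full_text": doc.is_full_text,
        "parts": [{"id": pid, "text": text} for pid, text in doc.iter_parts()],
        "annotations": [
            {
                "part_id": a.part_id,
                "start": a.start,
                "end": a.end,
                "surface": a.surface,
                "class": a.mention_class.value if a.mention_class else None,
                "source": a.source,
            }
            for a in anns
        ],
    }
    return json.dumps(obj, ensure_ascii=False, indent=1)


def from_json(content: str) -> tuple[Document, list[MentionAnnotation]]:
    obj = json.loads(content)
    doc = Document(
        doc_id=obj["doc_id"],
        parts=[(p["id"], p["text"]) for p in obj["parts"]],
        is_full_text=bool(obj.get("is_full_text", False)),
    )
    anns = [
        MentionAnnotation(
            doc_id=doc.doc_id,
            part_id=a["part_id"],
            start=a["start"],
            end=a["end"],
            surface=a["surface"],
            mention_class=MentionClass(a["class"]) if a.get("class") else None,
            source=a.get("source", "gold"),
        )
        for a in obj.get("annotations", [])
    ]
    validate_annotations(doc, anns)
    return doc, anns


def read_corpus_dir(
    path: str | Path, labels: frozenset[str] = DEFAULT_LABELS
) -> tuple[list[Document], list[MentionAnnotation]]:
    """Load a directory of ``*.txt``/``*.ann`` pairs and/or ``*.json`` files."""
    path = Path(path)
    docs: list[Document] = []
    anns: list[MentionAnnotation] = []
    for txt_file in sorted(path.glob("*.txt")):
        ann_file = txt_file.with_suffix(".ann")
        ann_content = ann_file.read_text() if ann_file.exists() else ""
        doc, doc_anns = read_brat(
            txt_file.read_text(), ann_content, doc_id=txt_file.stem, labels=labels
        )
        docs.append(doc)
        anns.extend(doc_anns)
    for json_file in sorted(path.glob("*.json")):
        doc, doc_anns = from_json(json_file.read_text())
        docs.append(doc)
        anns.extend(doc_anns)
    if not docs:
        raise FileNotFoundError(f"no .txt or .json documents under {path}")
    return docs, anns


def write_corpus_dir(
    path: str | Path,
    docs: Iterable[Document],
    anns: Sequence[MentionAnnotation],
    fmt: str = "brat",
) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    by_doc: dict[str, list[MentionAnnotation]] = {}
    for a in anns:
        by_doc.setdefault(a.doc_id, []).append(a)
    for doc in docs:
        doc_anns = by_doc.get(doc.doc_id, [])
        if fmt == "brat":
            txt, ann = write_brat(doc, doc_anns)
            (path / f"{doc.doc_id}.txt").write_text(txt)
            (path / f"{doc.doc_id}.ann").write_text(ann)
        elif fmt == "json":
            (path / f"{doc.doc_id}.json").write_text(to_json(doc, doc_anns))
        else:
            raise ValueError(f"unknown corpus format {fmt!r}")
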