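"""Core document, annotation and token containers.

Offsets are 0-based, half-open character (code point) positions into the
text of one document *part*.  A part is a titled section of a document
(abstract-only documents have a single part); all annotations reference a
part by id so offsets stay stable when parts are concatenated or reordered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator


class MentionClass(str, Enum):
    """Mutation-mention form: standard, semi-standard or natural language."""

    ST = "ST"
    SST = "SST"
    NL = "NL"


@dataclass(frozen=True)
class Token:
    """A tokenizer output unit: surface string plus its span in the part text."""

    surface: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("empty token surface")
        if self.end - self.start != len(self.surface):
            raise ValueError(
                f"token span ({self.start},{self.end}) inconsistent with "
                f"surface {self.surface!r}"
            )


@dataclass(frozen=True)
class MentionAnnotation:
    """A mutation mention: character span + surface + optional class label.

    ``source`` records provenance: ``"gold"`` for manual annotations or
    ``"predicted:<method>"`` for tagger output.
    """

    doc_id: str
    part_id: str
    start: int
    end: int
    surface: str
    mention_class: MentionClass | None = None
    source: str = "gold"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span ({self.start},{self.end})")

    def validate_against(self, text: str) -> None:
        """Check the span lies inside ``text`` and slices to ``surface``."""
        if self.end > len(text):
            raise ValueError(
                f"{self.doc_id}/{self.part_id}: span ({self.start},{self.end}) "
                f"outside text of length {len(text)}"
            )
        sliced = text[self.start : self.end]
        if sliced != self.surface:
            raise ValueError(
                f"{self.doc_id}/{self.part_id}: surface {self.surface!r} does "
                f"not equal text slice {sliced!r} at ({self.start},{self.end})"
            )

    def with_class(self, mention_class: MentionClass) -> "MentionAnnotation":
        return replace(self, mention_class=mention_class)


@dataclass
class Document:
    """A document as an ordered list of (part_id, text) sections."""

    doc_id: str
    parts: list[tuple[str, str]] = field(default_factory=list)
    is_full_text: bool = False

    def __post_init__(self) -> None:
        for part_id, text in self.parts:
            if not text:
                raise ValueError(f"{self.doc_id}: empty text for part {part_id!r}")

    def part_text(self, part_id: str) -> str:
        for pid, text in self.parts:
            if pid == part_id:
                return text
        raise KeyError(f"{self.doc_id}: no part {part_id!r}")

    def iter_parts(self) -> Iterator[tuple[str, str]]:
        return iter(self.parts)

    @property
    def text(self) -> str:
        """All part texts joined by single newlines (display only)."""
        return "\n".join(text for _, text in self.parts)


def validate_annotations(doc: Document, anns: Iterable[MentionAnnotation]) -> None:
    """Raise if any annotation violates the span/surface invariants on ``doc``."""
    for ann in anns:
        if ann.doc_id != doc.doc_id:
            raise ValueError(f"annotation doc_id {ann.doc_id!r} != {doc.doc_id!r}")
        ann.validate_against(doc.part_text(ann.part_id))
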