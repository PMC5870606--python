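"""Character-offset-preserving tokenizer for mutation-mention text.

Follows the tmVar-style segmentation used for variant NER: whitespace
separates tokens; every punctuation or symbol character is its own token;
splits are inserted at letter<->digit boundaries and at lowercase->uppercase
case changes ("delPhe" -> "del" + "Phe").  The one deliberate deviation from
the plain rule set: a case change is NOT split when it would break the
leading word of a sentence ("The" stays "The").  Greek letters and symbols
(Δ, >) count as symbols, i.e. single-character tokens, which the nomenclature
of large-scale variants ("TP73Δex2/3") and substitutions ("76A>T") requires.

Offsets count Unicode code points, 0-based and half-open.
"""

from __future__ import annotations

import re

from .types import Token

_SENT_BOUNDARY = re.compile(r"[.!?]+[\s]+(?=[^\sa-z])")
_WORD = re.compile(r"\S+")


def detect_sentence_starts(text: str) -> set[int]:
    """Offsets of the first non-space character of each sentence.

    A sentence starts at the first non-space character of the text, and
    after any run of ``.``/``!``/``?`` followed by whitespace and a
    non-lowercase character.  Deterministic and rule-based by design.
    """
    starts: set[int] = set()
    first = _WORD.search(text)
    if first is None:
        return starts
    starts.add(first.start())
    for m in _SENT_BOUNDARY.finditer(text):
        starts.add(m.end())
    return starts


def _is_letter(c: str) -> bool:
    return c.isalpha() and (("a" <= c.lower() <= "z"))


def _char_class(c: str) -> str:
    if c.isdigit():
        return "digit"
    if _is_letter(c):
        return "upper" if c.isupper() else "lower"
    return "symbol"  # incl. Greek letters, arrows, punctuation


def tokenize(text: str) -> list[Token]:
    """Segment ``text`` into offset-annotated tokens (empty text -> [])."""
    sentence_starts = detect_sentence_starts(text)
    tokens: list[Token] = []
    for word in _WORD.finditer(text):
        w, base = word.group(), word.start()
        run_start = 0
        word_split = False  # any split seen within this word so far
        for i in range(1, len(w) + 1):
            if i == len(w):
                split = True
            else:
                prev, cur = _char_class(w[i - 1]), _char_class(w[i])
                if prev == "symbol" or cur == "symbol":
                    split = True  # symbols are single-character tokens
                elif (prev == "digit") != (cur == "digit"):
                    split = True  # letter<->digit boundary
                elif prev == "lower" and cur == "upper":
                    # case-change split, suppressed in the leading run of a
                    # sentence-initial word ("The" not "T"+"he")
                    split = not (base in sentence_starts and not word_split)
                else:
                    split = False
            if split and i < len(w):
                word_split = True
            if split:
                tokens.append(Token(w[run_start:i], base + run_start, base + i))
                run_start = i
    return tokens


def token_surfaces(text: str) -> list[str]:
    return [t.surface for t in tokenize(text)]
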