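"""Deterministic ST / SST / NL classification of mutation-mention strings.

The classifier is an ordered if-else chain over a candidate mention:

1. if the (trimmed) mention fully matches any named ST regex -> **ST**;
2. else if it has >= 5 words, or contains >= 2 English-dictionary words
   -> **NL**;
3. else if it contains exactly 1 English-dictionary word -> **SST**;
4. else -> **ST**.

A "word" is a whitespace-delimited chunk containing at least one
alphabetic character, so positions and arrows ("18", "–>") do not inflate
the word count of semi-standard fragments.  The regex inventory and the
dictionary are plain-text package data and can be replaced by the user.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

from .types import MentionClass

_HAS_ALPHA = re.compile(r"[^\W\d_]")
_DICT_CHUNK = re.compile(r"[A-Za-z0-9]+")


def load_st_patterns(text: str | None = None) -> list[tuple[str, re.Pattern]]:
    """Load the named ST pattern inventory (package default if no text given)."""
    if text is None:
        text = (
            resources.files("mutmention.data").joinpath("st_patterns.tsv").read_text()
        )
    patterns: list[tuple[str, re.Pattern]] = []
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        name, _, pattern = line.partition("\t")
        if not pattern:
            raise ValueError(f"malformed pattern line (need name<TAB>regex): {line!r}")
        patterns.append((name.strip(), re.compile(pattern.strip())))
    return patterns


def load_dictionary(text: str | None = None) -> frozenset[str]:
    """Load the lowercase English word list (package default if no text given)."""
    if text is None:
        text = (
            resources.files("mutmention.data")
            .joinpath("english_words.txt")
            .read_text()
        )
    words = {
        w.strip().lower()
        for w in text.splitlines()
        if w.strip() and not w.startswith("#")
    }
    return frozenset(words)


@dataclass
class ClassifierConfig:
    st_regexes: list[tuple[str, re.Pattern]] = field(default_factory=load_st_patterns)
    dictionary: frozenset[str] = field(default_factory=load_dictionary)
    nl_word_threshold: int = 5
    nl_dict_threshold: int = 2
    sst_dict_threshold: int = 1

    def __post_init__(self) -> None:
        if min(self.nl_word_threshold, self.nl_dict_threshold,
               self.sst_dict_threshold) <= 0:
            raise ValueError("thresholds must be positive")
        if not self.dictionary:
            raise ValueError("dictionary must be non-empty")


_DEFAULT_CONFIG: ClassifierConfig | None = None


def default_config() -> ClassifierConfig:
    global _DEFAULT_CONFIG
    if _DEFAULT_CONFIG is None:
        _DEFAULT_CONFIG = ClassifierConfig()
    return _DEFAULT_CONFIG


def count_words(mention: str) -> int:
    """Number of whitespace-delimited chunks containing >=1 letter."""
    return sum(1 for chunk in mention.split() if _HAS_ALPHA.search(chunk))


def count_dictionary_words(mention: str, dictionary: frozenset[str]) -> int:
    """Count alphanumeric chunks whose lowercase form is a dictionary word."""
    return sum(
        1 for chunk in _DICT_CHUNK.findall(mention) if chunk.lower() in dictionary
    )


def matches_st_regex(mention: str, config: ClassifierConfig | None = None) -> str | None:
    """Name of the first ST pattern fully matching the trimmed mention, or None."""
    config = config or default_config()
    trimmed = mention.strip()
    for name, pattern in config.st_regexes:
        if pattern.fullmatch(trimmed):
            return name
    return None


def classify(mention: str, config: ClassifierConfig | None = None) -> MentionClass:
    """Classify a mention string into ST, SST or NL (ordered if-else chain)."""
    if not mention or not mention.strip():
        raise ValueError("cannot classify an empty mention")
    config = config or default_config()
    if matches_st_regex(mention, config) is not None:
        return MentionClass.ST
    n_dict = count_dictionary_words(mention, config.dictionary)
    if count_words(mention) >= config.nl_word_threshold or n_dict >= config.nl_dict_threshold:
        return MentionClass.NL
    if n_dict >= config.sst_dict_threshold:
        return MentionClass.SST
    return MentionClass.ST
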