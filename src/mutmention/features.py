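"""Per-token CRF feature extraction.

Handcrafted feature families, emitted for the token at hand and for each
neighbor within a configurable context window (neighbor features carry the
relative offset in their name): Porter stem, word-shape pattern
(uppercase -> ``A``, lowercase -> ``a``, digit -> ``0``, anything else kept),
prefix/suffix characters, a has-digit flag, and membership flags for term
dictionaries (amino acids, nucleotides, mutation-type words).  When a word
embedding model is supplied, the token's vector becomes real-valued
features named ``word_embedding[i]``, matching the tagger's feature-file
convention (e.g. ``word_embedding[0]=0.00492302``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .embeddings import EmbeddingModel, normalize_for_embedding
from .stem import porter_stem
from .types import Token

AMINO_ACIDS_3 = frozenset(
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp Tyr Val".split()
)
AMINO_ACIDS_FULL = frozenset(
    (
        "alanine arginine asparagine aspartate cysteine glutamine glutamate "
        "glycine histidine isoleucine leucine lysine methionine phenylalanine "
        "proline serine threonine tryptophan tyrosine valine "
        "aspartic glutamic"
    ).split()
)
NUCLEOTIDES = frozenset("adenine cytosine guanine thymine uracil".split())
MUTATION_WORDS = frozenset(
    (
        "mutation mutations mutant mutated substitution substituted deletion "
        "deleted insertion inserted duplication duplicated inversion variant "
        "variants polymorphism replaced replacement codon residue residues "
        "position frameshift translocation transition transversion missense "
        "nonsense truncation"
    ).split()
)


def default_dictionaries() -> dict[str, frozenset[str]]:
    return {
        "aa3": AMINO_ACIDS_3,
        "aa_full": AMINO_ACIDS_FULL,
        "nucleotide": NUCLEOTIDES,
        "mut_word": MUTATION_WORDS,
    }


@dataclass
class FeatureConfig:
    context_window: int = 2
    affix_lengths: tuple[int, ...] = (1, 2, 3)
    dictionaries: dict[str, frozenset[str]] = field(
        default_factory=default_dictionaries
    )
    use_embeddings: bool = True

    def __post_init__(self) -> None:
        if self.context_window < 0:
            raise ValueError("context_window must be >= 0")


def word_shape(surface: str) -> str:
    """Uppercase -> A, lowercase -> a, digit -> 0, anything else kept.

    Only Latin letters are abstracted; Greek letters and symbols stay
    themselves — the shape of "TP73Δex2/3" should keep its Δ.
    """
    out = []
    for c in surface:
        if c.isascii() and c.isupper():
            out.append("A")
        elif c.isascii() and c.islower():
            out.append("a")
        elif c.isdigit():
            out.append("0")
        else:
            out.append(c)
    return "".join(out)


def _collapse(shape: str) -> str:
    out = []
    for c in shape:
        if not out or out[-1] != c:
            out.append(c)
    return "".join(out)


def embedding_features(
    surface: str, model: "EmbeddingModel"
) -> dict[str, float]:
    """Real-valued ``word_embedding[i]`` features; empty for OOV tokens."""
    vec = model.lookup(normalize_for_embedding(surface))
    if vec is None:
        return {}
    return {f"word_embedding[{i}]": float(v) for i, v in enumerate(vec)}


def _single_token_features(
    surface: str, prefix: str, config: FeatureConfig
) -> dict[str, float]:
    feats: dict[str, float] = {
        f"{prefix}stem={porter_stem(surface)}": 1.0,
        f"{prefix}shape={word_shape(surface)}": 1.0,
        f"{prefix}shape_short={_collapse(word_shape(surface))}": 1.0,
    }
    for k in config.affix_lengths:
        if len(surface) >= k:
            feats[f"{prefix}prefix{k}={surface[:k]}"] = 1.0
            feats[f"{prefix}suffix{k}={surface[-k:]}"] = 1.0
    if any(c.isdigit() for c in surface):
        feats[f"{prefix}has_digit"] = 1.0
    if not any(c.isalnum() for c in surface):
        feats[f"{prefix}is_symbol"] = 1.0
    low = surface.lower()
    for name, words in config.dictionaries.items():
        if surface in words or low in words:
            feats[f"{prefix}dict:{name}"] = 1.0
    return feats


def token_features(
    tokens: Sequence[Token],
    index: int,
    config: FeatureConfig | None = None,
    embedding_model: "EmbeddingModel | None" = None,
) -> dict[str, float]:
    """Named feature map for ``tokens[index]`` (pure function of its inputs)."""
    config = config or FeatureConfig()
    if not 0 <= index < len(tokens):
        raise IndexError(index)
    feats: dict[str, float] = {"bias": 1.0}
    for d in range(-config.context_window, config.context_window + 1):
        j = index + d
        if not 0 <= j < len(tokens):
            continue
        prefix = "" if d == 0 else f"{d:+d}:"
        feats.update(_single_token_features(tokens[j].surface, prefix, config))
    if index == 0:
        feats["bos"] = 1.0
    if index == len(tokens) - 1:
        feats["eos"] = 1.0
    if config.use_embeddings and embedding_model is not None:
        feats.update(embedding_features(tokens[index].surface, embedding_model))
    return feats


def sequence_features(
    tokens: Sequence[Token],
    config: FeatureConfig | None = None,
    embedding_model: "EmbeddingModel | None" = None,
) -> list[dict[str, float]]:
    config = config or FeatureConfig()
    return [
        token_features(tokens, i, config, embedding_model)
        for i in range(len(tokens))
    ]
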