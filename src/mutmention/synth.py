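"""Seeded generator of synthetic abstracts with gold mutation mentions.

Emulates the statistical shape of mutation-mention corpora: a configurable
ST/SST/NL class mix (default 52/8/40, the shape of an NL-enriched abstract
corpus), a configurable share of mention-free documents (default 9%) so
precision is probed on genuinely negative text, and mention surfaces drawn
from a template bank whose instantiations are *validated against the
classifier* — a template whose rendering does not classify into its target
class is rejected at load time.  Filler sentences come from a neutral
biomedical phrase bank with no mutation-like strings.

This is test scaffolding, not a linguistic model: positions and residues
are sampled uniformly from bounded ranges, and documents are flat
single-part abstracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classify import ClassifierConfig, classify
from .types import Document, MentionAnnotation, MentionClass, validate_annotations

AA1 = list("ARNDCQEGHILKMFPSTWYV")
AA3 = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr "
    "Trp Tyr Val".split()
)
AA_FULL = (
    "alanine arginine asparagine aspartate cysteine glutamine glutamate "
    "glycine histidine isoleucine leucine lysine methionine phenylalanine "
    "proline serine threonine tryptophan tyrosine valine".split()
)
NT = list("ACGT")
CODONS = "TAC TAT TGG CGA GCT ATC CCG GAC".split()
SUB_VERBS = "substituted replaced exchanged converted mutated changed".split()


@dataclass(frozen=True)
class MentionTemplate:
    pattern: str
    target_class: MentionClass
    w_word: bool = True
    l_letter: bool = True
    p_position: str = "exact"  # exact | vague | none

    def __post_init__(self) -> None:
        ok = (self.w_word and self.l_letter and self.p_position in ("exact", "vague")) or (
            self.w_word and not self.l_letter and self.p_position == "exact"
        )
        if not ok:
            raise ValueError(
                f"template {self.pattern!r}: W/L/P combination not annotatable"
            )

    def render(self, rng: np.random.Generator) -> str:
        i, j = rng.choice(len(AA1), size=2, replace=False)
        k, l = rng.choice(4, size=2, replace=False)
        pos = int(rng.integers(1, 2001))
        slots = {
            "aa1": AA1[i], "aa1b": AA1[j],
            "aa3": AA3[i], "aa3b": AA3[j],
            "aaf": AA_FULL[i], "aafb": AA_FULL[j],
            "nt": NT[k],
            "ntb": NT[l],
            "ntlow": NT[rng.integers(0, 4)].lower(),
            "ntlowb": NT[rng.integers(0, 4)].lower(),
            "cod": CODONS[rng.integers(0, len(CODONS))],
            "codb": CODONS[rng.integers(0, len(CODONS))],
            "pos": pos, "pos2": pos + 1,
            "num": int(rng.integers(10000, 999999)),
            "chr": int(rng.integers(1, 23)),
            "d": int(rng.integers(2, 46)),
            "d2": int(rng.integers(1, 30)),
            "verb": SUB_VERBS[rng.integers(0, len(SUB_VERBS))],
        }
        return self.pattern.format(**slots)


_ST_TEMPLATES = [
    "{aa1}{pos}{aa1b}",
    "{aa3}{pos}{aa3b}",
    "c.{pos}{nt}>{ntb}",
    "g.{pos}{nt}>{ntb}",
    "c.{pos}del{nt}",
    "c.{pos}_{pos2}ins{nt}",
    "c.{pos}dup{nt}",
    "p.{aa3}{pos}{aa3b}",
    "rs{num}",
    "{pos}{nt}>{ntb}",
    "D{chr}S{num}",
    "IVS{d2}(+{d})",
    "{aa1}{pos}fs",
]
# (pattern, l_letter, p_position)
_SST_TEMPLATES = [
    ("{aa3} {pos} to {aa3b}", True, "exact"),
    ("{aaf} for {aafb} {pos}", True, "exact"),
    ("codon {pos}, {cod}–>{codb}", True, "exact"),
    ("{aa1}{pos} to {aa1b}", True, "exact"),
    ("{pos}-{d2}{ntlow}–>{ntlowb} mutation", True, "exact"),
    ("{aaf} to {aafb} {pos}", True, "exact"),
]
_NL_TEMPLATES = [
    ("{aaf} was {verb} by {aafb} at residue {pos}", True, "exact"),
    ("{aaf} to {aafb} substitution at codon {pos}", True, "exact"),
    ("substitution of {aaf} by {aafb} at position {pos}", True, "exact"),
    ("deletion of {d} residues from the amino terminus", False, "exact"),
    ("insertion of {d} nucleotides in exon {d2}", False, "exact"),
    ("in-frame deletion of {aaf} at position {pos}", True, "exact"),
    ("a {d}-bp deletion in exon {d2}", False, "exact"),
    ("the {aaf} residue at position {pos} was {verb} with {aafb}", True, "exact"),
    ("point mutation at amino acid {pos}", False, "exact"),
    ("{aaf} {pos} was {verb} to {aafb}", True, "exact"),
    ("removal of the last {d} residues of the protein", False, "exact"),
    ("duplication of {d} base pairs in exon {d2}", False, "exact"),
]

_CARRIERS = [
    "Sequencing revealed {m} in two unrelated patients.",
    "We identified {m} in the proband.",
    "The causal variant was {m} in this family.",
    "Functional assays showed that {m} reduced enzyme activity.",
    "Analysis confirmed {m} in all affected individuals.",
    "Genetic screening uncovered {m} among the carriers.",
]
_FILLERS = [
    "The protein localized to the nucleus under stress conditions.",
    "Samples were collected after informed consent.",
    "Expression levels were measured by quantitative PCR.",
    "The cohort comprised forty individuals from twelve families.",
    "Structural modeling suggested a destabilized hydrophobic core.",
    "Enzyme activity was assayed at physiological temperature.",
    "These findings broaden the phenotypic spectrum of the disorder.",
    "Cells were cultured in standard growth medium.",
]


def template_bank(
    classifier_config: ClassifierConfig | None = None,
    validation_draws: int = 10,
    seed: int = 12345,
) -> list[MentionTemplate]:
    """All mention templates, validated against the mention classifier.

    Every template is instantiated ``validation_draws`` times; if any
    rendering does not classify into the template's target class the bank
    raises with a diagnostic naming the template.
    """
    bank = (
        [MentionTemplate(p, MentionClass.ST) for p in _ST_TEMPLATES]
        + [
            MentionTemplate(p, MentionClass.SST, l_letter=l, p_position=pp)
            for p, l, pp in _SST_TEMPLATES
        ]
        + [
            MentionTemplate(p, MentionClass.NL, l_letter=l, p_position=pp)
            for p, l, pp in _NL_TEMPLATES
        ]
    )
    rng = np.random.default_rng(seed)
    for tpl in bank:
        for _ in range(validation_draws):
            surface = tpl.render(rng)
            got = classify(surface, classifier_config)
            if got != tpl.target_class:
                raise ValueError(
                    f"template {tpl.pattern!r} rendered {surface!r} which "
                    f"classifies as {got.value}, expected {tpl.target_class.value}"
                )
    return bank


@dataclass
class SynthConfig:
    n_documents: int = 100
    class_mix: tuple[float, float, float] = (0.52, 0.08, 0.40)  # ST, SST, NL
    mentions_per_doc: tuple[int, int] = (1, 3)  # inclusive range
    fraction_empty_docs: float = 0.09
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        if not 0 <= self.fraction_empty_docs < 1:
            raise ValueError("fraction_empty_docs must be in [0, 1)")
        if self.n_documents < 1:
            raise ValueError("need at least one document")


def generate_corpus(
    config: SynthConfig | None = None,
    classifier_config: ClassifierConfig | None = None,
) -> tuple[list[Document], list[MentionAnnotation]]:
    """Deterministic synthetic corpus with exact gold offsets."""
    config = config or SynthConfig()
    bank = template_bank(classifier_config)
    by_class = {
        cls: [t for t in bank if t.target_class is cls] for cls in MentionClass
    }
    rng = np.random.default_rng(config.seed)
    n_empty = round(config.fraction_empty_docs * config.n_documents)
    empty_ids = set(
        rng.permutation(config.n_documents)[:n_empty].tolist()
    )
    class_order = [MentionClass.ST, MentionClass.SST, MentionClass.NL]
    docs: list[Document] = []
    gold: list[MentionAnnotation] = []
    for i in range(config.n_documents):
        doc_id = f"synth-{i:04d}"
        sentences: list[tuple[str, MentionTemplate | None, str | None]] = []
        if i not in empty_ids:
            lo, hi = config.mentions_per_doc
            n_mentions = int(rng.integers(lo, hi + 1))
            for _ in range(n_mentions):
                cls = class_order[
                    rng.choice(3, p=np.asarray(config.class_mix))
                ]
                tpl = by_class[cls][rng.integers(0, len(by_class[cls]))]
                carrier = _CARRIERS[rng.integers(0, len(_CARRIERS))]
                sentences.append((carrier, tpl, tpl.render(rng)))
        n_filler = int(rng.integers(2, 5))
        for _ in range(n_filler):
            sentences.append((_FILLERS[rng.integers(0, len(_FILLERS))], None, None))
        perm = rng.permutation(len(sentences))
        text_parts: list[str] = []
        offset = 0
        doc_gold: list[MentionAnnotation] = []
        for k in perm:
            carrier, tpl, surface = sentences[k]
            if tpl is None:
                rendered = carrier
            else:
                slot = carrier.index("{m}")
                rendered = carrier.replace("{m}", surface)
                start = offset + slot
                doc_gold.append(
                    MentionAnnotation(
                        doc_id=doc_id, part_id="s1", start=start,
                        end=start + len(surface), surface=surface,
                        mention_class=tpl.target_class,
                    )
                )
            text_parts.append(rendered)
            offset += len(rendered) + 1  # joining space
        doc = Document(doc_id=doc_id, parts=[("s1", " ".join(text_parts))])
        validate_annotations(doc, doc_gold)
        docs.append(doc)
        gold.extend(doc_gold)
    return docs, gold


def perturb_for_boundary_tests(
    document: Document, gold: Sequence[MentionAnnotation]
) -> tuple[Document, list[MentionAnnotation]]:
    """Append a sign-prefixed variant and a bracketed-context NL mention.

    Exercises the boundary-fixing post-processor (gold covers the ``+`` of
    ``+1858C > T``) and partial matching (gold covers the unbracketed core
    of ``[changed conserved] glutamine at 115 to proline``).
    """
    part_id, text = document.parts[-1]
    s1 = "The +1858C > T variant was genotyped."
    m1 = "+1858C > T"
    s2 = "It [changed conserved] glutamine at 115 to proline."
    m2 = "glutamine at 115 to proline"
    new_text = f"{text} {s1} {s2}"
    base1 = len(text) + 1
    base2 = base1 + len(s1) + 1
    new_gold = list(gold) + [
        MentionAnnotation(
            doc_id=document.doc_id, part_id=part_id,
            start=base1 + s1.index(m1), end=base1 + s1.index(m1) + len(m1),
            surface=m1, mention_class=MentionClass.ST,
        ),
        MentionAnnotation(
            doc_id=document.doc_id, part_id=part_id,
            start=base2 + s2.index(m2), end=base2 + s2.index(m2) + len(m2),
            surface=m2, mention_class=MentionClass.NL,
        ),
    ]
    new_doc = Document(
        doc_id=document.doc_id,
        parts=document.parts[:-1] + [(part_id, new_text)],
        is_full_text=document.is_full_text,
    )
    validate_annotations(new_doc, new_gold)
    return new_doc, new_gold
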