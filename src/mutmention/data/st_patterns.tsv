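# Named regular expressions recognizing standard (ST) mutation mentions.
# One pattern per line: name<TAB>regex.  Patterns are anchored (fullmatch
# against the whitespace-trimmed mention) so that ST-like substrings inside
# longer descriptive phrases do not pre-empt the word-count branches.
# Covers one-letter and three-letter substitutions, HGVS coding/genomic
# edits, frameshifts, rsids, genetic markers, IVS notation and large-scale
# deletions; editable and extensible by users.
sav_one_letter	[A-Z][0-9]+[A-Z]
sav_three_letter	(?:Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|Tyr|Val)[0-9]+(?:Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|Tyr|Val)
protein_sub_spaced	(?:Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|Tyr|Val)\s*[0-9]+\s*(?:Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|Tyr|Val)
frameshift	(?:Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|Tyr|Val|[A-Z])[0-9]+fs(?:ins|del)?(?:[A-Z*][0-9]*)?
nt_substitution	[+\-−]?[0-9]+\s*[ACGTUacgtu]\s*(?:>|→|-+>|–>)\s*[ACGTUacgtu]
hgvs_dna	[cgmnr]\.\s*[0-9_+*\-− ]*[0-9]\s*(?:[ACGTUacgtu]\s*(?:>|→|-+>|–>)\s*[ACGTUacgtu]|del[ACGTUacgtu0-9]*|ins[ACGTUacgtu0-9]+|dup[ACGTUacgtu0-9]*|inv[0-9]*)
hgvs_protein	p\.\s*\(?\s*(?:Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|Tyr|Val|[A-Z])\s*[0-9]+\s*(?:Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|Tyr|Val|fs\*?[0-9]*|del|dup|ins[A-Za-z]*|[A-Z])\s*\)?
protein_pos_first	p\.\s*[0-9]+\s*[A-Z]\s*(?:>|→|-+>|–>)\s*[A-Z]
rsid	rs[0-9]+
genetic_marker	D[0-9]{1,2}S[0-9]+
del_ins_named	(?:del|delta|Δ|ins|dup)\s*(?:Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|Tyr|Val|[ACGTUacgtu]+)\s*[0-9]+
ivs	IVS\s*[0-9]+[0-9\s:()+\-−….,/delinsACGTUacgtu]*
large_scale_delta	\S+\s*Δ\s*(?:exons?|ex)?\s*[0-9/\-−]+
knockout	Δ/Δ
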