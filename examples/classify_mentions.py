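"""Classify mutation-mention strings into ST / SST / NL.

The classifier is an ordered if-else chain: standard-nomenclature regexes
first (ST), then word counts against an English dictionary (NL if >= 5
words or >= 2 dictionary words, SST if exactly 1, ST otherwise).
"""

from mutmention import classify

mentions = [
    "E6V",                                                   # one-letter SAV
    "c.76delA",                                              # HGVS coding deletion
    "rs206437",                                              # dbSNP identifier
    "Gly 18 to Lys",                                         # semi-standard
    "codon 92, TAC–>TAT",                                    # semi-standard
    "glutamic acid was substituted by valine at residue 6",  # natural language
    "deletion of 10 and 8 residues from the N- and C-terminals",
]

for mention in mentions:
    print(f"{classify(mention).value:4s} {mention}")

# ST rows fully match a standard-nomenclature pattern; SST rows contain
# exactly one descriptive English word; NL rows read as prose.
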