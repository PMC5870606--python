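# High-recall regexes (case-insensitive, searched anywhere in a document)
# flagging text likely to contain non-standard (NL/SST) mutation mentions.
# Used to pre-select documents for annotation; precision is deliberately
# sacrificed for recall.
substitut
replac(?:ed|ement|ing)\s+(?:by|with|of)?
(?:deletion|insertion|duplication|inversion|removal)\s+of
was\s+(?:substituted|replaced|deleted|inserted|mutated|changed|exchanged)
(?:to|into|for)\s+(?:alanine|arginine|asparagine|aspartate|cysteine|glutamine|glutamate|glycine|histidine|isoleucine|leucine|lysine|methionine|phenylalanine|proline|serine|threonine|tryptophan|tyrosine|valine)
(?:alanine|arginine|asparagine|aspartate|cysteine|glutamine|glutamate|glycine|histidine|isoleucine|leucine|lysine|methionine|phenylalanine|proline|serine|threonine|tryptophan|tyrosine|valine)\s+(?:at|to|for|was|residue)
at\s+(?:residue|codon|position|amino\s+acid)s?\s+[0-9]
truncat
frameshift
loss\s+of\s+(?:exon|chromosome|the)
in-?frame\s+(?:deletion|insertion)
[0-9]+\s*-?\s*bp\s+(?:deletion|insertion|duplication)
codon\s+[0-9]+
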