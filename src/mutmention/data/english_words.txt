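# Curated lowercase English word list used to detect descriptive natural
# language inside candidate mutation mentions.  Deliberately excluded:
# single letters, amino-acid three-letter codes (Gly, Lys, ...) and full
# amino-acid names (glycine, ...), nucleotide triplets, and the preposition
# "of", all of which occur routinely inside standard/semi-standard variant
# nomenclature fragments and would otherwise mimic descriptive English.
# One word per line; lines starting with '#' are comments.
about
above
acid
acids
across
addition
additional
affect
affected
affecting
affects
after
all
also
alter
alteration
alterations
altered
amino
analysis
any
are
associated
base
bases
because
been
before
begin
beginning
between
both
boundary
but
can
carboxyl
carrier
carrying
cause
caused
causes
causing
cell
cells
change
changed
changes
changing
chromosomal
chromosome
chromosomes
codon
codons
common
complete
conserved
contain
contained
containing
contains
copy
corresponding
could
damage
decrease
decreased
deleted
deleterious
deletion
deletions
described
detected
detection
did
different
disease
disrupted
disruption
distal
domain
downstream
duplicated
duplication
duplications
during
each
early
effect
effects
eight
either
end
ends
entire
exchange
exchanged
exon
exons
expressed
expression
family
few
first
five
following
found
four
frame
frameshift
from
function
functional
gene
genes
genetic
genome
genomic
has
have
identified
identify
immediately
important
increase
increased
individual
individuals
inframe
inserted
insertion
insertions
into
intron
introns
inversion
its
known
lack
lacking
large
last
late
leading
lead
leads
length
level
levels
located
location
locus
loss
lost
made
majority
many
mapped
mapping
marker
markers
may
missense
missing
more
most
mutant
mutants
mutated
mutation
mutational
mutations
near
new
nine
nonsense
normal
novel
nucleotide
nucleotides
number
observed
occur
occurred
occurring
occurs
one
only
other
our
over
pair
pairs
partial
patient
patients
point
polymorphism
polymorphisms
position
positions
predicted
presence
present
promoter
protein
proteins
proximal
reduced
reduction
region
regions
removal
removed
removing
repeat
repeats
replace
replaced
replacement
replaces
replacing
report
reported
residue
residues
result
resulted
resulting
results
same
second
segment
sequence
sequences
seven
several
severe
shift
shifted
short
show
showed
shown
single
site
sites
six
small
some
somatic
splice
splicing
start
stop
strand
structural
study
substituted
substituting
substitution
substitutions
such
ten
terminal
terminals
termination
terminus
than
that
the
their
there
these
this
three
through
transition
translocation
transversion
truncated
truncating
truncation
two
type
types
upstream
variant
variants
variation
variations
very
was
were
when
where
which
while
whole
will
within
without
and
are
all
also
any
at
but
by
can
did
each
few
for
had
has
have
how
into
its
may
more
most
new
not
now
one
only
our
out
over
some
such
ten
than
that
the
their
them
then
there
they
this
those
three
through
to
too
two
under
very
was
were
what
when
where
which
while
who
will
with
you
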