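# Methods

## Coordinate and record conventions

Features use 1-based, fully inclusive coordinates (a tRNA annotated `1..69`
is 69 bp), matching the convention of published mitogenome organization
tables. Records are circular: the junction between the last listed feature
and the first is a real adjacency and participates in gap/overlap totals
(in the bundled pteromalid fixtures this wrap adjacency happens to be 0 bp,
so totals are unaffected, but the contract is explicit). The AT-rich control
region is modelled as a regular feature (`CR`) so gene-order analyses can
use it as a positional marker. A "complete" record carries all 37 genes plus
`CR`; partial records load fine and are simply not complete.

GenBank labels are mapped onto the canonical vocabulary
(atp6/atp8, cox1–3, cytb, nad1–6/nad4l, rrnS/rrnL, trnA…trnV, CR) through an
editable alias table. The duplicated leucine and serine tRNAs are
disambiguated by anticodon following the universal mitochondrial convention
(L(UUR)→trnL2/taa, L(CUN)→trnL1/tag, S(UCN)→trnS2/tga, S(AGN)→trnS1/gct);
published organization tables rarely state this basis, so the mapping is
isolated in one table rather than hard-wired. Unmappable features are
skipped with a warning and recorded on the parsed record, so partial or
oddly annotated deposits still load.

## Composition and skew

AT skew = (A − T)/(A + T) and GC skew = (G − C)/(G + C) are computed from raw
counts and reported to three decimals; percentages to one decimal (the
precision at which such tables are conventionally printed). `N` bases are
excluded from denominators. Per-region rows concatenate feature spans *as
they lie on the reference strand*, without reverse complementing: the
statistics then describe the molecule's majority-strand content and the
regional rows are consistent with the full-genome row. A skew whose
denominator is zero is NaN, never silently 0.

Intergenic lengths use IGN(next, prev) = start(next) − end(prev) − 1, so
touching genes score 0 and a shared base scores −1. This convention
reproduces every intergenic value printed in the source organization tables.
When no feature is nested inside another, the circular IGN values satisfy
exact bp conservation: Σ IGN = genome length − Σ feature sizes. One caveat
inherited from the source data: the *N. vitripennis* coordinates sum to
95 bp of gaps while the accompanying text reports 94 bp; the
coordinate-derived value is what this package computes, and that single
printed total is not used as a test oracle.

## Codon-level analyses

The genetic code defaults to NCBI translation table 5 (invertebrate
mitochondrial: AGA/AGG = Ser, ATA = Met, TGA = Trp; stops TAA/TAG), taken
from Biopython and configurable. CDS extraction reverse complements
minus-strand features, frames from the annotated start, and classifies the
stop from the out-of-frame remainder: 0 bp → the final triplet must be
TAA/TAG, 1 bp → `T-`, 2 bp → `TA-` (incomplete stops completed to TAA by
post-transcriptional polyadenylation). Internal stops warn rather than fail,
since they usually indicate an annotation slip the user should see, not a
fatal state.

RSCU is computed per synonymous family as observed count divided by the
uniform expectation; whole-proteome usage concatenates the 13 PCGs with
terminal (complete or incomplete) stop codons excluded and start codons
included. The exact convention behind published RSCU figures is rarely
stated; this one is documented here and applied consistently.

Ka/Ks implements the Nei–Gojobori (1986) estimator. Site counts per codon
sum, over the three positions, the synonymous fraction of single-nucleotide
changes with stop-codon neighbours excluded from the denominator. Observed
differences for a codon pair differing at k positions are averaged over all
k! mutational pathways with equal weight; pathways through stop codons are
excluded (under table 5 no sense-codon pair has *all* pathways blocked, but
a counting fallback exists for other codes). The proportions pS, pN are
corrected with the Jukes–Cantor transform d = −(3/4)·ln(1 − (4/3)·p);
p ≥ 3/4 (saturation) and Ks = 0 are flagged as NaN rather than inventing a
number. The published per-gene values for the pteromalid genomes require the
deposited sequences (the reference being *Pachyneuron aphidis*), so the test
suite checks the estimator against an independent brute-force enumeration
oracle and against sequences with planted change counts instead of asserting
those figures. Codon alignments are assumed given per gene; alignment itself
is out of scope.

## Gene-order analysis

Orders are signed circular permutations; rotation- and reflection-equivalent
orders compare equal. Breakpoint distance restricts both orders to their
shared gene set, reduces each to its set of *unsigned* unordered circular
adjacency pairs, and counts adjacencies of one absent from the other.
Unsigned adjacencies with the control region included as a marker is the
convention that reproduces the published distances for these genomes
(0 between the two *Muscidifurax*; 5 for *P. vindemmiae* against either
*Muscidifurax* or *N. vitripennis*); a signed convention would score the
isolated *trnN* strand flip between the two arrangements as an extra
breakpoint and give 6. Including or excluding CR changes any distance by at
most 2 (its two adjacencies); for these genomes both conventions agree.

Conserved gene blocks are maximal runs of the (restricted) reference order
whose consecutive unordered adjacencies occur in every order. Because each
gene has exactly two neighbours on a circle, such a run is automatically
contiguous in every genome, either forward or whole-block reversed; reversed
occurrences are flagged per genome (e.g. the *trnE–trnF* block is inverted
in *P. vindemmiae* relative to *Muscidifurax*).

Event classification is a greedy hypothesis search, not a full
common-interval/TDRL scenario enumerator: orders are rotation-aligned to
maximize positional matches, and at the first mismatch the classifier tests
inversion, transposition and reverse-transposition hypotheses (in both
"segment arrives here" and "segment leaves here" forms), applies the
candidate that most increases positional agreement (ties broken by shorter
segment, then kind priority), and repeats up to a bounded number of rounds.
Whatever remains unexplained is reported as a single `tdrl_or_complex`
residue. Replaying the simple events on the source order reproduces the
target exactly, and planted single inversions/transpositions are recovered
100/100 in the seeded generate-and-recover tests. Between the *Muscidifurax*
and *P. vindemmiae* arrangements the classifier reports the *trnR*
relocation as a reverse transposition (the gene changes strand between the
two annotations) plus a single-gene *trnN* inversion and the *trnE–trnF*
inversion; descriptively the *trnR* event is the "transposition" of the
qualitative literature. Minimal-inversion (Hannenhalli–Pevzner) and DCJ
distances are deliberately out of scope.

The putative ancestral insect order (*Drosophila yakuba*-like) ships as a
constant and is the default simulation template.

## Trees

Neighbor joining is the standard Saitou–Nei agglomeration with two pinned-down
details the contracts rely on: ties in the Q criterion break by
lexicographic taxon-pair label (deterministic output), and negative branch
lengths are clamped to 0 with a warning. On additive matrices the generating
topology is recovered (Robinson–Foulds 0 over seeded random 6–10-taxon
trees, checked against dendropy's tree comparison). Sequence-based
phylogenies are inputs (Newick), never inferred here.

Fitch parsimony runs bottom-up with intersection-else-union (+1 change);
polytomies combine children pairwise in child order. The lifestyle coding
treats state 3 ("undefined") as full ambiguity {1, 2} rather than a third
observable state — white-pie taxa in ancestral-state figures are unknowns,
and scoring them as a real state would inflate change counts. Change counts
equal the exhaustive minimum over all internal assignments on random 10-tip
trees. Published tip codings for the full 20-taxon analysis exist only as
figure colours, so root-state conclusions are a function of user-supplied
codings, not a fixed oracle.

## Synthetic data

The generator emulates the architecture of an insect mitogenome: template
gene order and strands (default ancestral), per-type length ranges (tRNA
55–74 bp, rRNAs and control region in observed ranges, per-gene PCG codon
counts spanning atp8 ≈ 53 to nad5 ≈ 560 codons), iid bases at a configurable
AT target (default 0.84, the pteromalid average), protein genes with ATN
starts (TTG as a rare alternative when the composition admits G), internal
stop codons resampled away, and complete or incomplete stops planted at the
annotated rate. Genes are separated by short non-negative spacers, so bp
conservation holds exactly and no synthetic gene is nested or overlapping —
one respect (besides sequence homology, tRNA structure, and any real
substitution process) in which synthetic genomes are simpler than real ones:
passing tests demonstrate correctness of the accounting and estimators under
controlled conditions, not robustness to every annotation pathology.
Internal-stop resampling makes realized AT in coding regions fall ~0.8
percentage points below the nominal target at AT = 0.84; across whole
molecules the mean absolute deviation stays under 1 percentage point, which
the tests assert. All randomness flows through one seeded
`numpy.random.Generator`: fixed seed, byte-identical FASTA and gene table.

`mutate_coding_pair` plants exact numbers of synonymous and nonsynonymous
single-nucleotide changes at distinct codons (never creating stops), giving
Ka/Ks tests a ground truth: with one change per codon, NG86 difference
counts recover the planted numbers exactly.

## Problem sizes and tolerances

All desk-scale results (breakpoint distances, gap/overlap totals, PCG share,
skews from printed percentages) are exact integer/rounded-decimal
recomputations from the bundled fixtures and run in well under a second.
Property-based checks use 1,000 random order pairs for the breakpoint
oracle, 100 seeds per planted event kind, 62² single-codon pairs plus ~200
short random codon pairs for NG86, 20 random trees for NJ recovery and 10
(plus 20 module-level) for Fitch — sizes chosen to keep the full suite
around ten seconds while exercising every code path; enumeration oracles
are exact, so agreement is asserted with no numeric slack beyond float
round-off.
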