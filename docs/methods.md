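# Methods

This note documents the models, conventions and design choices behind
`trypanotag`: what each module computes, the parameters that matter, what
the synthetic fixtures do and do not emulate, and the known limits of the
approach.

## Coordinates, strands and case

All internal coordinates are 0-based, half-open. GFF3 input (1-based,
inclusive) is converted once at the I/O boundary; nothing downstream ever
re-derives genomic coordinates. Every `GeneModel` is strand-normalized:
CDS, upstream flank and downstream flank are reported in coding
orientation, so each design rule ("the last 80 nt of the 5' UTR", "the
first 80 nt of the ORF in reverse complement") is plain left-to-right
string arithmetic on both strands, and a single round-trip invariant
(flank|CDS|flank reassembles the chromosomal slice) covers the strand
logic.

Trypanosomatid UTRs are rarely annotated, so the "UTR" in the primer rules
is operationalized as the genomic flank immediately adjacent to the CDS;
explicit UTR features in the GFF3 are deliberately ignored for arm
extraction, and homology arms always abut the start/stop codon. This
matches the integration diagrams the rules come from, where arms abut the
ORF.

Case is semantic only for display: locus homology is written upper case,
plasmid-annealing and adapter segments lower case (the convention used for
the published primer tables). All comparisons are case-insensitive. N is
tolerated in genomic input but any N inside a designed primer is a hard
error — an oligo containing N cannot be synthesized.

## Plasmid templates

Templates are ordered element lists plus the published annealing strings
(stored byte-identical to their printed form and unit-tested as string
equality). The full plasmid sequences are not published, so built-in
templates carry deterministic synthetic placeholder bodies; every design
quantity depends only on annealing-site positions and element boundaries,
which are faithful, so placeholders change nothing downstream. Templates
loaded from a GenBank-style feature file replace the placeholders when
real sequences are available. Output provenance marks built-ins as
synthetic.

Two conventions worth stating:

* **Orientation.** Annealing strings are stored exactly as they appear on
  the synthesized primer (5'->3'). A "forward" site therefore occurs
  verbatim on the template top strand; a "reverse" site occurs as its
  reverse complement. Each site must occur exactly once, which is asserted
  at construction.
* **Cut-site abstraction.** Digest fragments are reported between
  recognition-site *start* positions. Overhang chemistry does not affect
  any design arithmetic, and the blunt abstraction makes in-silico
  fragments reproducible bit-exactly. Recognition sites are placed so the
  released fragments have the documented composition: SpeI/NcoI on pLENTv2
  releases tag -> intergenic -> resistance; EcoRI/XbaI on pPOTv2 releases
  resistance -> intergenic -> tag (the N-terminal fusion centre), ending at
  the tag's last codon so the downstream ORF reads in frame.

The pPOTv2 tag-annealing forward string is stored at its printed 16 nt
length even though the pPOTv4 linker annealing is 18 nt; the published
table is taken as authoritative per plasmid/strategy cell.

Internal tagging modifies pPOTv4 by replacing the 5' GS-linker element
with the insert (typically the signal-peptide coding sequence, which
brings its own start codon); the replaced linker's annealing role is
disabled because the corresponding primer then follows the internal-tag
rule. The template operation supports replacing either linker, but only
the 5'-side design rule is published, so 3'-side internal *designs* are
rejected with an explicit error rather than guessed.

## Long-primer design

Defaults: homology length 80 nt (the length at which long-primer tagging
is reliable), configurable 50-120 nt with an advisory warning below 80.
Deletion/internal truncation points are CDS nucleotide offsets and must be
codon-aligned (the CLI accepts amino-acid coordinates and converts as
aa i -> nt 3i). For N-terminal tagging the native ATG is retained inside
the arm; the cassette provides its own start codon, and the
post-recombination frame is verified by simulation rather than assumed.

Degeneracies are treated as regression tests of rule consistency: a
C-terminal deletion at the last codon reproduces the C-tag primers, an
N-terminal deletion at codon 0 reproduces the N-tag primers, and swapping
the pPOTv4 tag element never changes the primers (all pPOTv4 annealing
sites lie outside the tag).

A CDS-derived arm containing a frame-0 stop that the fused reading frame
would run through is rejected at design time; with well-formed annotation
this cannot happen, so it surfaces annotation defects early.

## Fusion PCR and cloning

Fusion designs use 500 bp arms (C-terminal: ORF 3' end excluding the stop
codon, plus the downstream flank; N-terminal: upstream flank plus the ORF
5' end) and 30 bp junction adapters equal to the terminal 30 nt of the
central fragment, written so every primer reads 5'->3' as synthesized.
The overlap join demands exact identity over the full adapter — adapters
are designed, not discovered — and an adapter occurring more than once in
the joined molecule is an assembly-ambiguity error.

Round-1 outer primers and nested primers are Tm-driven: candidate lengths
20-30 nt (or insets 20-30 bp) are scored by nearest-neighbor Tm against
the target (default 60 deg C), choosing the minimum |Tm - target| with
ties broken by the smaller length/inset and then lexicographically, so
batch output is deterministic. The original protocol's exact outer-primer
lengths are not published; Tm-driven selection is this package's choice
and is configurable. PCR cycling details (the five primer-less cycles
etc.) are wet-lab protocol and appear only as text, never simulated.

A release-enzyme site inside an arm draws a warning; inside the 30 bp
junction region it is an error, since the junction must survive the digest
clean-up intact.

pLENT cloning arms are 300-500 nt (default 400); the gene-arm forward and
utr-arm reverse primers carry the linearization site, the inner primers
SpeI and HindIII respectively, all with 4 nt of 5' padding for digestion
efficiency. The linearization enzyme is the first registry enzyme (fixed,
documented order) with zero sites in both arms and exactly one in the
predicted assembled plasmid. The assembled-plasmid model contains the arms
plus the vector SpeI..HindIII cassette span closed through the
linearization site; the bacterial backbone is omitted, matching the
tagging-relevant part of the construct (the fusion amplicon equals the
linearized plasmid without the backbone). Only the C-terminal cloning
workflow is implemented: the N-terminal variant is unpublished, and
N-terminal tagging is served by the pPOTv2 fusion route.

## Simulation model

The simulators are strict string machines, by design:

* **PCR** requires an exact match of the primer's 3'-terminal 15 nt
  (configurable) and exactly one binding site per primer; 5' overhangs are
  incorporated into the product. A single 3' mismatch yields no product.
* **Fusion** joins fragments whose terminal overlaps (>= 20 nt) are exact;
  the overlap graph must resolve to a unique chain, independent of input
  order.
* **Recombination** is an exact double-crossover at the homology-arm
  boundaries: the first and last arm-length nt of the amplicon must each
  occur exactly once in the locus, in the correct orientation and order.
  Mis-integration is represented by the uniqueness error, not by
  simulating aberrant events; near-matches are the off-target scanner's
  concern. N-terminal tagging is a pure insertion (zero-length replaced
  interval); C-terminal tagging replaces exactly the native stop codon,
  which lies between the two arm matches, with the cassette supplying the
  new stop; deletions replace the truncated CDS segment.

The tagged ORF is translated from a strategy-derived start (native ATG for
C-terminal strategies; the cassette's start codon, located from the
template layout, for N-terminal and internal strategies). When no start
hint is given, the simulator recovers the longest ATG-initiated ORF
overlapping the integration site. A design *passes* validation iff the
simulated amplicon equals the designed one, both arms match uniquely, and
the fused ORF is in frame with a single terminal stop at the expected
position.

## Off-target scanning and warnings

Off-target detection is seed-and-extend: every exact 20-mer of an arm is
looked up in the genome (both strands), each hit anchors an ungapped
full-arm alignment, and alignments with identity >= 0.90 over the full arm
outside the intended locus are reported. The 0.90-over-the-full-arm
threshold is this package's operationalization of "high homology between
ORFs" (no published threshold exists) and is configurable; the scan is
tested for equality against an all-offsets sliding-window oracle on
genomes up to 100 kb. Homopolymer-dominated arms are additionally flagged
low-complexity. Signal-peptide and GPI-anchor calls are consumed from a
user table, never predicted: implementing predictors would be scope creep
and unverifiable here; the biological rule encoded is that a signal
peptide makes the N-terminus unsuitable and a GPI-anchor site the
C-terminus. Warning severities are configuration-driven with documented
defaults; ordering is deterministic (code, then position).

## Well-count statistics

With a whole transfection distributed across N wells, occupancy is
Poisson with mean n/N, so the empty-well fraction estimates exp(-n/N) and
n = -N ln(1 - m/N). m = N is a saturation error (zero empty wells carry no
information). The 95% interval is Clopper-Pearson on the per-well
occupancy probability mapped through the same transform. The estimator is
validated against a seeded simulator that assigns each transfectant a
uniform random well: for n in {5, 20, 66, 200} and 10,000 replicates the
estimator applied to the mean occupied-well count recovers n within 5%.
Per-cell efficiency divides n by the number of cells transfected when
supplied (e.g. 1.2e7 for a standard nucleofection).

## Synthetic fixtures: what they do and do not show

The generator emulates exactly the structure the workflow relies on:
single-exon, ATG-initiated CDS with one terminal stop and no internal
frame-0 stops, on both strands, with intergenic flanks long enough for
1 kb flank extraction (CDS 300-900 nt, intergenic 2.1-2.7 kb by default,
GC 0.45); optional paralogs derived by per-base mutation at rate
1 - identity (start/stop restored, mutation-created stops repaired); and
plasmid placeholder bodies scrubbed of all registry enzyme sites and of
collisions with the annealing strings (including their 15 nt 3' cores), so
in-silico primer binding and digests are unambiguous by construction.
Identical spec and seed give byte-identical FASTA/GFF3 output.

Passing on these fixtures demonstrates the design arithmetic, frame logic,
simulators and scanners are correct. It does not demonstrate performance
on real genomes, which add unannotated UTRs, repeats and gene families
(more off-target hits and occasional enzyme-site conflicts — both
surfaced as warnings/errors rather than silently designed around),
realistic codon usage, or imperfect ORF annotation. Wet-lab observables
(transfection efficiencies, PCR yields and success rates, the homology-
length/efficiency relationship) are experimental quantities outside what
desk-scale computation can reproduce; the package confines itself to the
design rules, their verification, and the counting statistics.

Problem sizes used by the test suite and the acceptance script — 20-22
gene genomes, 180 designs per acceptance run, 10,000 plating replicates —
were chosen to exercise every code path with comfortable statistical
margins while keeping a full run in the low seconds.

## Numerical choices

* Nearest-neighbor Tm: SantaLucia unified parameters (Biopython's
  `DNA_NN3` table) at 50 mM monovalent salt, 500 nM total oligo (CT/4
  pairing term), entropic salt correction; valid for 10-60 nt. The Wallace
  rule 2(A+T)+4(G+C) is provided for quick estimates. An independent
  hand-coded parameter table in the test suite agrees within 0.5 deg C.
* All randomness is confined to the fixtures generator and the plating
  simulator, both driven by explicit seeds; design paths are fully
  deterministic, and batch TSV output is byte-identical across runs.
* Ties anywhere (Tm selection, enzyme selection) break by fixed documented
  orderings, never by iteration order of unordered containers.

## Known limitations

* Multi-exon CDS are rejected (single-exon is the rule in trypanosomatids;
  splicing is out of scope), as are circular contigs and IUPAC ambiguity
  codes beyond N.
* Primer-dimer/hairpin screening and ligation/sticky-end chemistry are not
  modeled.
* The recombination model scores only the intended double-crossover;
  population-level integration efficiency is not predicted.
* Built-in plasmid element bodies are placeholders; designs against them
  are structurally correct but their amplicon interiors are synthetic
  until real template sequences are loaded.
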