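# trypanotag

Design and in-silico verification of PCR-based endogenous gene tagging
constructs for trypanosomatids (*Trypanosoma brucei*, *Leishmania* spp.).

Endogenous tagging modifies a gene at its native chromosomal locus so the
encoded protein carries a fluorescent or epitope tag under native
regulation. In *T. brucei*, homologous recombination is efficient enough
that the entire integration fragment can be made in one PCR from a pPOT
template plasmid using **long primers**: each primer is 80 nt of locus
homology followed by a short plasmid-annealing sequence, so the amplicon
carries the tag and a drug-resistance cassette flanked by homology arms.
*Leishmania* needs longer homology (~500 bp), which is assembled instead by
**fusion PCR** (two genomic arms joined to a central tag+resistance
fragment released from a pLENT plasmid by restriction digest, then
amplified with nested primers) or by classical restriction cloning into
pLENTv2.

`trypanotag` automates both workflows and — unlike a primer list — verifies
every design computationally down to the predicted fusion protein.

## What it does

* **Long-primer design** for all five pPOT strategies: N-terminal tag,
  C-terminal tag, N/C deletion mutants, and internal tagging via a modified
  pPOTv4 template. Primer composition follows the published rules exactly
  (e.g. C-tag forward = last 80 nt of the ORF excluding the stop codon +
  the 18 nt 5' GS-linker annealing sequence `ggttctggtagtggttcc`).
* **Fusion-PCR design**: 500 bp arms with 30 bp junction adapters, central
  SpeI/NcoI (C-terminal, pLENTv2) or EcoRI/XbaI (N-terminal, pPOTv2)
  fragments, and Tm-optimized nested primers; plus pLENT restriction-cloning
  arm design with automatic selection of a unique linearization enzyme.
* **In-silico verification**: strict PCR simulation (exact 3' annealing),
  overlap-extension assembly, double-crossover recombination at the homology
  arms, and frame/stop checking of the resulting fusion ORF.
* **QC warnings**: seed-and-extend off-target scanning of homology arms
  (default: report loci >= 90% identical over the full arm), signal-peptide /
  GPI-anchor terminal-feature flags from a user-supplied table, ORF
  confidence labels, truncated flanks, configurable severities.
* **Transfection statistics**: zero-class Poisson correction of 96-well
  cloning counts, n = -N ln(1 - m/N), with Clopper-Pearson intervals and a
  seeded plating simulator.
* **Synthetic fixtures**: a deterministic generator of genomes (single-exon
  CDS, both strands, optional paralogs at controlled identity) and
  placeholder plasmid templates, so the whole package is testable offline.

The plasmid registry covers pPOTv2, pPOTv4 and the pLENTv2 tag x resistance
grid (pLENTv2-YB ... -CP). Published annealing sequences are embedded
verbatim; element bodies are synthetic placeholders (the full plasmid
sequences are not published) and can be replaced from a GenBank-style file.

## Worked example

```bash
trypanotag fixtures --genes 5 --seed 11 --out demo
trypanotag design-long --genome demo/genome.fasta --gff demo/genome.gff3 \
    --genes Tsyn0001 --template pPOTv4 --strategy C_TAG --out designs
tail -2 designs/primers.tsv
```

```
Tsyn0001  C_TAG  Tsyn0001_C_TAG_F  TTACCCTATATGGGTCGAATCTGAAGAGTTCCACAGATAACCAGTGTCATCAGACCGTTAGGCTGAACAACTCCAAACTAggttctggtagtggttcc   98  80  18  52.0  .
Tsyn0001  C_TAG  Tsyn0001_C_TAG_R  TGAATTCCCGAAAAGGGTCCGGTCGCATAATCCCAGCATGAAGTAATGGCTGTAACTTGGGCAAGCCATACATCAGGCGAccaatttgagagacctgtgc 100  80  20  54.1  .
```

Upper case is locus homology (80 nt), lower case is the plasmid-annealing
segment (18 nt GS-linker / 20 nt outer site); the columns are lengths and
the annealing segment's nearest-neighbor Tm in deg C. Verify the design:

```bash
trypanotag simulate --design designs/report.json --out validation.json
```

```json
{
  "gene_id": "Tsyn0001",
  "design_kind": "long:C_TAG",
  "passed": true,
  "in_frame": true,
  "stop_check": "single_terminal",
  "protein_length": 248,
  "replaced_interval": [1375, 1378]
}
```

The simulator amplified the cassette from pPOTv4 with the two primers,
integrated it at the locus by double crossover, and translated the tagged
ORF: the fusion protein is in frame with a single terminal stop (248
residues = the 125-residue native protein plus 123 residues of GS
linker::eYFP::GS linker). The 3 nt replaced interval is the native stop
codon, which the cassette replaces. `stats wells --total 96 --positive 48`
prints the Poisson-corrected clone count (66.54) for transfection
bookkeeping.

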