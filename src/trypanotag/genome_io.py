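"""FASTA + GFF3 loading into strand-normalized gene models.

Each protein-coding gene becomes a :class:`GeneModel` whose CDS and flanks
are reported in coding orientation regardless of genomic strand, so every
downstream design rule ("last 80 nt of the 5' UTR", "first 80 nt of the
ORF") is simple left-to-right string arithmetic.

Trypanosomatid UTRs are rarely annotated, so the primer-rule notions of
5'/3' UTR are operationalized as the genomic flanks immediately adjacent to
the CDS; any five_prime_UTR/three_prime_UTR features in the GFF3 are ignored
for arm extraction. Multi-exon CDS are rejected: trypanosomatid CDS are
single-exon and splicing is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from pyfaidx import Fasta

from .errors import LookupError_, UnsupportedStructureError
from .seqcore import as_dna, revcomp

DEFAULT_FLANK_LENGTH = 1000


@dataclass
class GeneModel:
    """A protein-coding locus with coding-strand CDS and flanking sequence.

    ``cds_interval`` is 0-based half-open in genome coordinates. For strand
    '-', ``cds``, ``upstream_flank`` and ``downstream_flank`` are the reverse
    complement of the corresponding genomic slices; ``upstream_flank`` always
    ends immediately before the start codon and ``downstream_flank`` begins
    immediately after the stop codon, in coding orientation.
    """

    gene_id: str
    chromosome: str
    strand: str
    cds_interval: tuple[int, int]
    cds: str
    upstream_flank: str
    downstream_flank: str
    flank_length: int
    warnings: list[str] = field(default_factory=list)

    @property
    def cds_length(self) -> int:
        return len(self.cds)

    def locus_context(self) -> str:
        """Contiguous coding-strand slice upstream_flank + cds + downstream_flank."""
        return self.upstream_flank + self.cds + self.downstream_flank

    @property
    def cds_start_in_context(self) -> int:
        return len(self.upstream_flank)


class Genome:
    """Loaded genome: chromosome sequences plus GeneModel records.

    Gene lookup is case-insensitive (with a warning on inexact-case hits);
    unknown ids raise an error listing near-miss ids.
    """

    def __init__(self, sequences: dict[str, str], genes: dict[str, GeneModel]):
        self.sequences = sequences
        self.genes = genes
        self._lower_index = {gid.lower(): gid for gid in genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def get_gene(self, gene_id: str) -> GeneModel:
        if gene_id in self.genes:
            return self.genes[gene_id]
        canonical = self._lower_index.get(gene_id.lower())
        if canonical is not None:
            gene = self.genes[canonical]
            gene.warnings.append(
                f"gene id {gene_id!r} matched {canonical!r} case-insensitively"
            )
            return gene
        near = [g for g in self.genes if gene_id.lower() in g.lower() or g.lower() in gene_id.lower()]
        hint = f"; near misses: {near[:5]}" if near else ""
        raise LookupError_(f"gene id {gene_id!r} not found{hint}")


def _gene_id_for_cds(db: gffutils.FeatureDB, cds: gffutils.Feature) -> str:
    """Resolve a CDS feature to its gene identifier via the Parent chain."""
    for anc in db.parents(cds, featuretype="gene"):
        return anc.id
    # no gene ancestor: fall back to the nearest parent, then own attributes
    for anc in db.parents(cds):
        return anc.id
    for key in ("gene_id", "Parent", "ID"):
        if key in cds.attributes:
            return cds.attributes[key][0]
    raise LookupError_(f"CDS at {cds.seqid}:{cds.start} carries no gene identifier")


def load_genome(
    fasta_path: str | Path,
    gff_path: str | Path,
    flank_length: int = DEFAULT_FLANK_LENGTH,
) -> Genome:
    """Read FASTA + GFF3 and build one GeneModel per protein-coding gene.

    Genes closer than ``flank_length`` to a contig end get truncated flanks
    plus a warning. A gene whose CDS comprises more than one segment raises
    UnsupportedStructureError.
    """
    fasta = Fasta(str(fasta_path), rebuild=True)
    sequences = {name: as_dna(str(fasta[name][:]), f"contig {name}") for name in fasta.keys()}

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    by_gene: dict[str, list[gffutils.Feature]] = {}
    for cds in db.features_of_type("CDS"):
        by_gene.setdefault(_gene_id_for_cds(db, cds), []).append(cds)

    genes: dict[str, GeneModel] = {}
    for gene_id, segments in by_gene.items():
        if len(segments) > 1:
            raise UnsupportedStructureError(
                f"gene {gene_id!r} has {len(segments)} CDS segments; "
                "multi-exon CDS are not supported (trypanosomatid CDS are single-exon)"
            )
        seg = segments[0]
        if seg.seqid not in sequences:
            raise LookupError_(
                f"gene {gene_id!r} references contig {seg.seqid!r} absent from the FASTA"
            )
        chrom = sequences[seg.seqid]
        start, end = seg.start - 1, seg.end  # GFF3 1-based inclusive -> half-open
        strand = seg.strand
        warnings: list[str] = []

        if strand == "+":
            up_start = max(0, start - flank_length)
            upstream = chrom[up_start:start]
            downstream = chrom[end : end + flank_length]
            cds_seq = chrom[start:end]
        else:
            # coding orientation: upstream flank is genomically 3' of the CDS
            upstream = revcomp(chrom[end : end + flank_length])
            down_start = max(0, start - flank_length)
            downstream = revcomp(chrom[down_start:start])
            cds_seq = revcomp(chrom[start:end])

        if len(upstream) < flank_length:
            warnings.append(
                f"upstream flank truncated to {len(upstream)} nt at contig end"
            )
        if len(downstream) < flank_length:
            warnings.append(
                f"downstream flank truncated to {len(downstream)} nt at contig end"
            )
        if len(cds_seq) % 3 != 0:
            warnings.append(f"CDS length {len(cds_seq)} is not a multiple of 3")
        if not cds_seq.startswith("ATG"):
            warnings.append("CDS does not begin with ATG")
        if len(cds_seq) < 6:
            raise UnsupportedStructureError(
                f"gene {gene_id!r} CDS is only {len(cds_seq)} nt"
            )

        genes[gene_id] = GeneModel(
            gene_id=gene_id,
            chromosome=seg.seqid,
            strand=strand,
            cds_interval=(start, end),
            cds=cds_seq,
            upstream_flank=upstream,
            downstream_flank=downstream,
            flank_length=flank_length,
            warnings=warnings,
        )

    return Genome(sequences, genes)
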