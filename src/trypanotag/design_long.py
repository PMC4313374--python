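"""Long-primer design for the five pPOT strategies.

Each primer is the locus-derived homology segment (5') followed by the
plasmid-derived annealing segment (3'): the locus sequence is always 5' of
the sequence that anneals to the template. The default homology length is
80 nt, the length at which long-primer tagging is reliable in T. brucei;
it is configurable within 50-120 nt with a warning below 80.

Strategy rules (H = homology length, upper case = locus, lower = plasmid):

  N_TAG     fwd = last H nt of upstream flank + fwd_outer
            rev = revcomp(first H nt of CDS) + linker3_rev (v4) / tag_rev (v2)
  C_TAG     fwd = last H nt of CDS minus stop + linker5_fwd (v4) / tag_fwd (v2)
            rev = revcomp(first H nt of downstream flank) + rev_outer
  N_DEL     fwd as N_TAG; rev = revcomp(H nt of CDS from the truncation point)
            + linker3_rev
  C_DEL     fwd = H nt of CDS ending at the truncation point + linker5_fwd;
            rev as C_TAG
  INTERNAL  fwd as N_TAG; rev = revcomp(H nt of CDS immediately after the
            template-embedded insert) + linker3_rev (modified pPOTv4 only)

Homology arms always abut the start/stop codon (no user-adjustable gap).
For N_TAG the native ATG is retained in the arm; the post-recombination
reading frame is verified by the insilico module rather than assumed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .errors import (
    AlphabetError,
    FrameError,
    InsufficientFlankError,
    PrematureStopError,
    RegistryError,
    UsageError,
)
from .genome_io import GeneModel, Genome
from .plasmids import PlasmidTemplate
from .seqcore import frame0_stop_codon_positions, is_codon_aligned, revcomp

DEFAULT_HOMOLOGY = 80
HOMOLOGY_RANGE = (50, 120)
RECOMMENDED_HOMOLOGY = 80


class Strategy(str, enum.Enum):
    N_TAG = "N_TAG"
    C_TAG = "C_TAG"
    N_DEL = "N_DEL"
    C_DEL = "C_DEL"
    INTERNAL = "INTERNAL"


@dataclass
class Primer:
    """An oligo, 5'->3' as synthesized: homology segment then anneal segment.

    ``homology_segment`` is stored upper case (locus convention) and
    ``anneal_segment`` lower case (plasmid convention, exactly as published);
    ``sequence`` is the canonical upper-case concatenation and ``display``
    preserves the mixed-case convention.
    """

    name: str
    homology_segment: str
    anneal_segment: str
    strategy: Strategy
    tm_anneal: float

    @property
    def sequence(self) -> str:
        return (self.homology_segment + self.anneal_segment).upper()

    @property
    def display(self) -> str:
        return self.homology_segment.upper() + self.anneal_segment.lower()

    def __len__(self) -> int:
        return len(self.homology_segment) + len(self.anneal_segment)


@dataclass
class LongPrimerDesign:
    gene_id: str
    plasmid: str
    strategy: Strategy
    forward: Primer
    reverse: Primer
    predicted_amplicon: str
    homology_length: int
    truncation_point: int | None = None
    warnings: list[str] = field(default_factory=list)
    # provenance for the simulator: template object and the top-strand span
    # of the amplified cassette (fwd anneal-site start .. rev anneal-site end)
    template: PlasmidTemplate | None = field(default=None, repr=False)
    template_span: tuple[int, int] | None = None


def _tm(anneal: str) -> float:
    from .design_fusion import melting_temperature

    return melting_temperature(anneal, method="nearest_neighbor")


def _check_primer_alphabet(seq: str, name: str) -> None:
    if "N" in seq.upper():
        raise AlphabetError(f"primer {name} contains N and cannot be synthesized")


def _check_no_premature_stop(gene: GeneModel, interval: tuple[int, int], what: str) -> None:
    """Reject a CDS-derived arm containing a frame-0 stop the fused reading
    frame would run through (annotation defect surfaced at design time)."""
    lo, hi = interval
    internal = [p for p in frame0_stop_codon_positions(gene.cds) if p < len(gene.cds) - 3]
    bad = [p for p in internal if lo <= p < hi]
    if bad:
        raise PrematureStopError(
            f"{gene.gene_id}: frame-0 stop codon at CDS position {bad[0]} "
            f"inside the {what} homology arm"
        )


def _roles_for(template: PlasmidTemplate, strategy: Strategy) -> tuple[str, str]:
    """(forward role, reverse role) of the annealing segments per strategy."""
    fam = template.family
    if fam == "pPOTv4":
        tag5, tag3 = "linker5_fwd", "linker3_rev"
    elif fam == "pPOTv2":
        tag5, tag3 = "tag_fwd", "tag_rev"
    else:
        raise RegistryError(
            f"long-primer design requires a pPOT template, got family {fam!r}"
        )
    if strategy in (Strategy.N_TAG, Strategy.N_DEL, Strategy.INTERNAL):
        if strategy is not Strategy.N_TAG and fam != "pPOTv4":
            raise RegistryError(f"{strategy.value} requires a pPOTv4-family template")
        return "fwd_outer", tag3
    if strategy in (Strategy.C_TAG, Strategy.C_DEL):
        if strategy is Strategy.C_DEL and fam != "pPOTv4":
            raise RegistryError("C_DEL requires a pPOTv4-family template")
        return tag5, "rev_outer"
    raise UsageError(f"unknown strategy {strategy!r}")


def design_long(
    gene: GeneModel,
    template: PlasmidTemplate,
    strategy: Strategy | str,
    homology_length: int = DEFAULT_HOMOLOGY,
    truncation_point: int | None = None,
) -> LongPrimerDesign:
    """Design one long-primer pair plus its predicted amplicon.

    ``truncation_point`` (N_DEL/C_DEL/INTERNAL) is a codon-aligned CDS
    nucleotide offset strictly inside the CDS: for C_DEL the retained ORF
    prefix ends there; for N_DEL the retained suffix starts there; for
    INTERNAL it marks where locus homology resumes, i.e. the length of the
    CDS prefix embedded in the modified template.
    """
    strategy = Strategy(strategy)
    H = homology_length
    warnings: list[str] = []

    lo, hi = HOMOLOGY_RANGE
    if not lo <= H <= hi:
        raise UsageError(f"homology length {H} outside supported range {lo}-{hi}")
    if H < RECOMMENDED_HOMOLOGY:
        warnings.append(
            f"BELOW_RECOMMENDED_HOMOLOGY: {H} nt arms are below the 80 nt "
            "at which long-primer tagging is reliable"
        )

    cds, L = gene.cds, gene.cds_length
    needs_trunc = strategy in (Strategy.N_DEL, Strategy.C_DEL, Strategy.INTERNAL)
    if needs_trunc:
        if truncation_point is None:
            raise UsageError(f"{strategy.value} requires a truncation point")
        t = truncation_point
        if not is_codon_aligned(t):
            raise FrameError(
                f"truncation point {t} is not codon-aligned (offset {t % 3})"
            )
        if not 0 < t < L if strategy is Strategy.C_DEL else not 0 <= t < L:
            raise FrameError(f"truncation point {t} outside CDS of length {L}")
    else:
        if truncation_point is not None:
            raise UsageError(f"{strategy.value} takes no truncation point")
        t = 0

    if strategy is Strategy.INTERNAL:
        if template.internal_insert is None:
            raise RegistryError(
                "INTERNAL design requires a template modified by insert_internal_element"
            )
        if template.internal_insert[0] != "5prime":
            raise RegistryError(
                "only the 5'-side internal-tag rule is published; "
                "3'-side internal designs are unsupported"
            )

    fwd_role, rev_role = _roles_for(template, strategy)
    fwd_anneal = template.anneal_sites[fwd_role]
    rev_anneal = template.anneal_sites[rev_role]

    # --- locus homology segments ------------------------------------------
    if strategy in (Strategy.N_TAG, Strategy.N_DEL, Strategy.INTERNAL):
        if len(gene.upstream_flank) < H:
            raise InsufficientFlankError(
                f"{gene.gene_id}: upstream flank {len(gene.upstream_flank)} nt < {H} nt"
            )
        fwd_hom = gene.upstream_flank[-H:]
    elif strategy is Strategy.C_TAG:
        if L - 3 < H:
            raise InsufficientFlankError(f"{gene.gene_id}: CDS too short for {H} nt arm")
        fwd_hom = cds[:-3][-H:]
        _check_no_premature_stop(gene, (L - 3 - H, L - 3), "forward")
    else:  # C_DEL
        if t < H:
            raise InsufficientFlankError(
                f"{gene.gene_id}: truncation point {t} leaves no room for {H} nt arm"
            )
        fwd_hom = cds[t - H : t]
        _check_no_premature_stop(gene, (t - H, t), "forward")

    if strategy in (Strategy.C_TAG, Strategy.C_DEL):
        if len(gene.downstream_flank) < H:
            raise InsufficientFlankError(
                f"{gene.gene_id}: downstream flank {len(gene.downstream_flank)} nt < {H} nt"
            )
        rev_hom_plus = gene.downstream_flank[:H]
    else:
        start = t  # 0 for N_TAG; truncation/insert end for N_DEL/INTERNAL
        if start + H > L:
            raise InsufficientFlankError(
                f"{gene.gene_id}: CDS arm [{start}, {start + H}) exceeds CDS length {L}"
            )
        rev_hom_plus = cds[start : start + H]
        _check_no_premature_stop(gene, (start, start + H), "reverse")
    rev_hom = revcomp(rev_hom_plus)

    for seq, nm in ((fwd_hom, "forward"), (rev_hom, "reverse")):
        _check_primer_alphabet(seq, nm)

    prefix = f"{gene.gene_id}_{strategy.value}"
    forward = Primer(f"{prefix}_F", fwd_hom.upper(), fwd_anneal, strategy, _tm(fwd_anneal))
    reverse = Primer(f"{prefix}_R", rev_hom.upper(), rev_anneal, strategy, _tm(rev_anneal))

    f0 = template.anneal_site_span(fwd_role)[0]
    r1 = template.anneal_site_span(rev_role)[1]
    if not f0 < r1:
        raise RegistryError(
            f"template {template.name!r}: {fwd_role} site not 5' of {rev_role} site"
        )
    amplicon = fwd_hom.upper() + template.full_sequence[f0:r1] + revcomp(rev_hom).upper()

    if gene.warnings:
        warnings.extend(f"gene: {w}" for w in gene.warnings)

    return LongPrimerDesign(
        gene_id=gene.gene_id,
        plasmid=template.name,
        strategy=strategy,
        forward=forward,
        reverse=reverse,
        predicted_amplicon=amplicon,
        homology_length=H,
        truncation_point=truncation_point,
        warnings=warnings,
        template=template,
        template_span=(f0, r1),
    )


@dataclass
class BatchResult:
    designs: list[LongPrimerDesign]
    failures: list[tuple[str, str]]  # (gene_id, error message)

    @property
    def summary(self) -> dict:
        warned = sum(1 for d in self.designs if d.warnings)
        return {
            "requested": len(self.designs) + len(self.failures),
            "designed": len(self.designs),
            "failed": len(self.failures),
            "warned": warned,
        }


def batch_design(
    genome: Genome,
    gene_ids: list[str],
    template: PlasmidTemplate,
    strategy: Strategy | str,
    homology_length: int = DEFAULT_HOMOLOGY,
    truncation_points: dict[str, int] | None = None,
) -> BatchResult:
    """Design every gene in ``gene_ids``; one failure does not abort the batch."""
    if not gene_ids:
        raise UsageError("empty gene id list")
    designs: list[LongPrimerDesign] = []
    failures: list[tuple[str, str]] = []
    for gid in gene_ids:
        try:
            gene = genome.get_gene(gid)
            tp = (truncation_points or {}).get(gid)
            designs.append(
                design_long(gene, template, strategy, homology_length, tp)
            )
        except Exception as exc:  # captured per gene, reported in the summary
            failures.append((gid, f"{type(exc).__name__}: {exc}"))
    return BatchResult(designs, failures)


def aa_to_nt_truncation(aa_index: int) -> int:
    """Convert an amino-acid truncation coordinate to CDS nucleotides (aa i -> nt 3i)."""
    if aa_index < 0:
        raise UsageError("amino-acid coordinate must be non-negative")
    return 3 * aa_index
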