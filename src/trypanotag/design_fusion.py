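"""Fusion-PCR tagging design and pLENT restriction-cloning design.

Fusion PCR builds a tagging amplicon from three pieces: two ~500 bp arms
amplified from the genome (the gene 3' end and the downstream region for
C-terminal tagging; the upstream region and the gene 5' end for N-terminal)
and a central tag+intergenic+resistance fragment released from a plasmid by
a double digest (SpeI/NcoI from pLENTv2 for C; EcoRI/XbaI from pPOTv2 for
N, since pLENTv2 is not suitable for N-terminal tagging). Round-1 junction
primers carry 30 bp adapters of homology to the central fragment ends; the
primer-less fusion joins the fragments at those exact overlaps, and nested
round-2 primers inset 20-30 bp from the outer ends amplify the final
construct.

Round-1 outer primers and nested primers are melting-temperature driven:
among candidate lengths (20-30 nt) or insets (20-30 bp) the one whose
nearest-neighbor Tm is closest to the target is chosen, ties broken by the
smaller length/inset then lexicographically - batch output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.SeqUtils import MeltingTemp as _mt

from .design_long import Strategy
from .errors import (
    AssemblyError,
    DigestError,
    InsufficientFlankError,
    RegistryError,
    UsageError,
)
from .enzymes import get_enzyme
from .genome_io import GeneModel
from .plasmids import PlasmidTemplate, digest_release
from .seqcore import find_substring, revcomp

DEFAULT_ARM_LENGTH = 500
DEFAULT_ADAPTER_LENGTH = 30
DEFAULT_NESTED_INSET_RANGE = (20, 30)
DEFAULT_TARGET_TM = 60.0
CLONING_ARM_RANGE = (300, 500)
PRIMER_CANDIDATE_LENGTHS = range(20, 31)
_CLONING_PAD = "GCGC"  # 4 nt 5' padding for efficient digestion of PCR ends

# documented nearest-neighbor conditions: SantaLucia unified parameters,
# 50 mM monovalent salt, 500 nM total oligo (CT/4 pairing term)
_NN_SALT_MM = 50.0
_NN_DNAC_NM = 250.0


def melting_temperature(s: str, method: str = "nearest_neighbor") -> float:
    """Oligo melting temperature in deg C.

    ``nearest_neighbor`` uses the SantaLucia-1998 unified parameter set at
    50 mM monovalent salt and 500 nM oligo (valid for 10-60 nt);
    ``wallace`` is the 2*(A+T) + 4*(G+C) rule (any length).
    """
    seq = s.upper()
    if method == "wallace":
        if not seq:
            raise UsageError("empty sequence")
        return float(_mt.Tm_Wallace(seq))
    if method == "nearest_neighbor":
        if not 10 <= len(seq) <= 60:
            raise UsageError(
                f"nearest-neighbor Tm is supported for 10-60 nt, got {len(seq)}"
            )
        return float(
            _mt.Tm_NN(
                seq,
                nn_table=_mt.DNA_NN3,
                Na=_NN_SALT_MM,
                dnac1=_NN_DNAC_NM,
                dnac2=_NN_DNAC_NM,
                saltcorr=5,
            )
        )
    raise UsageError(f"unknown Tm method {method!r}")


def _pick_by_tm(candidates: list[tuple[int, str]], target_tm: float) -> tuple[int, str, float]:
    """Choose (key, sequence) minimizing |Tm - target|; ties by smaller key
    then lexicographically smaller sequence."""
    best = None
    for key, seq in candidates:
        tm = melting_temperature(seq, "nearest_neighbor")
        rank = (abs(tm - target_tm), key, seq)
        if best is None or rank < best[0]:
            best = (rank, key, seq, tm)
    assert best is not None
    return best[1], best[2], best[3]


@dataclass
class FusionPrimer:
    """A round-1 or nested primer: optional plasmid-homology adapter (5')
    followed by the genomic annealing portion (3'), 5'->3' as synthesized."""

    name: str
    adapter: str  # "" when the primer has no overhang
    genomic: str
    tm_genomic: float

    @property
    def sequence(self) -> str:
        return (self.adapter + self.genomic).upper()

    @property
    def display(self) -> str:
        return self.adapter.lower() + self.genomic.upper()

    def __len__(self) -> int:
        return len(self.adapter) + len(self.genomic)


@dataclass
class ArmDesign:
    forward: FusionPrimer
    reverse: FusionPrimer
    sequence: str  # the genomic arm itself
    predicted_product: str  # round-1 amplicon including the adapter


@dataclass
class FusionDesign:
    gene_id: str
    terminus: str
    arm_length: int
    gene_arm: ArmDesign
    utr_arm: ArmDesign
    central_fragment: str
    release_enzymes: tuple[str, str]
    nested_fwd: FusionPrimer
    nested_rev: FusionPrimer
    nested_insets: tuple[int, int]
    predicted_final_amplicon: str
    warnings: list[str] = field(default_factory=list)
    template: PlasmidTemplate | None = field(default=None, repr=False)

    @property
    def joined_product(self) -> str:
        """The primer-less fusion product before the nested trim."""
        left, right = (
            (self.gene_arm, self.utr_arm)
            if self.terminus == "C"
            else (self.utr_arm, self.gene_arm)
        )
        return left.sequence + self.central_fragment + right.sequence


def _outer_primer(name: str, arm: str, target_tm: float) -> tuple[str, float]:
    cands = [(k, arm[:k]) for k in PRIMER_CANDIDATE_LENGTHS if k <= len(arm)]
    _, seq, tm = _pick_by_tm(cands, target_tm)
    return seq, tm


def _end_primer(name: str, arm: str, target_tm: float) -> tuple[str, float]:
    cands = [(k, revcomp(arm[-k:])) for k in PRIMER_CANDIDATE_LENGTHS if k <= len(arm)]
    _, seq, tm = _pick_by_tm(cands, target_tm)
    return seq, tm


def _check_release_sites(
    arm_name: str,
    arm: str,
    enzymes: tuple[str, str],
    junction_end: str,
    adapter_length: int,
    warnings: list[str],
) -> None:
    """Release-enzyme sites inside an arm re-cut the fragment during digest
    clean-up: warn anywhere, hard error inside the junction adapter region."""
    for name in enzymes:
        site = get_enzyme(name).site
        hits = find_substring(arm, site)
        if not hits:
            continue
        danger = (
            [h for h in hits if h + len(site) > len(arm) - adapter_length]
            if junction_end == "3"
            else [h for h in hits if h < adapter_length]
        )
        if danger:
            raise DigestError(
                f"{name} site at {arm_name} position {danger[0]} lies inside "
                "the junction adapter region"
            )
        warnings.append(
            f"ENZYME_CONFLICT: {name} site(s) at {arm_name} position(s) {hits}"
        )


def design_fusion(
    gene: GeneModel,
    template: PlasmidTemplate,
    terminus: str,
    arm_length: int = DEFAULT_ARM_LENGTH,
    adapter_length: int = DEFAULT_ADAPTER_LENGTH,
    nested_inset_range: tuple[int, int] = DEFAULT_NESTED_INSET_RANGE,
    target_tm: float = DEFAULT_TARGET_TM,
) -> FusionDesign:
    """Design a complete two-round fusion-PCR tagging amplicon."""
    terminus = terminus.upper()
    if terminus not in ("N", "C"):
        raise UsageError(f"terminus must be 'N' or 'C', got {terminus!r}")

    if terminus == "C":
        if template.family != "pLENTv2":
            raise RegistryError(
                f"C-terminal fusion uses a pLENTv2 template, got {template.family!r}"
            )
        release = ("SpeI", "NcoI")
    else:
        if template.family != "pPOTv2":
            raise RegistryError(
                "pLENTv2 is not suitable for N-terminal tagging; use pPOTv2 "
                f"(got {template.family!r})"
            )
        release = ("EcoRI", "XbaI")
    central = digest_release(template, *release)

    context = gene.locus_context()
    cds_start = gene.cds_start_in_context
    cds_end = cds_start + gene.cds_length
    inset_lo, inset_hi = nested_inset_range
    if not 0 < inset_lo <= inset_hi:
        raise UsageError(f"bad nested inset range {nested_inset_range}")
    min_arm = inset_hi + max(PRIMER_CANDIDATE_LENGTHS) + adapter_length
    if arm_length < min_arm:
        raise UsageError(f"arm length {arm_length} too short (need >= {min_arm})")

    warnings: list[str] = []
    if terminus == "C":
        # gene arm: arm_length nt ending at the stop codon (stop excluded)
        lo = cds_end - 3 - arm_length
        if lo < 0:
            raise InsufficientFlankError(
                f"{gene.gene_id}: locus too short for a {arm_length} nt gene arm"
            )
        gene_arm_seq = context[lo : cds_end - 3]
        if len(gene.downstream_flank) < arm_length:
            raise InsufficientFlankError(
                f"{gene.gene_id}: downstream flank shorter than {arm_length} nt"
            )
        utr_arm_seq = context[cds_end : cds_end + arm_length]
        left_seq, right_seq = gene_arm_seq, utr_arm_seq
        left_name, right_name = "gene arm", "utr arm"
    else:
        if len(gene.upstream_flank) < arm_length:
            raise InsufficientFlankError(
                f"{gene.gene_id}: upstream flank shorter than {arm_length} nt"
            )
        utr_arm_seq = context[cds_start - arm_length : cds_start]
        if cds_start + arm_length > len(context):
            raise InsufficientFlankError(
                f"{gene.gene_id}: locus too short for a {arm_length} nt gene arm"
            )
        gene_arm_seq = context[cds_start : cds_start + arm_length]
        left_seq, right_seq = utr_arm_seq, gene_arm_seq
        left_name, right_name = "utr arm", "gene arm"

    left_adapter = revcomp(central[:adapter_length])  # on the left arm's reverse primer
    right_adapter = central[-adapter_length:]  # on the right arm's forward primer

    _check_release_sites(left_name, left_seq, release, "3", adapter_length, warnings)
    _check_release_sites(right_name, right_seq, release, "5", adapter_length, warnings)

    gid = gene.gene_id
    lf_seq, lf_tm = _outer_primer(f"{gid}_left_F", left_seq, target_tm)
    lr_seq, lr_tm = _end_primer(f"{gid}_left_R", left_seq, target_tm)
    rf_seq, rf_tm = _outer_primer(f"{gid}_right_F", right_seq, target_tm)
    rr_seq, rr_tm = _end_primer(f"{gid}_right_R", right_seq, target_tm)

    left = ArmDesign(
        forward=FusionPrimer(f"{gid}_fus_{terminus}_1F", "", lf_seq, lf_tm),
        reverse=FusionPrimer(f"{gid}_fus_{terminus}_1R", left_adapter, lr_seq, lr_tm),
        sequence=left_seq,
        predicted_product=left_seq + central[:adapter_length],
    )
    right = ArmDesign(
        forward=FusionPrimer(f"{gid}_fus_{terminus}_2F", right_adapter, rf_seq, rf_tm),
        reverse=FusionPrimer(f"{gid}_fus_{terminus}_2R", "", rr_seq, rr_tm),
        sequence=right_seq,
        predicted_product=central[-adapter_length:] + right_seq,
    )

    joined = left_seq + central + right_seq
    for probe, junction in ((central[:adapter_length], "left"), (central[-adapter_length:], "right")):
        if len(find_substring(joined, probe)) != 1:
            raise AssemblyError(
                f"{junction} junction adapter occurs more than once: assembly ambiguous"
            )

    insets = range(inset_lo, inset_hi + 1)
    k = min(PRIMER_CANDIDATE_LENGTHS)
    fwd_inset, nf_seq, nf_tm = _pick_by_tm(
        [(i, joined[i : i + k]) for i in insets], target_tm
    )
    rev_inset, nr_seq, nr_tm = _pick_by_tm(
        [(i, revcomp(joined[len(joined) - i - k : len(joined) - i])) for i in insets],
        target_tm,
    )
    nested_fwd = FusionPrimer(f"{gid}_fus_{terminus}_nestF", "", nf_seq, nf_tm)
    nested_rev = FusionPrimer(f"{gid}_fus_{terminus}_nestR", "", nr_seq, nr_tm)
    final = joined[fwd_inset : len(joined) - rev_inset]

    gene_arm, utr_arm = (left, right) if terminus == "C" else (right, left)
    return FusionDesign(
        gene_id=gid,
        terminus=terminus,
        arm_length=arm_length,
        gene_arm=gene_arm,
        utr_arm=utr_arm,
        central_fragment=central,
        release_enzymes=release,
        nested_fwd=nested_fwd,
        nested_rev=nested_rev,
        nested_insets=(fwd_inset, rev_inset),
        predicted_final_amplicon=final,
        warnings=warnings,
        template=template,
    )


# ---------------------------------------------------------------------------
# pLENT restriction cloning


@dataclass
class CloningDesign:
    gene_id: str
    terminus: str
    arm_length: int
    gene_arm_fwd: FusionPrimer
    gene_arm_rev: FusionPrimer
    utr_arm_fwd: FusionPrimer
    utr_arm_rev: FusionPrimer
    linearization_enzyme: str
    gene_fragment: str  # digested gene-arm insert (site-start abstraction)
    utr_fragment: str
    assembled_plasmid: str  # circular, written from the gene arm
    predicted_linearized: str
    warnings: list[str] = field(default_factory=list)


def _count_circular(seq: str, site: str) -> int:
    """Occurrences of ``site`` in a circular sequence."""
    wrapped = seq + seq[: len(site) - 1]
    return len(find_substring(wrapped, site))


def design_plent_cloning(
    gene: GeneModel,
    template: PlasmidTemplate,
    terminus: str = "C",
    arm_length: int = 400,
    target_tm: float = DEFAULT_TARGET_TM,
) -> CloningDesign:
    """Design pLENT C-terminal tagging arms for restriction cloning.

    The gene arm (3' end of the ORF, stop excluded) carries the
    linearization site (forward) and SpeI (reverse); the downstream arm
    carries HindIII (forward) and the linearization site (reverse); both
    sites get 4 nt of 5' padding. The linearization enzyme is the first
    registry enzyme with no site in either arm and exactly one site in the
    predicted assembled plasmid.
    """
    terminus = terminus.upper()
    if terminus != "C":
        raise UsageError(
            "only the C-terminal pLENT cloning workflow is published; "
            "N-terminal tagging uses the pPOTv2 fusion route"
        )
    if template.family != "pLENTv2":
        raise RegistryError(f"pLENT cloning requires a pLENTv2 template, got {template.family!r}")
    lo, hi = CLONING_ARM_RANGE
    if not lo <= arm_length <= hi:
        raise UsageError(f"arm length {arm_length} outside the supported {lo}-{hi} nt range")

    context = gene.locus_context()
    cds_end = gene.cds_start_in_context + gene.cds_length
    if cds_end - 3 - arm_length < 0:
        raise InsufficientFlankError(f"{gene.gene_id}: locus too short for the gene arm")
    gene_arm = context[cds_end - 3 - arm_length : cds_end - 3]
    if len(gene.downstream_flank) < arm_length:
        raise InsufficientFlankError(f"{gene.gene_id}: downstream flank too short")
    utr_arm = context[cds_end : cds_end + arm_length]

    spe = get_enzyme("SpeI").site
    hind = get_enzyme("HindIII").site
    full = template.full_sequence
    spe_hits = find_substring(full, spe)
    hind_hits = find_substring(full, hind)
    if len(spe_hits) != 1 or len(hind_hits) != 1:
        raise DigestError(
            f"template {template.name!r} must carry unique SpeI and HindIII sites"
        )
    vector_span = full[spe_hits[0] : hind_hits[0] + len(hind)]

    warnings: list[str] = []
    for enz_name, arm, arm_name in (("SpeI", gene_arm, "gene arm"), ("HindIII", utr_arm, "utr arm")):
        for enz2 in ("SpeI", "HindIII"):
            hits = find_substring(arm, get_enzyme(enz2).site)
            if hits:
                warnings.append(
                    f"ENZYME_CONFLICT: {enz2} site(s) in {arm_name} at {hits}"
                )

    conflicts: list[str] = []
    chosen = None
    from .enzymes import REGISTRY

    for enz in REGISTRY.values():
        in_gene = len(find_substring(gene_arm, enz.site))
        in_utr = len(find_substring(utr_arm, enz.site))
        assembled = gene_arm + vector_span + utr_arm + enz.site
        n_total = _count_circular(assembled, enz.site)
        if in_gene == 0 and in_utr == 0 and n_total == 1:
            chosen = enz
            break
        conflicts.append(
            f"{enz.name}: {in_gene} in gene arm, {in_utr} in utr arm, "
            f"{n_total} in assembled plasmid"
        )
    if chosen is None:
        from .errors import SelectionError

        raise SelectionError(
            "no admissible linearization enzyme: " + "; ".join(conflicts)
        )

    tm = target_tm
    gf_seq, gf_tm = _outer_primer("gf", gene_arm, tm)
    gr_seq, gr_tm = _end_primer("gr", gene_arm, tm)
    uf_seq, uf_tm = _outer_primer("uf", utr_arm, tm)
    ur_seq, ur_tm = _end_primer("ur", utr_arm, tm)
    gid = gene.gene_id
    pad = _CLONING_PAD

    assembled = gene_arm + vector_span + utr_arm + chosen.site
    linearized = chosen.site + gene_arm + vector_span + utr_arm

    return CloningDesign(
        gene_id=gid,
        terminus=terminus,
        arm_length=arm_length,
        gene_arm_fwd=FusionPrimer(f"{gid}_clo_GF", pad + chosen.site, gf_seq, gf_tm),
        gene_arm_rev=FusionPrimer(f"{gid}_clo_GR", pad + spe, gr_seq, gr_tm),
        utr_arm_fwd=FusionPrimer(f"{gid}_clo_UF", pad + hind, uf_seq, uf_tm),
        utr_arm_rev=FusionPrimer(f"{gid}_clo_UR", pad + chosen.site, ur_seq, ur_tm),
        linearization_enzyme=chosen.name,
        gene_fragment=chosen.site + gene_arm + spe,
        utr_fragment=hind + utr_arm + chosen.site,
        assembled_plasmid=assembled,
        predicted_linearized=linearized,
        warnings=warnings,
    )
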