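"""In-silico verification: PCR, fusion assembly and homologous recombination.

The simulators are intentionally strict string machines. PCR binding
requires an exact match of a primer's 3'-terminal ``min_anneal`` nt;
fusion joining requires exact terminal overlaps; recombination is modeled
as an exact double-crossover at the homology-arm boundaries, because that
is the intended, correctly-integrated product - mis-integration is
represented by the arm-uniqueness error, not by simulating aberrant events.
Near-matches are the qc module's concern.

``validate_design`` chains the simulators for a long-primer or fusion
design and verifies the predicted fusion protein: a design passes iff the
fused ORF is in frame with a single terminal stop and both arms match the
locus uniquely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .design_fusion import FusionDesign, FusionPrimer
from .design_long import LongPrimerDesign, Primer, Strategy
from .errors import AssemblyError, MistargetError, PcrError, UsageError
from .genome_io import GeneModel
from .seqcore import STOP_CODONS, find_substring, revcomp, translate

DEFAULT_MIN_ANNEAL = 15
DEFAULT_MIN_OVERLAP = 20


@dataclass
class Amplicon:
    """A predicted PCR product with fragment/primer provenance."""

    sequence: str
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


def _primer_seq(p: Primer | FusionPrimer | str) -> str:
    if isinstance(p, str):
        return p.upper()
    return p.sequence


def simulate_pcr(
    template: str,
    fwd: Primer | FusionPrimer | str,
    rev: Primer | FusionPrimer | str,
    min_anneal: int = DEFAULT_MIN_ANNEAL,
) -> Amplicon:
    """Predict the single product of a PCR on a linear template.

    Binding requires an exact match of the primer's 3'-terminal
    ``min_anneal`` nt (top strand for fwd, bottom strand for rev); 5'
    overhangs are tolerated and incorporated into the product. Zero or
    multiple binding sites, or a forward site downstream of the reverse
    site, raise PcrError.
    """
    tpl = template.upper()
    f = _primer_seq(fwd)
    r = _primer_seq(rev)
    if len(f) < min_anneal or len(r) < min_anneal:
        raise UsageError(f"primers must be at least min_anneal={min_anneal} nt")

    f_sites = find_substring(tpl, f[-min_anneal:])
    r_sites = find_substring(tpl, revcomp(r[-min_anneal:]))
    if not f_sites or not r_sites:
        raise PcrError(
            f"no product: {len(f_sites)} forward and {len(r_sites)} reverse binding sites"
        )
    if len(f_sites) > 1 or len(r_sites) > 1:
        raise PcrError(
            f"ambiguous product: {len(f_sites)} forward and {len(r_sites)} "
            "reverse binding sites"
        )
    f_end = f_sites[0] + min_anneal  # template position just 3' of the fwd 3' end
    r_start = r_sites[0]  # template position of the rev primer's 3'-end match
    if f_end > r_start:
        raise PcrError("no product: forward site downstream of (or overlapping) reverse site")
    product = f + tpl[f_end:r_start] + revcomp(r)
    return Amplicon(product, [f"fwd@{f_sites[0]}", f"rev@{r_start}"])


def simulate_fusion(
    fragments: list[str],
    nested_fwd: Primer | FusionPrimer | str,
    nested_rev: Primer | FusionPrimer | str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> Amplicon:
    """Join fragments at exact terminal overlaps, then amplify with nested primers.

    Assembly is order-independent: the overlap graph (3' end of one fragment
    identical to the 5' start of another over >= min_overlap nt) must
    resolve to a unique linear chain covering every fragment; a missing or
    ambiguous junction raises AssemblyError naming the junction.
    """
    if len(fragments) < 2:
        raise UsageError("fusion requires at least two fragments")
    frs = [f.upper() for f in fragments]
    n = len(frs)

    def overlap(a: str, b: str) -> int:
        """Longest k >= min_overlap with a's 3' k nt == b's 5' k nt."""
        for k in range(min(len(a), len(b)), min_overlap - 1, -1):
            if a[-k:] == b[:k]:
                return k
        return 0

    edges: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n)}
    for i in range(n):
        for j in range(n):
            if i != j:
                k = overlap(frs[i], frs[j])
                if k:
                    edges[i].append((j, k))

    succ: dict[int, tuple[int, int]] = {}
    for i, outs in edges.items():
        if len(outs) > 1:
            raise AssemblyError(f"ambiguous junction at fragment {i}: {len(outs)} partners")
        if outs:
            succ[i] = outs[0]
    targets = {j for j, _ in succ.values()}
    starts = [i for i in range(n) if i not in targets]
    if len(starts) != 1 or len(succ) != n - 1:
        raise AssemblyError(
            f"fragments do not chain into one product ({len(succ)} joins for "
            f"{n} fragments); check the junction overlaps"
        )
    order = [starts[0]]
    while order[-1] in succ:
        order.append(succ[order[-1]][0])
    if len(order) != n:
        raise AssemblyError("overlap graph contains a cycle")

    joined = frs[order[0]]
    for idx in order[1:]:
        k = overlap(joined, frs[idx])
        if not k:
            raise AssemblyError(f"junction into fragment {idx} lost after joining")
        joined = joined + frs[idx][k:]

    product = simulate_pcr(joined, nested_fwd, nested_rev)
    product.provenance = [f"order={order}"] + product.provenance
    return product


@dataclass
class RecombinationResult:
    modified_locus: str
    replaced_interval: tuple[int, int]  # locus coordinates, half-open
    fused_orf: str  # start codon through terminal stop (when found)
    fusion_protein: str  # translated, stop stripped
    in_frame: bool
    stop_check: str  # "single_terminal" | "premature" | "none"


def _scan_orf(modified: str, orf_start: int) -> tuple[str, str]:
    """Translate from orf_start to the first in-frame stop."""
    region = modified[orf_start:]
    usable = region[: len(region) // 3 * 3]
    if len(usable) < 3:
        return "", "none"
    tr = translate(usable)
    if not tr.stop_codon_indices:
        return usable, "none"
    first = tr.stop_codon_indices[0]
    return usable[: 3 * (first + 1)], "single_terminal"


def _default_orf_start(modified: str, core_lo: int, core_hi: int) -> int | None:
    """Longest ATG-initiated ORF overlapping the replaced region."""
    best: tuple[int, int] | None = None  # (length, start)
    for pos in find_substring(modified, "ATG"):
        if pos >= core_hi:
            break
        orf, status = _scan_orf(modified, pos)
        if status != "single_terminal":
            continue
        if pos + len(orf) <= core_lo:
            continue
        if best is None or len(orf) > best[0]:
            best = (len(orf), pos)
    return best[1] if best else None


def simulate_recombination(
    locus: str,
    amplicon: Amplicon | str,
    arm_length: int,
    orf_start: int | None = None,
    expected_orf_length: int | None = None,
) -> RecombinationResult:
    """Double-crossover integration of an amplicon at its homology arms.

    The first and last ``arm_length`` nt of the amplicon must each occur
    exactly once in the locus, left before right; the locus interval between
    the arm matches is replaced by the amplicon's core (zero-length interval
    for pure insertion, positive for deletions). The tagged ORF is
    translated from ``orf_start`` in modified-locus coordinates (for
    N-terminal strategies this is the cassette-internal start codon given by
    the template layout; if omitted, the longest ATG-initiated ORF
    overlapping the integration site is used). ``expected_orf_length``
    (including the stop codon) distinguishes a premature stop from the
    intended terminal one.
    """
    seq = amplicon.sequence if isinstance(amplicon, Amplicon) else amplicon.upper()
    loc = locus.upper()
    if len(seq) < 2 * arm_length:
        raise UsageError(f"amplicon shorter than two {arm_length} nt arms")
    left_arm = seq[:arm_length]
    right_arm = seq[-arm_length:]

    left_hits = find_substring(loc, left_arm)
    right_hits = find_substring(loc, right_arm)
    if len(left_hits) != 1 or len(right_hits) != 1:
        raise MistargetError(
            f"homology arms must match the locus exactly once: left at "
            f"{left_hits}, right at {right_hits}"
        )
    rc_hits = find_substring(loc, revcomp(left_arm)) + find_substring(loc, revcomp(right_arm))
    if rc_hits:
        raise MistargetError(f"arm matches the opposite strand at {rc_hits}: wrong orientation")
    left_end = left_hits[0] + arm_length
    right_start = right_hits[0]
    if left_hits[0] > right_start:
        raise MistargetError("arms match in the wrong order on the locus")
    if right_start < left_end:
        raise MistargetError("arm matches overlap on the locus")

    core = seq[arm_length : len(seq) - arm_length]
    replaced = (left_end, right_start)
    modified = loc[:left_end] + core + loc[right_start:]

    if orf_start is None:
        orf_start = _default_orf_start(modified, left_end, left_end + len(core))
    if orf_start is None:
        return RecombinationResult(modified, replaced, "", "", False, "none")

    fused_orf, status = _scan_orf(modified, orf_start)
    if status == "single_terminal" and expected_orf_length is not None:
        if len(fused_orf) < expected_orf_length:
            status = "premature"
        elif len(fused_orf) > expected_orf_length:
            status = "none"  # ran past the intended stop: frame shifted
    protein = translate(fused_orf).protein.rstrip("*") if fused_orf else ""
    in_frame = status == "single_terminal" and fused_orf[:3] == "ATG"
    return RecombinationResult(modified, replaced, fused_orf, protein, in_frame, status)


# ---------------------------------------------------------------------------
# end-to-end validation


@dataclass
class ValidationReport:
    gene_id: str
    design_kind: str
    passed: bool
    in_frame: bool
    stop_check: str
    protein_length: int
    replaced_interval: tuple[int, int] | None
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    recombination: RecombinationResult | None = field(default=None, repr=False)


def _long_orf_coordinates(
    design: LongPrimerDesign, gene: GeneModel
) -> tuple[int, int]:
    """(orf_start, expected_orf_length incl. stop) in modified-locus coordinates."""
    template = design.template
    f0, r1 = design.template_span
    L = gene.cds_length
    up = gene.cds_start_in_context
    tag_lo, tag_hi = template.tag_orf_span()
    strat = design.strategy

    if strat in (Strategy.C_TAG, Strategy.C_DEL):
        # ORF keeps the native start; cassette supplies linker+tag+stop
        orf_start = up
        prefix = L - 3 if strat is Strategy.C_TAG else design.truncation_point
        expected = prefix + (tag_hi - f0)
    else:
        # cassette supplies the start codon; native CDS supplies the stop
        left_end = up  # upstream arm ends exactly at the CDS start
        orf_start = left_end + (tag_lo - f0)
        resume = 0 if strat is Strategy.N_TAG else design.truncation_point
        expected = (r1 - tag_lo) + (L - resume)
    return orf_start, expected


def _fusion_orf_coordinates(design: FusionDesign, gene: GeneModel) -> tuple[int, int]:
    template = design.template
    up = gene.cds_start_in_context
    L = gene.cds_length
    central = design.central_fragment
    tag_lo, tag_hi = template.tag_orf_span()
    full = template.full_sequence
    frag_start = full.find(central)
    if design.terminus == "C":
        orf_start = up
        expected = (L - 3) + (tag_hi - frag_start)
    else:
        # central fragment ends at the tag's 3' junction; ORF runs into the CDS
        left_end = up  # upstream arm abuts the CDS start
        orf_start = left_end + (tag_lo - frag_start)
        expected = (len(central) - (tag_lo - frag_start)) + L
    return orf_start, expected


def validate_design(
    design: LongPrimerDesign | FusionDesign,
    gene: GeneModel,
    min_anneal: int = DEFAULT_MIN_ANNEAL,
) -> ValidationReport:
    """Chain PCR -> (fusion) -> recombination -> translation for one design.

    Component failures are collected into the report rather than raised.
    """
    errors: list[str] = []
    warnings = list(design.warnings)
    locus = gene.locus_context()
    rec = None

    try:
        if isinstance(design, LongPrimerDesign):
            kind = f"long:{design.strategy.value}"
            amp = simulate_pcr(
                design.template.full_sequence, design.forward, design.reverse, min_anneal
            )
            if amp.sequence != design.predicted_amplicon:
                errors.append("simulated amplicon differs from the design prediction")
            orf_start, expected = _long_orf_coordinates(design, gene)
            rec = simulate_recombination(
                locus, amp, design.homology_length, orf_start, expected
            )
        else:
            kind = f"fusion:{design.terminus}"
            left, right = (
                (design.gene_arm, design.utr_arm)
                if design.terminus == "C"
                else (design.utr_arm, design.gene_arm)
            )
            p_left = simulate_pcr(locus, left.forward, left.reverse, min_anneal)
            p_right = simulate_pcr(locus, right.forward, right.reverse, min_anneal)
            if p_left.sequence != left.predicted_product:
                errors.append("left round-1 product differs from prediction")
            if p_right.sequence != right.predicted_product:
                errors.append("right round-1 product differs from prediction")
            amp = simulate_fusion(
                [p_left.sequence, design.central_fragment, p_right.sequence],
                design.nested_fwd,
                design.nested_rev,
            )
            if amp.sequence != design.predicted_final_amplicon:
                errors.append("fusion product differs from the design prediction")
            arm_check = design.arm_length - max(design.nested_insets)
            orf_start, expected = _fusion_orf_coordinates(design, gene)
            rec = simulate_recombination(locus, amp, arm_check, orf_start, expected)
    except Exception as exc:
        errors.append(f"{type(exc).__name__}: {exc}")

    if rec is None:
        return ValidationReport(
            design.gene_id, kind, False, False, "none", 0, None, errors, warnings
        )
    passed = rec.in_frame and rec.stop_check == "single_terminal" and not errors
    return ValidationReport(
        gene_id=design.gene_id,
        design_kind=kind,
        passed=passed,
        in_frame=rec.in_frame,
        stop_check=rec.stop_check,
        protein_length=len(rec.fusion_protein),
        replaced_interval=rec.replaced_interval,
        errors=errors,
        warnings=warnings,
        recombination=rec,
    )
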