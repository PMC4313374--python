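"""Warning engine: off-target arm homology, terminal-feature flags,
ORF-confidence labels, customizable severities.

Signal-peptide and GPI-anchor calls are consumed from a user-supplied
annotation table, never predicted here. Off-target scanning is
seed-and-extend: every exact 20-mer match of a homology arm outside the
intended locus is extended ungapped in both directions, and hits whose
identity over the full arm length reaches ``min_identity`` are reported.
0.90 over the full arm is this package's operationalization of "high
homology between ORFs"; it is configurable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import LookupError_, UsageError
from .genome_io import GeneModel, Genome
from .seqcore import revcomp

DEFAULT_SEED_LENGTH = 20
DEFAULT_MIN_IDENTITY = 0.90


class WarningCode(str, enum.Enum):
    OFF_TARGET_ARM = "OFF_TARGET_ARM"
    SIGNAL_PEPTIDE_N = "SIGNAL_PEPTIDE_N"
    GPI_ANCHOR_C = "GPI_ANCHOR_C"
    ORF_LOW_CONFIDENCE = "ORF_LOW_CONFIDENCE"
    SHORT_FLANK = "SHORT_FLANK"
    NON_ATG_START = "NON_ATG_START"
    ENZYME_CONFLICT = "ENZYME_CONFLICT"
    BELOW_RECOMMENDED_HOMOLOGY = "BELOW_RECOMMENDED_HOMOLOGY"


#: default severity per code; overridable via the ``config`` mapping
DEFAULT_SEVERITIES: dict[WarningCode, str] = {
    WarningCode.OFF_TARGET_ARM: "warn",
    WarningCode.SIGNAL_PEPTIDE_N: "warn",
    WarningCode.GPI_ANCHOR_C: "warn",
    WarningCode.ORF_LOW_CONFIDENCE: "warn",
    WarningCode.SHORT_FLANK: "warn",
    WarningCode.NON_ATG_START: "warn",
    WarningCode.ENZYME_CONFLICT: "warn",
    WarningCode.BELOW_RECOMMENDED_HOMOLOGY: "info",
}


@dataclass
class QcWarning:
    code: WarningCode
    severity: str
    gene_id: str
    message: str
    evidence: dict = field(default_factory=dict)

    def __str__(self) -> str:
        return f"[{self.severity}] {self.code.value} {self.gene_id}: {self.message}"


@dataclass
class OffTargetHit:
    chromosome: str
    position: int  # 0-based start of the aligned window on the top strand
    strand: str
    identity: float
    low_complexity: bool = False


@dataclass
class FeatureAnnotation:
    gene_id: str
    signal_peptide: bool
    gpi_anchor: bool
    orf_confidence: str  # supported | dubious | unknown


def load_annotations(
    path: str | Path, genome: Genome | None = None
) -> dict[str, FeatureAnnotation]:
    """Read the TSV feature table (gene_id, signal_peptide, gpi_anchor,
    orf_confidence); unknown gene ids are rejected when a genome is given."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise UsageError(f"cannot parse annotation table {path}: {exc}") from exc
    required = {"gene_id", "signal_peptide", "gpi_anchor", "orf_confidence"}
    missing = required - set(df.columns)
    if missing:
        raise UsageError(f"annotation table lacks columns: {sorted(missing)}")
    out: dict[str, FeatureAnnotation] = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        gid = str(row.gene_id)
        if gid in out:
            raise UsageError(f"annotation table line {lineno}: duplicate gene id {gid!r}")
        conf = str(row.orf_confidence)
        if conf not in ("supported", "dubious", "unknown"):
            raise UsageError(
                f"annotation table line {lineno}: bad orf_confidence {conf!r}"
            )
        if genome is not None and gid not in genome.genes:
            raise LookupError_(
                f"annotation table line {lineno}: unknown gene id {gid!r}"
            )
        out[gid] = FeatureAnnotation(
            gid,
            str(row.signal_peptide).strip() in ("1", "true", "True", "yes"),
            str(row.gpi_anchor).strip() in ("1", "true", "True", "yes"),
            conf,
        )
    return out


def _is_low_complexity(arm: str) -> bool:
    """Flag arms dominated by a single base (homopolymer-like)."""
    up = arm.upper()
    return max(up.count(b) for b in "ACGT") >= 0.8 * len(up)


def _identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _scan_strand(
    arm: str,
    chrom_name: str,
    chrom: str,
    strand: str,
    exclude: tuple[int, int] | None,
    seed: int,
    min_identity: float,
    hits: dict[tuple[str, int, str], OffTargetHit],
) -> None:
    """Seed-and-extend one arm orientation against one chromosome top strand."""
    n, m = len(chrom), len(arm)
    index: dict[str, list[int]] = {}
    for p in range(m - seed + 1):
        index.setdefault(arm[p : p + seed], []).append(p)
    seen_offsets: set[int] = set()
    for g in range(n - seed + 1):
        kmer = chrom[g : g + seed]
        for p in index.get(kmer, ()):
            offset = g - p  # window start for a full-arm ungapped alignment
            if offset in seen_offsets or offset < 0 or offset + m > n:
                continue
            seen_offsets.add(offset)
            if exclude is not None and not (
                offset + m <= exclude[0] or offset >= exclude[1]
            ):
                continue
            ident = _identity(arm, chrom[offset : offset + m])
            if ident >= min_identity:
                key = (chrom_name, offset, strand)
                prev = hits.get(key)
                if prev is None or ident > prev.identity:
                    hits[key] = OffTargetHit(
                        chrom_name, offset, strand, ident, _is_low_complexity(arm)
                    )


def scan_off_target(
    arm: str,
    genome: Genome,
    intended: tuple[str, int, int] | None = None,
    seed: int = DEFAULT_SEED_LENGTH,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[OffTargetHit]:
    """Find near-identical copies of a homology arm outside the intended locus.

    ``intended`` is (chromosome, start, end) of the locus the arm is meant to
    target; windows overlapping it are skipped. Both strands are scanned.
    Returns hits sorted by (chromosome, position, strand).
    """
    arm = arm.upper()
    if len(arm) < seed:
        raise UsageError(f"arm ({len(arm)} nt) shorter than the seed length {seed}")
    hits: dict[tuple[str, int, str], OffTargetHit] = {}
    for chrom_name, chrom in genome.sequences.items():
        exclude = None
        if intended is not None and intended[0] == chrom_name:
            exclude = (intended[1], intended[2])
        _scan_strand(arm, chrom_name, chrom, "+", exclude, seed, min_identity, hits)
        _scan_strand(
            revcomp(arm), chrom_name, chrom, "-", exclude, seed, min_identity, hits
        )
    return sorted(hits.values(), key=lambda h: (h.chromosome, h.position, h.strand))


def _arm_intervals(design, gene: GeneModel) -> list[tuple[str, str]]:
    """(label, arm sequence) pairs whose genomic copies direct integration."""
    from .design_fusion import FusionDesign
    from .design_long import LongPrimerDesign
    from .seqcore import revcomp as _rc

    if isinstance(design, LongPrimerDesign):
        return [
            ("forward arm", design.forward.homology_segment),
            ("reverse arm", _rc(design.reverse.homology_segment)),
        ]
    if isinstance(design, FusionDesign):
        return [
            ("gene arm", design.gene_arm.sequence),
            ("utr arm", design.utr_arm.sequence),
        ]
    return []


def evaluate_warnings(
    design,
    gene: GeneModel,
    genome: Genome | None = None,
    annotations: dict[str, FeatureAnnotation] | None = None,
    config: dict | None = None,
) -> list[QcWarning]:
    """Assemble the warning list for one design.

    N-terminal strategies on signal-peptide genes and C-terminal strategies
    on GPI-anchored genes are flagged (the respective terminus is unsuitable
    for tagging); dubious ORFs, truncated flanks, non-ATG starts,
    sub-recommended homology and enzyme conflicts are carried through; when
    a genome is supplied each homology arm is scanned for off-targets.
    Output ordering is deterministic: by code, then position. Absent
    annotations are not an error.
    """
    severities = dict(DEFAULT_SEVERITIES)
    for key, val in (config or {}).items():
        severities[WarningCode(key)] = val

    def make(code: WarningCode, message: str, **evidence) -> QcWarning:
        return QcWarning(code, severities[code], gene.gene_id, message, evidence)

    out: list[QcWarning] = []
    strategy = getattr(design, "strategy", None)
    terminus = getattr(design, "terminus", None)
    n_terminal = terminus == "N" or (
        strategy is not None and strategy.value in ("N_TAG", "N_DEL")
    )
    c_terminal = terminus == "C" or (
        strategy is not None and strategy.value in ("C_TAG", "C_DEL")
    )

    ann = (annotations or {}).get(gene.gene_id)
    if ann is not None:
        if n_terminal and ann.signal_peptide:
            out.append(
                make(
                    WarningCode.SIGNAL_PEPTIDE_N,
                    "predicted signal peptide: the N-terminus is unsuitable for tagging",
                )
            )
        if c_terminal and ann.gpi_anchor:
            out.append(
                make(
                    WarningCode.GPI_ANCHOR_C,
                    "predicted GPI-anchor addition site: the C-terminus is "
                    "unsuitable for tagging",
                )
            )
        if ann.orf_confidence == "dubious":
            out.append(
                make(WarningCode.ORF_LOW_CONFIDENCE, "ORF annotation flagged dubious")
            )

    for w in gene.warnings:
        if "truncated" in w:
            out.append(make(WarningCode.SHORT_FLANK, w))
        elif "ATG" in w:
            out.append(make(WarningCode.NON_ATG_START, w))

    for w in getattr(design, "warnings", []):
        if w.startswith("ENZYME_CONFLICT"):
            out.append(make(WarningCode.ENZYME_CONFLICT, w))
        elif w.startswith("BELOW_RECOMMENDED_HOMOLOGY"):
            out.append(make(WarningCode.BELOW_RECOMMENDED_HOMOLOGY, w))

    if genome is not None:
        lo, hi = gene.cds_interval
        pad = gene.flank_length
        intended = (gene.chromosome, max(0, lo - pad), hi + pad)
        for label, arm in _arm_intervals(design, gene):
            for hit in scan_off_target(arm, genome, intended):
                out.append(
                    make(
                        WarningCode.OFF_TARGET_ARM,
                        f"{label} matches {hit.chromosome}:{hit.position}({hit.strand}) "
                        f"at {hit.identity:.1%} identity"
                        + (" [low-complexity arm]" if hit.low_complexity else ""),
                        chromosome=hit.chromosome,
                        position=hit.position,
                        strand=hit.strand,
                        identity=hit.identity,
                    )
                )

    order = {c: i for i, c in enumerate(WarningCode)}
    out.sort(key=lambda w: (order[w.code], w.evidence.get("position", -1), w.message))
    return out
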