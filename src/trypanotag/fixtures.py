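"""Synthetic-data generator: genomes, gene models, paralogs and placeholder
plasmids with the structure the design and simulation modules assume.

Genomes emulate the features the tagging workflow relies on: single-exon
ATG-initiated CDS with a single terminal stop on both strands, long
CDS-adjacent intergenic flanks, and optional paralogs at a controlled
percent identity (for off-target scanning). They do not emulate realistic
trypanosomatid codon usage or polycistronic transcription units.

Plasmid placeholder bodies are random sequence filtered against every
registry enzyme site and against collisions with the published annealing
strings (including their 15-nt 3'-terminal cores, so in-silico primer
binding stays unambiguous). Identical spec + seed give byte-identical
output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .enzymes import REGISTRY
from .errors import FixtureSpecError, RegistryError
from .plasmids import ANNEAL_TABLE, FWD_ROLES, PlasmidTemplate
from .seqcore import STOP_CODONS, find_substring, revcomp

_BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


# ---------------------------------------------------------------------------
# low-level sequence generation

def _rand_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]  # A C G T
    return "".join(rng.choice(_BASES, size=n, p=probs))


def _rand_codons(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons)
    return "".join(_NONSTOP_CODONS[i] for i in idx)


def _forbidden_strings() -> list[str]:
    out = {e.site for e in REGISTRY.values()}
    for s in ANNEAL_TABLE.values():
        up = s.upper()
        for probe in (up, up[-15:]):
            out.add(probe)
            out.add(revcomp(probe))
    return sorted(out)


_FORBIDDEN = _forbidden_strings()


@dataclass
class _Part:
    name: str
    seq: str
    mutable: bool


def _assemble_clean(
    parts: list[_Part],
    orf_spans: list[tuple[str, str]],
    rng: np.random.Generator,
    max_rounds: int = 20000,
) -> list[tuple[str, str]]:
    """Iteratively mutate mutable parts until no accidental enzyme site,
    annealing-string collision, or premature frame-0 stop remains.

    ``orf_spans`` name (first_part, last_part) reading frames scanned for
    frame-0 stops; only the final codon of a span may be a stop. Forbidden
    substrings lying entirely inside immutable parts are intentional layout
    features and are left alone.
    """

    def offsets() -> dict[str, tuple[int, int]]:
        pos, spans = 0, {}
        for p in parts:
            spans[p.name] = (pos, pos + len(p.seq))
            pos += len(p.seq)
        return spans

    def mutate_at(abs_pos: int, spans: dict[str, tuple[int, int]]) -> bool:
        for p in parts:
            s, e = spans[p.name]
            if p.mutable and s <= abs_pos < e:
                local = abs_pos - s
                old = p.seq[local]
                new = str(rng.choice([b for b in "ACGT" if b != old]))
                p.seq = p.seq[:local] + new + p.seq[local + 1 :]
                return True
        return False

    for _ in range(max_rounds):
        spans = offsets()
        seq = "".join(p.seq for p in parts)
        mutable_mask = [False] * len(seq)
        for p in parts:
            if p.mutable:
                s, e = spans[p.name]
                for i in range(s, e):
                    mutable_mask[i] = True

        issue_pos = None
        for probe in _FORBIDDEN:
            for hit in find_substring(seq, probe):
                span = range(hit, hit + len(probe))
                mut = [i for i in span if mutable_mask[i]]
                if mut:
                    issue_pos = mut[0]
                    break
                # occurrence entirely within fixed parts: intentional
            if issue_pos is not None:
                break

        if issue_pos is None:
            for first, last in orf_spans:
                s = spans[first][0]
                e = spans[last][1]
                orf = seq[s:e]
                for k in range((e - s) // 3 - 1):  # all but the final codon
                    if orf[3 * k : 3 * k + 3] in STOP_CODONS:
                        cand = [s + 3 * k + j for j in range(3) if mutable_mask[s + 3 * k + j]]
                        if not cand:
                            raise FixtureSpecError(
                                f"immutable premature stop in ORF span {first}..{last}"
                            )
                        issue_pos = cand[0]
                        break
                if issue_pos is not None:
                    break

        if issue_pos is None:
            return [(p.name, p.seq) for p in parts]
        if not mutate_at(issue_pos, spans):
            raise FixtureSpecError("could not repair fixture sequence")
    raise FixtureSpecError("placeholder scrubbing did not converge")


def _template_rng(name: str) -> np.random.Generator:
    # fixed per-name seed: built-in templates are identical across runs
    return np.random.default_rng(zlib.crc32(("trypanotag:" + name).encode()) & 0x7FFFFFFF)


def _orf(rng: np.random.Generator, n_codons: int = 100) -> str:
    return "ATG" + _rand_codons(rng, n_codons - 2) + "TAA"


def _gs_codons(rng: np.random.Generator, n_codons: int) -> str:
    pool = ["GGA", "GGT", "GGC", "TCT", "TCC", "AGC", "TCA", "AGT"]
    return "".join(pool[i] for i in rng.integers(0, len(pool), size=n_codons))


# ---------------------------------------------------------------------------
# plasmid templates

def _anneal(family: str, role: str) -> str:
    key = ("pPOT", role) if ("pPOT", role) in ANNEAL_TABLE else (family, role)
    return ANNEAL_TABLE[key]


def _build_ppotv4() -> PlasmidTemplate:
    rng = _template_rng("pPOTv4")
    fwd = _anneal("pPOTv4", "fwd_outer").upper()
    rev = _anneal("pPOTv4", "rev_outer")
    l5 = _anneal("pPOTv4", "linker5_fwd").upper()
    l3 = _anneal("pPOTv4", "linker3_rev")
    parts = [
        _Part("fwd_site", fwd, False),
        _Part("actin_5utr_a", _rand_seq(rng, 120), True),
        _Part("bsr", _orf(rng), True),
        _Part("aldolase_3utr_a", _rand_seq(rng, 120), True),
        _Part("actin_5utr_b", _rand_seq(rng, 120), True),
        _Part("kpnI_site", "GGTACC", False),
        _Part("gs_linker_5", "ATG" + l5 + _gs_codons(rng, 13), True),
        _Part("hindIII_site", "AAGCTT", False),
        _Part("tag", _rand_codons(rng, 80), True),
        _Part("bamHI_site", "GGATCC", False),
        _Part("gs_linker_3", _gs_codons(rng, 14) + revcomp(l3).upper(), True),
        _Part("tag_stop", "TAA", False),
        _Part("pfr2_3utr", _rand_seq(rng, 120), True),
        _Part("aldolase_5utr", _rand_seq(rng, 120), True),
        _Part("hpt", _orf(rng), True),
        _Part("aldolase_3utr_b", _rand_seq(rng, 120), True),
        _Part("rev_site", revcomp(rev).upper(), False),
    ]
    # keep the embedded annealing cores and cassette frame intact while scrubbing
    for p in parts:
        if p.name in ("gs_linker_5", "gs_linker_3"):
            p.mutable = False
    elements = _assemble_clean(
        parts,
        orf_spans=[("bsr", "bsr"), ("gs_linker_5", "tag_stop"), ("hpt", "hpt")],
        rng=rng,
    )
    t = PlasmidTemplate(
        name="pPOTv4",
        family="pPOTv4",
        elements=elements,
        anneal_sites={
            "fwd_outer": _anneal("pPOTv4", "fwd_outer"),
            "rev_outer": rev,
            "linker5_fwd": _anneal("pPOTv4", "linker5_fwd"),
            "linker3_rev": l3,
        },
        tag_name="eYFP",
        resistance_names=("bsr", "hpt"),
    )
    t.validate()
    return t


def _build_ppotv2() -> PlasmidTemplate:
    rng = _template_rng("pPOTv2")
    fwd = _anneal("pPOTv2", "fwd_outer").upper()
    rev = _anneal("pPOTv2", "rev_outer")
    tag_fwd = _anneal("pPOTv2", "tag_fwd")
    tag_rev = _anneal("pPOTv2", "tag_rev")
    parts = [
        _Part("fwd_site", fwd, False),
        _Part("actin_5utr_a", _rand_seq(rng, 120), True),
        _Part("ecoRI_site", "GAATTC", False),
        _Part("bsr", _orf(rng), True),
        _Part("aldolase_3utr_a", _rand_seq(rng, 120), True),
        _Part("actin_5utr_b", _rand_seq(rng, 120), True),
        _Part("tag_start", "ATG", False),
        _Part("ty_n", _rand_codons(rng, 10), True),
        _Part("tag5_anneal", tag_fwd.upper(), False),
        _Part("tag_body", _rand_seq(rng, 210), True),
        _Part("tag3_anneal", revcomp(tag_rev).upper(), False),
        _Part("ty_c", _rand_codons(rng, 10), True),
        _Part("xbaI_site", "TCTAGA", False),
        _Part("tag_stop", "TAA", False),
        _Part("pfr2_3utr", _rand_seq(rng, 120), True),
        _Part("aldolase_5utr", _rand_seq(rng, 120), True),
        _Part("hpt", _orf(rng), True),
        _Part("aldolase_3utr_b", _rand_seq(rng, 120), True),
        _Part("rev_site", revcomp(rev).upper(), False),
    ]
    elements = _assemble_clean(
        parts,
        orf_spans=[("bsr", "bsr"), ("tag_start", "tag_stop"), ("hpt", "hpt")],
        rng=rng,
    )
    t = PlasmidTemplate(
        name="pPOTv2",
        family="pPOTv2",
        elements=elements,
        anneal_sites={
            "fwd_outer": _anneal("pPOTv2", "fwd_outer"),
            "rev_outer": rev,
            "tag_fwd": tag_fwd,
            "tag_rev": tag_rev,
        },
        tag_name="Ty::eYFP::Ty",
        resistance_names=("bsr", "hpt"),
    )
    t.validate()
    return t


_PLENT_TAGS = {"Y": "eYFP", "T": "dTomFP", "C": "CFP"}
_PLENT_DRUGS = {"B": "bsr", "N": "neo", "P": "pac"}


def _build_plent(name: str) -> PlasmidTemplate:
    code = name.split("-", 1)[1]
    tag_name = _PLENT_TAGS[code[0]]
    drug_name = _PLENT_DRUGS[code[1]]
    rng = _template_rng(name)
    tag_rng = _template_rng("pLENT-tag-" + tag_name)
    drug_rng = _template_rng("pLENT-drug-" + drug_name)
    parts = [
        _Part("pgkb_5utr_a", _rand_seq(rng, 120), True),
        # the tag element must keep its leading SpeI site (fragment boundary):
        # scrub only the body, merge the two parts into one element afterwards
        _Part("tag_site", "ACTAGT", False),
        _Part("tag_body", _rand_codons(tag_rng, 80) + "TAA", True),
        _Part("xbaI_site", "TCTAGA", False),
        _Part("bamHI_site", "GGATCC", False),
        _Part("pgka_3utr", _rand_seq(rng, 120), True),
        _Part("nheI_site", "GCTAGC", False),
        _Part("pgkb_5utr_b", _rand_seq(rng, 120), True),
        _Part("ecoRI_site", "GAATTC", False),
        _Part("resistance", _orf(drug_rng), True),
        _Part("ncoI_site", "CCATGG", False),
        _Part("hindIII_site", "AAGCTT", False),
        _Part("gss_3utr", _rand_seq(rng, 120), True),
        _Part("backbone", _rand_seq(rng, 300), True),
    ]
    scrubbed = _assemble_clean(
        parts,
        orf_spans=[("tag_site", "tag_body"), ("resistance", "resistance")],
        rng=rng,
    )
    by_name = dict(scrubbed)
    elements = []
    for el_name, seq in scrubbed:
        if el_name == "tag_site":
            elements.append(("tag", seq + by_name["tag_body"]))
        elif el_name == "tag_body":
            continue
        else:
            elements.append((el_name, seq))
    t = PlasmidTemplate(
        name=name,
        family="pLENTv2",
        elements=elements,
        anneal_sites={},
        tag_name=tag_name,
        resistance_names=(drug_name,),
    )
    return t


def make_plasmid(layout: str) -> PlasmidTemplate:
    """Build a named template with synthetic element bodies.

    Layouts: "pPOTv2", "pPOTv4", or "pLENTv2-XY" with X in {Y,T,C} (tag) and
    Y in {B,N,P} (resistance). Deterministic: the same layout always yields
    byte-identical sequence.
    """
    if layout == "pPOTv4":
        return _build_ppotv4()
    if layout == "pPOTv2":
        return _build_ppotv2()
    if layout.startswith("pLENTv2-"):
        code = layout.split("-", 1)[1]
        if len(code) == 2 and code[0] in _PLENT_TAGS and code[1] in _PLENT_DRUGS:
            return _build_plent(layout)
    raise RegistryError(f"unknown template layout {layout!r}")


# ---------------------------------------------------------------------------
# genomes

@dataclass
class FixtureSpec:
    """Parameters of a synthetic genome.

    ``paralog_specs`` entries are (source gene id or 0-based index, identity
    fraction); each adds one extra gene derived from the source CDS by
    per-base mutation at rate 1 - identity. ``strand_mix`` is the fraction
    of genes placed on the '-' strand.
    """

    n_genes: int = 20
    cds_length_range: tuple[int, int] = (300, 900)
    intergenic_length_range: tuple[int, int] = (2100, 2700)
    gc_fraction: float = 0.45
    paralog_specs: list[tuple[object, float]] = field(default_factory=list)
    strand_mix: float = 0.4
    seed: int = 0
    contig_name: str = "chr1"


def _mutate_cds(cds: str, identity: float, rng: np.random.Generator) -> str:
    rate = 1.0 - identity
    bases = list(cds)
    for i in range(len(bases)):
        if rng.random() < rate:
            bases[i] = str(rng.choice([b for b in "ACGT" if b != bases[i]]))
    # restore start/stop, remove any internal frame-0 stop the mutation created
    bases[0:3] = list("ATG")
    bases[-3:] = list(cds[-3:])
    seq = "".join(bases)
    for k in range(1, len(seq) // 3 - 1):
        if seq[3 * k : 3 * k + 3] in STOP_CODONS:
            seq = seq[: 3 * k + 2] + "C" + seq[3 * k + 3 :]
    return seq


def build_genome(spec: FixtureSpec) -> dict:
    """Construct the genome in memory.

    Returns a dict with 'fasta', 'gff3' and 'annotations' text plus a
    'genes' table of (gene_id, strand, cds) ground truth.
    """
    if spec.n_genes < 1:
        raise FixtureSpecError("n_genes must be >= 1")
    lo, hi = spec.cds_length_range
    ig_lo, ig_hi = spec.intergenic_length_range
    if lo < 9 or hi < lo or ig_lo < 1 or ig_hi < ig_lo:
        raise FixtureSpecError("length ranges must be positive and ordered")

    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"Tsyn{i + 1:04d}" for i in range(spec.n_genes)]
    cds_by_id: dict[str, str] = {}
    for gid in gene_ids:
        n = int(rng.integers(lo, hi + 1)) // 3 * 3
        n = max(n, 9)
        stop = ["TAA", "TAG", "TGA"][int(rng.integers(0, 3))]
        cds_by_id[gid] = "ATG" + _rand_codons(rng, n // 3 - 2) + stop

    # paralogs are appended after the primary genes
    entries: list[tuple[str, str]] = list(cds_by_id.items())
    for k, (src, identity) in enumerate(spec.paralog_specs):
        if isinstance(src, int):
            if not 0 <= src < spec.n_genes:
                raise FixtureSpecError(f"paralog source index {src} out of range")
            src_id = gene_ids[src]
        else:
            src_id = str(src)
            if src_id not in cds_by_id:
                raise FixtureSpecError(f"paralog source gene {src_id!r} absent")
        if not 0.0 < identity <= 1.0:
            raise FixtureSpecError(f"paralog identity {identity} outside (0, 1]")
        pid = f"{src_id}p{k + 1}"
        entries.append((pid, _mutate_cds(cds_by_id[src_id], identity, rng)))

    chrom_parts: list[str] = []
    features: list[tuple[str, int, int, str]] = []  # gene_id, start, end, strand
    pos = 0
    for gid, cds in entries:
        spacer = _rand_seq(rng, int(rng.integers(ig_lo, ig_hi + 1)), spec.gc_fraction)
        chrom_parts.append(spacer)
        pos += len(spacer)
        strand = "-" if rng.random() < spec.strand_mix else "+"
        genomic = cds if strand == "+" else revcomp(cds)
        chrom_parts.append(genomic)
        features.append((gid, pos, pos + len(cds), strand))
        pos += len(cds)
    tail = _rand_seq(rng, int(rng.integers(ig_lo, ig_hi + 1)), spec.gc_fraction)
    chrom_parts.append(tail)
    chromosome = "".join(chrom_parts)

    fasta_lines = [f">{spec.contig_name}"]
    for i in range(0, len(chromosome), 70):
        fasta_lines.append(chromosome[i : i + 70])
    fasta = "\n".join(fasta_lines) + "\n"

    gff_lines = ["##gff-version 3"]
    for gid, start, end, strand in features:
        s1, e1 = start + 1, end  # to 1-based inclusive
        c = spec.contig_name
        gff_lines.append(f"{c}\ttrypanotag\tgene\t{s1}\t{e1}\t.\t{strand}\t.\tID={gid}")
        gff_lines.append(
            f"{c}\ttrypanotag\tmRNA\t{s1}\t{e1}\t.\t{strand}\t.\tID={gid}.1;Parent={gid}"
        )
        gff_lines.append(
            f"{c}\ttrypanotag\tCDS\t{s1}\t{e1}\t.\t{strand}\t0\tID={gid}.1.cds;Parent={gid}.1"
        )
    gff3 = "\n".join(gff_lines) + "\n"

    conf_levels = ["supported", "dubious", "unknown"]
    ann_lines = ["gene_id\tsignal_peptide\tgpi_anchor\torf_confidence"]
    for gid, _ in entries:
        sp = int(rng.random() < 0.2)
        gpi = int(rng.random() < 0.15)
        conf = conf_levels[int(rng.choice([0, 0, 0, 0, 0, 1, 2]))]
        ann_lines.append(f"{gid}\t{sp}\t{gpi}\t{conf}")
    annotations = "\n".join(ann_lines) + "\n"

    return {
        "fasta": fasta,
        "gff3": gff3,
        "annotations": annotations,
        "genes": [(gid, strand, cds) for (gid, cds), (_, _, _, strand) in zip(entries, features)],
        "chromosome": chromosome,
    }


def make_genome(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write genome.fasta, genome.gff3 and annotations.tsv; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    built = build_genome(spec)
    paths = {
        "fasta": out / "genome.fasta",
        "gff3": out / "genome.gff3",
        "annotations": out / "annotations.tsv",
    }
    paths["fasta"].write_text(built["fasta"])
    paths["gff3"].write_text(built["gff3"])
    paths["annotations"].write_text(built["annotations"])
    return paths
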