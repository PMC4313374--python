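"""Plasmid template registry: pPOTv2, pPOTv4 and the pLENTv2 variants.

A :class:`PlasmidTemplate` is an ordered 5'->3' cassette layout (named
elements with sequences) plus the published primer-annealing strings. The
full plasmid sequences are not published, so built-in templates carry
deterministic synthetic placeholder bodies for the UTR/tag/resistance
elements, with the published annealing strings and the canonical restriction
sites embedded at the correct junctions. All design arithmetic depends only
on annealing-site positions and element boundaries, so placeholder bodies
are safe; real sequences can be supplied via a GenBank-style feature file.

Annealing-site orientation convention: a "fwd" site is stored as the primer
suffix and occurs verbatim on the template top strand; a "rev" site is
stored as the primer suffix (5'->3' as synthesized) and therefore occurs as
its reverse complement on the top strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .errors import DigestError, FrameError, RegistryError
from .seqcore import find_sites, find_substring, frame0_stop_codon_positions, revcomp

# The published annealing strings, keyed by (plasmid family, role).
# Stored exactly as printed (lower case); unit-tested as string equality.
ANNEAL_TABLE: dict[tuple[str, str], str] = {
    ("pPOT", "fwd_outer"): "gtataatgcagacctgctgc",
    ("pPOT", "rev_outer"): "ccaatttgagagacctgtgc",
    ("pPOTv4", "linker3_rev"): "actacccgatcctgatcc",
    ("pPOTv4", "linker5_fwd"): "ggttctggtagtggttcc",
    ("pPOTv2", "tag_rev"): "cttgtacagctcgtccatgc",
    ("pPOTv2", "tag_fwd"): "actagtgtgagcaagg",
}

# role name -> orientation on the template top strand
FWD_ROLES = {"fwd_outer", "linker5_fwd", "tag_fwd"}
REV_ROLES = {"rev_outer", "linker3_rev", "tag_rev"}


@dataclass
class PlasmidTemplate:
    """Symbolic cassette layout plus annealing sites and full sequence."""

    name: str
    family: str  # "pPOTv4", "pPOTv2" or "pLENTv2"
    elements: list[tuple[str, str]]  # ordered (element_name, sequence), 5'->3'
    anneal_sites: dict[str, str]  # role -> primer-suffix string (as synthesized)
    tag_name: str = "eYFP"
    resistance_names: tuple[str, ...] = ()
    internal_insert: tuple[str, str] | None = None  # (side, insert sequence)
    provenance: str = "synthetic placeholder bodies"
    _seq_cache: str | None = field(default=None, repr=False, compare=False)

    @property
    def full_sequence(self) -> str:
        if self._seq_cache is None:
            self._seq_cache = "".join(seq for _, seq in self.elements).upper()
        return self._seq_cache

    def element_span(self, element_name: str) -> tuple[int, int]:
        """Half-open span of a named element in full_sequence."""
        pos = 0
        for name, seq in self.elements:
            if name == element_name:
                return pos, pos + len(seq)
            pos += len(seq)
        raise RegistryError(f"template {self.name!r} has no element {element_name!r}")

    def has_element(self, element_name: str) -> bool:
        return any(name == element_name for name, _ in self.elements)

    def anneal_site_span(self, role: str) -> tuple[int, int]:
        """Unique top-strand span of an annealing site (revcomp'd for rev roles)."""
        try:
            primer_suffix = self.anneal_sites[role]
        except KeyError:
            raise RegistryError(
                f"template {self.name!r} has no annealing role {role!r}"
            ) from None
        top = primer_suffix if role in FWD_ROLES else revcomp(primer_suffix)
        hits = find_substring(self.full_sequence, top)
        if len(hits) != 1:
            raise RegistryError(
                f"annealing site {role!r} occurs {len(hits)} times in {self.name!r}"
            )
        return hits[0], hits[0] + len(top)

    def tag_orf_span(self) -> tuple[int, int]:
        """Span of the cassette's tag reading frame (start codon through stop).

        For pPOTv4 the ORF begins at the 5' GS linker element (which carries
        the start codon) or at an internal insert replacing it; for pPOTv2 at
        the tag cassette start codon. pLENT tags carry no start codon (they
        are fused C-terminally), so the span begins at the tag element.
        """
        if self.family == "pPOTv4":
            start_el = "internal_insert" if (
                self.internal_insert and self.internal_insert[0] == "5prime"
            ) else "gs_linker_5"
            return self.element_span(start_el)[0], self.element_span("tag_stop")[1]
        if self.family == "pPOTv2":
            return self.element_span("tag_start")[0], self.element_span("tag_stop")[1]
        if self.family == "pLENTv2":
            return self.element_span("tag")
        raise RegistryError(f"unknown template family {self.family!r}")

    def validate(self) -> None:
        """Assert every annealing site occurs exactly once, correctly oriented."""
        for role in self.anneal_sites:
            self.anneal_site_span(role)


def insert_internal_element(
    template: PlasmidTemplate, insert: str, side: str = "5prime"
) -> PlasmidTemplate:
    """Return a modified pPOTv4-family template for internal tagging.

    The 5' (or 3') GS-linker element is replaced by ``insert`` (e.g. a signal
    peptide coding sequence) in frame with the tag; the replaced linker's
    annealing role is disabled, because the corresponding primer now follows
    the internal-tag rule instead.
    """
    if template.family != "pPOTv4":
        raise RegistryError(
            f"internal tagging requires a pPOTv4-family template, got {template.family!r}"
        )
    if side not in ("5prime", "3prime"):
        raise FrameError(f"side must be '5prime' or '3prime', got {side!r}")
    insert = insert.upper()
    if len(insert) == 0:
        raise FrameError("empty insert: zero-length replacement is not the internal-tag workflow")
    if len(insert) % 3 != 0:
        raise FrameError(f"insert length {len(insert)} is not a multiple of 3")
    if frame0_stop_codon_positions(insert):
        raise FrameError("insert contains a frame-0 stop codon")

    target = "gs_linker_5" if side == "5prime" else "gs_linker_3"
    disabled_role = "linker5_fwd" if side == "5prime" else "linker3_rev"
    if not template.has_element(target):
        raise RegistryError(f"template {template.name!r} has no {target} element")

    new_elements = [
        ("internal_insert", insert) if name == target else (name, seq)
        for name, seq in template.elements
    ]
    new_sites = {k: v for k, v in template.anneal_sites.items() if k != disabled_role}
    return replace(
        template,
        name=f"{template.name}+internal",
        elements=new_elements,
        anneal_sites=new_sites,
        internal_insert=(side, insert),
        _seq_cache=None,
    )


def swap_tag(
    template: PlasmidTemplate, new_tag: str, tag_name: str = "custom"
) -> PlasmidTemplate:
    """Replace the tag element body of a pPOTv4-family template.

    Because every pPOTv4 annealing site lies outside the tag element, the
    same long primer pair targets a gene with any tag - this operation is
    the modular exchange that property rests on. The replacement must be a
    codon-multiple with no frame-0 stop.
    """
    if template.family != "pPOTv4":
        raise RegistryError(
            "tag exchange without primer redesign is a pPOTv4-family property"
        )
    new_tag = new_tag.upper()
    if len(new_tag) % 3 != 0:
        raise FrameError(f"tag length {len(new_tag)} is not a multiple of 3")
    if frame0_stop_codon_positions(new_tag):
        raise FrameError("replacement tag contains a frame-0 stop codon")
    elements = [
        ("tag", new_tag) if name == "tag" else (name, seq)
        for name, seq in template.elements
    ]
    out = replace(
        template, name=f"{template.name}:{tag_name}", elements=elements,
        tag_name=tag_name, _seq_cache=None,
    )
    out.validate()
    return out


def digest_release(template: PlasmidTemplate, enzyme5: str, enzyme3: str) -> str:
    """Fragment released by a double digest, between the two cut positions.

    Both enzymes must cut the template exactly once, with the ``enzyme5`` cut
    5' of the ``enzyme3`` cut. Fragments are reported between recognition-site
    start positions (blunt abstraction): overhang chemistry does not affect
    any downstream design arithmetic, and this keeps in-silico fragments
    reproducible bit-exactly.
    """
    seq = template.full_sequence
    sites5 = find_sites(seq, enzyme5)
    sites3 = find_sites(seq, enzyme3)
    if len(sites5) != 1:
        raise DigestError(
            f"{enzyme5} cuts {template.name!r} {len(sites5)} times (need exactly 1)"
        )
    if len(sites3) != 1:
        raise DigestError(
            f"{enzyme3} cuts {template.name!r} {len(sites3)} times (need exactly 1)"
        )
    if not sites5[0] < sites3[0]:
        raise DigestError(
            f"{enzyme5} site ({sites5[0]}) is not 5' of {enzyme3} site ({sites3[0]})"
        )
    return seq[sites5[0] : sites3[0]]


def get_template(name: str) -> PlasmidTemplate:
    """Retrieve a built-in template by name.

    Accepts "pPOTv2", "pPOTv4" and the pLENTv2 resistance x tag grid
    ("pLENTv2-YB", "pLENTv2-TN", ...). Built-in templates are deterministic:
    placeholder bodies are generated from a fixed internal seed.
    """
    from . import fixtures  # deferred: fixtures builds the placeholder bodies

    return fixtures.make_plasmid(name)


def list_templates() -> list[str]:
    tags = {"Y": "eYFP", "T": "dTomFP", "C": "CFP"}
    drugs = {"B": "bsr", "N": "neo", "P": "pac"}
    plents = [f"pLENTv2-{t}{d}" for t in tags for d in drugs]
    return ["pPOTv2", "pPOTv4"] + plents


def write_genbank(template: PlasmidTemplate, path: str | Path) -> None:
    """Export a template as a GenBank-style flat file with one feature per element."""
    record = SeqRecord(
        Seq(template.full_sequence),
        id=template.name[:16].replace(" ", "_"),
        name=template.name[:16].replace(" ", "_"),
        description=f"trypanotag template family={template.family} tag={template.tag_name}",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    pos = 0
    for el_name, seq in template.elements:
        record.features.append(
            SeqFeature(
                FeatureLocation(pos, pos + len(seq)),
                type="misc_feature",
                qualifiers={"label": [el_name]},
            )
        )
        pos += len(seq)
    for role, site in template.anneal_sites.items():
        record.features.append(
            SeqFeature(
                FeatureLocation(0, 0),
                type="primer_bind",
                qualifiers={"label": [role], "note": [site]},
            )
        )
    SeqIO.write([record], str(path), "genbank")


def read_genbank(path: str | Path, family: str) -> PlasmidTemplate:
    """Load a template from a GenBank-style feature file.

    Elements are taken from misc_feature labels in positional order;
    annealing roles from primer_bind features (role in label, primer suffix
    in note). The loaded template is validated for site uniqueness.
    """
    record = SeqIO.read(str(path), "genbank")
    seq = str(record.seq).upper()
    elements: list[tuple[str, str]] = []
    anneal: dict[str, str] = {}
    for feat in sorted(record.features, key=lambda f: int(f.location.start)):
        label = feat.qualifiers.get("label", ["?"])[0]
        if feat.type == "misc_feature":
            elements.append((label, seq[int(feat.location.start) : int(feat.location.end)]))
        elif feat.type == "primer_bind":
            anneal[label] = feat.qualifiers.get("note", [""])[0]
    template = PlasmidTemplate(
        name=record.name,
        family=family,
        elements=elements,
        anneal_sites=anneal,
        provenance=f"loaded from {path}",
    )
    template.validate()
    return template
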