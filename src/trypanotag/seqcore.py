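"""Nucleotide/protein sequence primitives and coordinate conventions.

Sequences are plain Python strings over {A, C, G, T, N}, canonicalized to
upper case on validation; lower case is semantic only for display (locus
homology upper, plasmid annealing lower) and all comparisons are
case-insensitive. Coordinates are 0-based half-open throughout the package;
GFF3 input (1-based inclusive) is converted at the I/O boundary.

A CDS-relative interval is codon-aligned iff both endpoints are multiples
of 3 from the CDS start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .enzymes import get_enzyme
from .errors import AlphabetError, StartCodonError

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_STANDARD_TABLE = unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)  # {"TAA", "TAG", "TGA"}
CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"


def as_dna(s: str, context: str = "sequence") -> str:
    """Canonicalize to upper case and validate the alphabet.

    Raises AlphabetError for any residue outside {A, C, G, T, N}.
    """
    up = s.upper()
    bad = set(up) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"{context} contains invalid residues: {sorted(bad)}")
    return up


def revcomp(s: str) -> str:
    """Reverse complement; N maps to N, case is preserved per residue."""
    as_dna(s, "revcomp input")
    return s.translate(_COMPLEMENT)[::-1]


def gc_fraction(s: str) -> float:
    up = s.upper()
    if not up:
        return 0.0
    return (up.count("G") + up.count("C")) / len(up)


@dataclass
class Translation:
    """Result of translating successive codons from position 0.

    ``protein`` uses '*' for stops; ``stop_codon_indices`` lists 0-based codon
    indices at which stop codons occur (used to assert exactly one terminal
    stop in fused ORFs); ``trailing_nt`` counts ignored 3'-terminal residues.
    """

    protein: str
    stop_codon_indices: list[int] = field(default_factory=list)
    trailing_nt: int = 0

    @property
    def has_single_terminal_stop(self) -> bool:
        return len(self.stop_codon_indices) == 1 and self.protein.endswith("*")


def translate(s: str, require_atg: bool = False) -> Translation:
    """Standard-genetic-code translation of successive codons from position 0.

    Trailing 1-2 nt are ignored (recorded in ``trailing_nt``). ``require_atg``
    enforces an ATG start. Codons containing N translate to 'X'.
    """
    up = as_dna(s, "translate input")
    if len(up) < 3:
        raise AlphabetError(f"translate requires length >= 3, got {len(up)}")
    if require_atg and not up.startswith("ATG"):
        raise StartCodonError(f"sequence does not start with ATG: {up[:3]}...")
    n_codons = len(up) // 3
    aas = []
    stops = []
    for i in range(n_codons):
        codon = up[3 * i : 3 * i + 3]
        aa = CODON_TO_AA.get(codon, "X")
        if aa == "*":
            stops.append(i)
        aas.append(aa)
    return Translation("".join(aas), stops, len(up) - 3 * n_codons)


def frame0_stop_codon_positions(s: str) -> list[int]:
    """Nucleotide offsets of frame-0 stop codons (multiples of 3)."""
    up = s.upper()
    return [3 * i for i in range(len(up) // 3) if up[3 * i : 3 * i + 3] in STOP_CODONS]


def find_sites(s: str, enzyme_name: str) -> list[int]:
    """0-based start positions of an enzyme's recognition sequence on the
    given strand, including overlapping occurrences.

    All registry enzymes are palindromic, so top-strand positions describe
    both strands; palindromic sites are therefore reported once.
    """
    enzyme = get_enzyme(enzyme_name)
    return find_substring(as_dna(s, "find_sites input"), enzyme.site)


def find_substring(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) occurrence start positions, case-insensitive."""
    hay = haystack.upper()
    ndl = needle.upper()
    out = []
    i = hay.find(ndl)
    while i != -1:
        out.append(i)
        i = hay.find(ndl, i + 1)
    return out


def is_codon_aligned(offset: int) -> bool:
    """True iff ``offset`` (nt from a CDS start) lies on a codon boundary."""
    return offset % 3 == 0
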