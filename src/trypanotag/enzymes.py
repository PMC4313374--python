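"""Restriction enzyme registry.

The built-in set covers every enzyme the pPOT/pLENT cassettes use for
modular exchange, fragment release and plasmid linearization. All are
palindromic 6-cutters; recognition sequences are the canonical ones.
``cut_offset`` is the position of the top-strand cut within the recognition
site (recorded for completeness; fragment arithmetic in this package uses the
site-start abstraction, see plasmids.digest_release).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import RegistryError


@dataclass(frozen=True)
class Enzyme:
    name: str
    site: str  # recognition sequence, upper case, top strand
    cut_offset: int


# Insertion order is the deterministic preference order used when a unique
# linearization enzyme is selected for pLENT cloning designs.
REGISTRY: dict[str, Enzyme] = {
    e.name: e
    for e in [
        Enzyme("KpnI", "GGTACC", 5),
        Enzyme("HindIII", "AAGCTT", 1),
        Enzyme("BamHI", "GGATCC", 1),
        Enzyme("SpeI", "ACTAGT", 1),
        Enzyme("XbaI", "TCTAGA", 1),
        Enzyme("EcoRI", "GAATTC", 1),
        Enzyme("NcoI", "CCATGG", 1),
        Enzyme("NheI", "GCTAGC", 1),
        Enzyme("BsiWI", "CGTACG", 1),
        Enzyme("PciI", "ACATGT", 1),
    ]
}


def get_enzyme(name: str) -> Enzyme:
    """Look up an enzyme by name (case-sensitive, as conventionally written)."""
    try:
        return REGISTRY[name]
    except KeyError:
        known = ", ".join(REGISTRY)
        raise RegistryError(f"unknown enzyme {name!r}; registry has: {known}") from None


def all_sites() -> list[str]:
    """All recognition sequences in registry order."""
    return [e.site for e in REGISTRY.values()]
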