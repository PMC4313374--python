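"""Exception hierarchy for design and simulation failures.

Every hard failure raised by the toolkit derives from :class:`TrypanotagError`
so batch drivers can capture per-gene failures without aborting a run.
"""


class TrypanotagError(Exception):
    """Base class for all toolkit errors."""


class AlphabetError(TrypanotagError):
    """A sequence contains residues outside {A, C, G, T, N}, or a designed
    primer contains N (an oligo with N cannot be synthesized)."""


class StartCodonError(TrypanotagError):
    """Translation was required to begin at ATG but did not."""


class FrameError(TrypanotagError):
    """A coordinate or insert violates codon-frame constraints."""


class PrematureStopError(TrypanotagError):
    """A stop codon interrupts a reading frame that a fusion must run through."""


class RegistryError(TrypanotagError):
    """Unknown restriction enzyme or plasmid template."""


class LookupError_(TrypanotagError):
    """Gene id not present in the loaded genome."""


class UnsupportedStructureError(TrypanotagError):
    """Gene structure outside scope (e.g. multi-exon CDS)."""


class InsufficientFlankError(TrypanotagError):
    """Requested homology or arm length exceeds the available sequence."""


class DigestError(TrypanotagError):
    """Zero or multiple cut sites where exactly one was required."""


class PcrError(TrypanotagError):
    """In-silico PCR produced no product or an ambiguous product."""


class AssemblyError(TrypanotagError):
    """Fusion overlap join failed or was ambiguous at a junction."""


class MistargetError(TrypanotagError):
    """A homology arm matched the genome zero or multiple times, or in the
    wrong orientation - the computational analogue of mis-integration."""


class SelectionError(TrypanotagError):
    """No admissible linearization enzyme could be selected."""


class UsageError(TrypanotagError):
    """Invalid user input at the API or CLI boundary."""


class SaturationError(TrypanotagError):
    """All wells positive: the zero-class Poisson estimate is unbounded."""


class FixtureSpecError(TrypanotagError):
    """A synthetic-genome specification is infeasible."""
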