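"""Fusion-PCR design, pLENT cloning design, and melting temperatures."""

import dataclasses
import math

import pytest

from trypanotag.design_fusion import (
    design_fusion,
    design_plent_cloning,
    melting_temperature,
)
from trypanotag.errors import InsufficientFlankError, RegistryError, UsageError
from trypanotag.plasmids import digest_release
from trypanotag.seqcore import find_sites, revcomp

# ---------------------------------------------------------------------------
# melting temperature


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("gtataatgcagacctgctgc", 60.0),  # 10 AT + 10 GC
        ("AAAA", 8.0),
        ("GGCC", 16.0),
    ],
)
def test_wallace_rule(seq, expected):
    assert melting_temperature(seq, "wallace") == pytest.approx(expected)


def _nn_oracle(seq: str) -> float:
    """Independent nearest-neighbor Tm with the published unified parameters
    (50 mM monovalent salt, 500 nM total oligo, CT/4 pairing term)."""
    table = {
        "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
        "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
        "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
        "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
        "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
        "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
        "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
        "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
    }
    term = {"A": (2.3, 4.1), "T": (2.3, 4.1), "G": (0.1, -2.8), "C": (0.1, -2.8)}
    s = seq.upper()
    dh = term[s[0]][0] + term[s[-1]][0]
    ds = term[s[0]][1] + term[s[-1]][1]
    for i in range(len(s) - 1):
        h, v = table[s[i : i + 2]]
        dh += h
        ds += v
    ds += 0.368 * (len(s) - 1) * math.log(0.05)  # entropic salt correction
    ct = 125e-9  # (dnac1 - dnac2/2) with 250 nM each strand
    return 1000.0 * dh / (ds + 1.987 * math.log(ct)) - 273.15


@pytest.mark.parametrize(
    "seq",
    [
        "gtataatgcagacctgctgc",
        "ccaatttgagagacctgtgc",
        "ACGTACGTAACCGGTTACGT",
        "GGGGCCCCAAAATTTTGCAT",
    ],
)
def test_nearest_neighbor_against_published_parameter_oracle(seq):
    assert melting_temperature(seq) == pytest.approx(_nn_oracle(seq), abs=0.5)


def test_tm_length_limits():
    with pytest.raises(UsageError):
        melting_temperature("ACGTACGT")  # 8 nt < 10
    with pytest.raises(UsageError):
        melting_temperature("A" * 61)
    assert melting_temperature("A" * 61, "wallace") > 0


# ---------------------------------------------------------------------------
# fusion design


def test_c_terminal_fusion_geometry(gene, plent_yb):
    d = design_fusion(gene, plent_yb, "C")
    central = digest_release(plent_yb, "SpeI", "NcoI")
    assert d.central_fragment == central
    # junction adapters: 30 bp of homology to the fragment ends
    assert d.gene_arm.reverse.adapter == revcomp(central[:30])
    assert d.utr_arm.forward.adapter == central[-30:]
    # gene arm: 500 nt ending at (and excluding) the stop codon
    assert d.gene_arm.sequence == gene.locus_context()[
        gene.cds_start_in_context + gene.cds_length - 503 :
        gene.cds_start_in_context + gene.cds_length - 3
    ]
    assert len(d.gene_arm.sequence) == 500
    assert d.utr_arm.sequence == gene.downstream_flank[:500]
    # round-1 gene-arm product: arm + adapter
    assert len(d.gene_arm.predicted_product) == 530
    assert d.gene_arm.predicted_product == d.gene_arm.sequence + central[:30]


def test_n_terminal_fusion_orientation(gene, ppotv2):
    """N-terminal designs draw the centre from pPOTv2 with adapters to the
    resistance 5' end and the tag 3' end."""
    d = design_fusion(gene, ppotv2, "N")
    central = digest_release(ppotv2, "EcoRI", "XbaI")
    assert d.central_fragment == central
    assert d.utr_arm.reverse.adapter == revcomp(central[:30])
    assert d.gene_arm.forward.adapter == central[-30:]
    assert d.utr_arm.sequence == gene.upstream_flank[-500:]
    # final layout: 5'UTR arm | resistance | intergenic | tag | ORF arm
    final = d.predicted_final_amplicon
    assert central in final
    assert final.index(central) == 500 - d.nested_insets[0]


def test_nested_trim_bounds(gene, plent_yb):
    d = design_fusion(gene, plent_yb, "C")
    lo, hi = 20, 30
    assert lo <= d.nested_insets[0] <= hi and lo <= d.nested_insets[1] <= hi
    joined = d.joined_product
    assert len(d.predicted_final_amplicon) == len(joined) - sum(d.nested_insets)
    assert d.predicted_final_amplicon in joined


def test_fusion_template_family_checks(gene, ppotv2, plent_yb):
    with pytest.raises(RegistryError):
        design_fusion(gene, ppotv2, "C")
    with pytest.raises(RegistryError):
        design_fusion(gene, plent_yb, "N")  # pLENTv2 unsuitable for N-terminal


def test_fusion_needs_flank(gene, plent_yb):
    short = dataclasses.replace(gene, downstream_flank=gene.downstream_flank[:300])
    with pytest.raises(InsufficientFlankError):
        design_fusion(short, plent_yb, "C")


# ---------------------------------------------------------------------------
# pLENT restriction cloning


def test_cloning_design_clean_arms(gene, plent_yb):
    d = design_plent_cloning(gene, plent_yb, "C", 400)
    # site layout on the four primers
    assert d.gene_arm_rev.adapter.endswith("ACTAGT")
    assert d.utr_arm_fwd.adapter.endswith("AAGCTT")
    lin = d.linearization_enzyme
    assert d.gene_arm_fwd.adapter[4:] == d.utr_arm_rev.adapter[4:]
    # the linearization enzyme cuts the assembled plasmid exactly once
    from trypanotag.enzymes import get_enzyme

    site = get_enzyme(lin).site
    assert len(find_sites(d.assembled_plasmid, lin)) == 1
    assert find_sites(d.gene_arm_fwd.genomic + d.utr_arm_rev.genomic, lin) == []
    assert site not in d.gene_fragment[len(site) : -len(site)]
    assert 300 <= d.arm_length <= 500
    assert d.predicted_linearized.startswith(site)


def test_cloning_arm_length_range(gene, plent_yb):
    with pytest.raises(UsageError):
        design_plent_cloning(gene, plent_yb, "C", 200)
    with pytest.raises(UsageError):
        design_plent_cloning(gene, plent_yb, "C", 600)


def test_cloning_site_in_arm_warns_but_designs(gene, plent_yb):
    flank = "AAGCTT" + gene.downstream_flank[6:]
    bumpy = dataclasses.replace(gene, downstream_flank=flank)
    d = design_plent_cloning(bumpy, plent_yb, "C", 400)
    assert any("HindIII" in w for w in d.warnings)
    assert d.linearization_enzyme  # still selected


def test_cloning_terminus_n_unsupported(gene, plent_yb):
    with pytest.raises(UsageError):
        design_plent_cloning(gene, plent_yb, "N", 400)
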