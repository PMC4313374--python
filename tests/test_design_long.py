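"""Long-primer design rules for all five pPOT strategies."""

import dataclasses

import pytest

from trypanotag.design_long import Strategy, batch_design, design_long
from trypanotag.errors import (
    AlphabetError,
    FrameError,
    InsufficientFlankError,
    RegistryError,
    UsageError,
)
from trypanotag.plasmids import ANNEAL_TABLE, insert_internal_element, swap_tag
from trypanotag.report import designs_to_tsv
from trypanotag.seqcore import revcomp

FWD_OUTER = ANNEAL_TABLE[("pPOT", "fwd_outer")]
REV_OUTER = ANNEAL_TABLE[("pPOT", "rev_outer")]
L5 = ANNEAL_TABLE[("pPOTv4", "linker5_fwd")]
L3 = ANNEAL_TABLE[("pPOTv4", "linker3_rev")]


def test_n_tag_rule(gene, ppotv4):
    d = design_long(gene, ppotv4, "N_TAG")
    assert d.forward.sequence == (gene.upstream_flank[-80:] + FWD_OUTER).upper()
    assert len(d.forward) == 100
    assert d.reverse.homology_segment == revcomp(gene.cds[:80])
    assert d.reverse.anneal_segment == L3
    # the native ATG is retained at the arm's 3' genomic end
    assert gene.cds[:3] == "ATG"


def test_c_tag_rule(gene, ppotv4):
    d = design_long(gene, ppotv4, "C_TAG")
    # forward primer's 3'-most 18 nt are the 5' GS-linker annealing sequence
    assert d.forward.sequence[-18:] == L5.upper()
    # homology excludes the stop codon and ends codon-aligned
    hom = d.forward.homology_segment
    assert hom == gene.cds[:-3][-80:]
    assert hom[-3:] not in ("TAA", "TAG", "TGA") or gene.cds[-6:-3] == hom[-3:]
    assert (gene.cds_length - 3) % 3 == 0
    assert d.reverse.sequence == (revcomp(gene.downstream_flank[:80]) + REV_OUTER).upper()


def test_ppotv2_anneal_segments(gene, ppotv2):
    n = design_long(gene, ppotv2, "N_TAG")
    c = design_long(gene, ppotv2, "C_TAG")
    assert n.reverse.anneal_segment == ANNEAL_TABLE[("pPOTv2", "tag_rev")]
    assert c.forward.anneal_segment == ANNEAL_TABLE[("pPOTv2", "tag_fwd")]
    assert n.forward.anneal_segment == FWD_OUTER
    assert c.reverse.anneal_segment == REV_OUTER


def test_deletion_rules(gene, ppotv4):
    t = gene.cds_length // 2 // 3 * 3
    nd = design_long(gene, ppotv4, "N_DEL", truncation_point=t)
    assert nd.reverse.homology_segment == revcomp(gene.cds[t : t + 80])
    assert nd.forward.sequence == (gene.upstream_flank[-80:] + FWD_OUTER).upper()
    cd = design_long(gene, ppotv4, "C_DEL", truncation_point=t)
    assert cd.forward.homology_segment == gene.cds[t - 80 : t]
    assert cd.forward.anneal_segment == L5


def test_internal_rule(gene, ppotv4):
    insert = gene.cds[:30]
    mod = insert_internal_element(ppotv4, insert, "5prime")
    d = design_long(gene, mod, "INTERNAL", truncation_point=30)
    assert d.forward.anneal_segment == FWD_OUTER
    # reverse homology resumes immediately after the template-embedded prefix
    assert d.reverse.homology_segment == revcomp(gene.cds[30:110])
    assert d.reverse.anneal_segment == L3
    with pytest.raises(RegistryError):
        design_long(gene, ppotv4, "INTERNAL", truncation_point=30)


def test_amplicon_consistency(gene, ppotv4):
    """Primers must be re-derivable from the predicted amplicon ends."""
    for strat, tp in [("N_TAG", None), ("C_TAG", None), ("C_DEL", 90)]:
        d = design_long(gene, ppotv4, strat, truncation_point=tp)
        amp = d.predicted_amplicon
        H = d.homology_length
        assert amp[:H] == d.forward.homology_segment
        assert amp[H : H + len(d.forward.anneal_segment)] == d.forward.anneal_segment.upper()
        assert amp[-H:] == revcomp(d.reverse.homology_segment)
        ra = d.reverse.anneal_segment
        assert amp[-(H + len(ra)) : -H] == revcomp(ra).upper()


def test_degeneracy_c_del_equals_c_tag(genome, ppotv4):
    for gid in ["Tsyn0001", "Tsyn0005", "Tsyn0012"]:
        g = genome.get_gene(gid)
        cd = design_long(g, ppotv4, "C_DEL", truncation_point=g.cds_length - 3)
        ct = design_long(g, ppotv4, "C_TAG")
        assert cd.forward.sequence == ct.forward.sequence
        assert cd.reverse.sequence == ct.reverse.sequence


def test_degeneracy_n_del_equals_n_tag(genome, ppotv4):
    for gid in ["Tsyn0002", "Tsyn0008"]:
        g = genome.get_gene(gid)
        nd = design_long(g, ppotv4, "N_DEL", truncation_point=0)
        nt = design_long(g, ppotv4, "N_TAG")
        assert nd.forward.sequence == nt.forward.sequence
        assert nd.reverse.sequence == nt.reverse.sequence


def test_tag_swap_leaves_primers_unchanged(gene, ppotv4):
    """The same long primer pair targets a gene with any tag."""
    swapped = swap_tag(ppotv4, "CAT" * 120, "halo")
    for strat in ("N_TAG", "C_TAG"):
        a = design_long(gene, ppotv4, strat)
        b = design_long(gene, swapped, strat)
        assert a.forward.sequence == b.forward.sequence
        assert a.reverse.sequence == b.reverse.sequence


def test_homology_length_options(gene, ppotv4):
    d = design_long(gene, ppotv4, "C_TAG", homology_length=60)
    assert len(d.forward.homology_segment) == 60
    assert any("BELOW_RECOMMENDED_HOMOLOGY" in w for w in d.warnings)
    with pytest.raises(UsageError):
        design_long(gene, ppotv4, "C_TAG", homology_length=130)
    with pytest.raises(UsageError):
        design_long(gene, ppotv4, "C_TAG", homology_length=40)


def test_truncation_errors(gene, ppotv4):
    with pytest.raises(FrameError):
        design_long(gene, ppotv4, "C_DEL", truncation_point=91)  # not codon-aligned
    with pytest.raises(FrameError):
        design_long(gene, ppotv4, "N_DEL", truncation_point=gene.cds_length + 3)
    with pytest.raises(UsageError):
        design_long(gene, ppotv4, "N_DEL")  # missing truncation point
    with pytest.raises(UsageError):
        design_long(gene, ppotv4, "C_TAG", truncation_point=30)


def test_insufficient_flank(gene, ppotv4):
    short = dataclasses.replace(gene, upstream_flank=gene.upstream_flank[-40:])
    with pytest.raises(InsufficientFlankError):
        design_long(short, ppotv4, "N_TAG")


def test_primer_with_n_rejected(gene, ppotv4):
    flank = gene.upstream_flank[:-10] + "NNNNNNNNNN"
    withn = dataclasses.replace(gene, upstream_flank=flank)
    with pytest.raises(AlphabetError):
        design_long(withn, ppotv4, "N_TAG")


def test_batch_shared_suffix_and_failures(genome, ppotv4):
    ids = [f"Tsyn{i:04d}" for i in range(1, 11)]
    res = batch_design(genome, ids, ppotv4, "C_TAG")
    assert len(res.designs) == 10 and not res.failures
    # the outer reverse annealing sequence is gene-independent
    assert {d.reverse.sequence[-20:] for d in res.designs} == {REV_OUTER.upper()}

    res2 = batch_design(genome, ids + ["Missing01"], ppotv4, "C_TAG")
    assert len(res2.designs) == 10 and len(res2.failures) == 1
    assert res2.failures[0][0] == "Missing01"
    assert res2.summary["failed"] == 1

    with pytest.raises(UsageError):
        batch_design(genome, [], ppotv4, "C_TAG")


def test_batch_output_deterministic(genome, ppotv4):
    ids = sorted(genome.genes)
    a = designs_to_tsv(batch_design(genome, ids, ppotv4, "C_TAG").designs)
    b = designs_to_tsv(batch_design(genome, ids, ppotv4, "C_TAG").designs)
    assert a == b
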