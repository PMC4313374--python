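"""PCR, fusion-assembly and recombination simulators; end-to-end validation."""

import pytest

from trypanotag.design_fusion import design_fusion
from trypanotag.design_long import design_long
from trypanotag.errors import AssemblyError, MistargetError, PcrError
from trypanotag.insilico import (
    simulate_fusion,
    simulate_pcr,
    simulate_recombination,
    validate_design,
)
from trypanotag.plasmids import insert_internal_element
from trypanotag.seqcore import revcomp, translate


def _oracle_protein(design, gene):
    """Predicted fusion protein by direct concatenation + translation,
    without any simulator."""
    cds = gene.cds
    full = design.template.full_sequence
    tag_lo, tag_hi = design.template.tag_orf_span()
    if hasattr(design, "strategy"):
        f0, r1 = design.template_span
        t = design.truncation_point
        strat = design.strategy.value
        if strat == "C_TAG":
            orf = cds[:-3] + full[f0:tag_hi]
        elif strat == "C_DEL":
            orf = cds[:t] + full[f0:tag_hi]
        elif strat == "N_TAG":
            orf = full[tag_lo:r1] + cds
        else:  # N_DEL, INTERNAL
            orf = full[tag_lo:r1] + cds[t:]
    else:
        central = design.central_fragment
        frag_start = full.index(central)
        if design.terminus == "C":
            orf = cds[:-3] + central[: tag_hi - frag_start]
        else:
            orf = central[tag_lo - frag_start :] + cds
    tr = translate(orf)
    assert tr.has_single_terminal_stop
    return tr.protein.rstrip("*")


# ---------------------------------------------------------------------------
# simulate_pcr


def test_pcr_product_ends_reproduce_primers(gene, ppotv4):
    d = design_long(gene, ppotv4, "C_TAG")
    amp = simulate_pcr(ppotv4.full_sequence, d.forward, d.reverse)
    assert amp.sequence.startswith(d.forward.sequence)
    assert amp.sequence.endswith(revcomp(d.reverse.sequence))
    assert amp.sequence == d.predicted_amplicon


def test_pcr_product_length_arithmetic(gene, ppotv4):
    d = design_long(gene, ppotv4, "C_TAG")
    f0, r1 = d.template_span
    assert len(d.predicted_amplicon) == (r1 - f0) + 2 * 80
    amp = simulate_pcr(ppotv4.full_sequence, d.forward, d.reverse)
    assert len(amp.sequence) == (r1 - f0) + 2 * 80


def test_pcr_three_prime_mismatch_gives_no_product(gene, ppotv4):
    d = design_long(gene, ppotv4, "C_TAG")
    bad = d.forward.sequence[:-1] + ("A" if d.forward.sequence[-1] != "A" else "C")
    with pytest.raises(PcrError):
        simulate_pcr(ppotv4.full_sequence, bad, d.reverse)


def test_pcr_no_binding_site():
    with pytest.raises(PcrError):
        simulate_pcr("ACGT" * 30, "G" * 20, "C" * 20)


def test_pcr_ambiguous_sites():
    block = "ATGCATTACGGATCAGTCAT"
    template = block + "A" * 40 + block + "T" * 30
    fwd = block
    rev = revcomp("T" * 20)
    with pytest.raises(PcrError):
        simulate_pcr(template, fwd, rev)


def test_pcr_wrong_primer_order():
    template = "ATACGATCGCAGTACCAGTT" + "A" * 40 + "CGATTAGCATCAGCATTAGC"
    fwd = "CGATTAGCATCAGCATTAGC"
    rev = revcomp("ATACGATCGCAGTACCAGTT")
    with pytest.raises(PcrError):
        simulate_pcr(template, fwd, rev)


# ---------------------------------------------------------------------------
# simulate_fusion


def test_fusion_matches_design_prediction(gene, plent_yb):
    d = design_fusion(gene, plent_yb, "C")
    frags = [
        d.gene_arm.predicted_product,
        d.central_fragment,
        d.utr_arm.predicted_product,
    ]
    amp = simulate_fusion(frags, d.nested_fwd, d.nested_rev)
    assert amp.sequence == d.predicted_final_amplicon


def test_fusion_is_order_independent(gene, plent_yb):
    d = design_fusion(gene, plent_yb, "C")
    frags = [
        d.utr_arm.predicted_product,
        d.gene_arm.predicted_product,
        d.central_fragment,
    ]
    amp = simulate_fusion(frags, d.nested_fwd, d.nested_rev)
    assert amp.sequence == d.predicted_final_amplicon


def test_fusion_missing_overlap():
    with pytest.raises(AssemblyError):
        simulate_fusion(["A" * 60, "C" * 60], "A" * 20, "G" * 20)


# ---------------------------------------------------------------------------
# simulate_recombination


def test_tagging_replaced_intervals(gene, ppotv4):
    """N-tagging is a pure insertion; C-tagging replaces exactly the native
    stop codon (the 5' arm excludes it, the 3' arm begins after it)."""
    n = validate_design(design_long(gene, ppotv4, "N_TAG"), gene).recombination
    assert n.replaced_interval[1] - n.replaced_interval[0] == 0
    c = validate_design(design_long(gene, ppotv4, "C_TAG"), gene).recombination
    assert c.replaced_interval[1] - c.replaced_interval[0] == 3


def test_c_del_replaced_interval(gene, ppotv4):
    t = gene.cds_length // 2 // 3 * 3
    d = design_long(gene, ppotv4, "C_DEL", truncation_point=t)
    rec = validate_design(d, gene).recombination
    lo, hi = rec.replaced_interval
    assert hi - lo == gene.cds_length - t  # deleted suffix incl. native stop


def test_length_conservation(genome, ppotv4, ppotv2, plent_yb):
    for gid in ["Tsyn0003", "Tsyn0007", "Tsyn0011"]:
        g = genome.get_gene(gid)
        t = g.cds_length // 2 // 3 * 3
        designs = [
            design_long(g, ppotv4, "N_TAG"),
            design_long(g, ppotv4, "C_TAG"),
            design_long(g, ppotv4, "N_DEL", truncation_point=t),
            design_long(g, ppotv4, "C_DEL", truncation_point=t),
            design_fusion(g, plent_yb, "C"),
            design_fusion(g, ppotv2, "N"),
        ]
        locus = g.locus_context()
        for d in designs:
            rec = validate_design(d, g).recombination
            lo, hi = rec.replaced_interval
            if hasattr(d, "strategy"):
                core = len(d.predicted_amplicon) - 2 * d.homology_length
            else:
                arm = d.arm_length - max(d.nested_insets)
                core = len(d.predicted_final_amplicon) - 2 * arm
            assert len(rec.modified_locus) == len(locus) - (hi - lo) + core


def test_duplicated_locus_is_mistarget(gene, ppotv4):
    d = design_long(gene, ppotv4, "C_TAG")
    duplicated = gene.locus_context() + "ACGT" * 10 + gene.locus_context()
    with pytest.raises(MistargetError):
        simulate_recombination(duplicated, d.predicted_amplicon, 80)


def test_wrong_orientation_is_mistarget(gene, ppotv4):
    d = design_long(gene, ppotv4, "C_TAG")
    with pytest.raises(MistargetError):
        simulate_recombination(
            revcomp(gene.locus_context()), d.predicted_amplicon, 80
        )


def test_recombination_default_orf_recovery(gene, ppotv4):
    """Without an explicit start hint the longest ORF spanning the insertion
    is recovered (the tagged ORF)."""
    d = design_long(gene, ppotv4, "C_TAG")
    rec = simulate_recombination(gene.locus_context(), d.predicted_amplicon, 80)
    assert rec.in_frame
    assert rec.fusion_protein == _oracle_protein(d, gene)


# ---------------------------------------------------------------------------
# end-to-end validation


@pytest.mark.parametrize("strategy", ["N_TAG", "C_TAG", "N_DEL", "C_DEL", "INTERNAL"])
def test_validate_all_long_strategies(genome, ppotv4, strategy):
    for gid in ["Tsyn0004", "Tsyn0009"]:
        g = genome.get_gene(gid)
        t = g.cds_length // 2 // 3 * 3
        if strategy == "INTERNAL":
            template = insert_internal_element(ppotv4, g.cds[:30], "5prime")
            d = design_long(g, template, strategy, truncation_point=30)
        elif strategy.endswith("DEL"):
            d = design_long(g, ppotv4, strategy, truncation_point=t)
        else:
            d = design_long(g, ppotv4, strategy)
        rep = validate_design(d, g)
        assert rep.passed, rep.errors
        assert rep.stop_check == "single_terminal"
        assert rep.recombination.fusion_protein == _oracle_protein(d, g)


@pytest.mark.parametrize("terminus", ["N", "C"])
def test_validate_fusion_termini(genome, ppotv2, plent_yb, terminus):
    for gid in ["Tsyn0006", "Tsyn0010"]:
        g = genome.get_gene(gid)
        template = plent_yb if terminus == "C" else ppotv2
        d = design_fusion(g, template, terminus)
        rep = validate_design(d, g)
        assert rep.passed, rep.errors
        assert rep.recombination.fusion_protein == _oracle_protein(d, g)


def test_validation_collects_failures(genome, ppotv4):
    """A verbatim gene duplication breaks arm uniqueness and fails cleanly."""
    import dataclasses

    g = genome.get_gene("Tsyn0001")
    dup = dataclasses.replace(
        g, downstream_flank=g.downstream_flank[:200] + g.upstream_flank[-200:] + g.cds
    )
    d = design_long(g, ppotv4, "N_TAG")
    rep = validate_design(d, dup)
    assert not rep.passed
    assert rep.errors
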