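"""Serialization of designs and validation reports to TSV, FASTA and JSON.

TSV/FASTA primer sequences follow the display convention: locus homology in
upper case, plasmid-annealing/adapter segments in lower case. JSON records
carry enough provenance (template name, internal insert, options) for the
`simulate` subcommand to rebuild and re-verify every design.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from typing import Iterable

from .design_fusion import CloningDesign, FusionDesign, FusionPrimer
from .design_long import LongPrimerDesign, Primer
from .insilico import ValidationReport

TSV_HEADER = (
    "gene_id\tkind\tprimer\tsequence\tlength\thomology_nt\tanneal_nt\ttm_anneal_c\twarnings"
)


def _warn_text(warnings: list) -> str:
    return "; ".join(str(w) for w in warnings) if warnings else "."


def _long_rows(d: LongPrimerDesign) -> Iterable[tuple]:
    for p in (d.forward, d.reverse):
        yield (
            d.gene_id,
            d.strategy.value,
            p.name,
            p.display,
            len(p),
            len(p.homology_segment),
            len(p.anneal_segment),
            f"{p.tm_anneal:.1f}",
            _warn_text(d.warnings),
        )


def _fusion_rows(d: FusionDesign) -> Iterable[tuple]:
    primers = [
        d.gene_arm.forward,
        d.gene_arm.reverse,
        d.utr_arm.forward,
        d.utr_arm.reverse,
        d.nested_fwd,
        d.nested_rev,
    ]
    for p in primers:
        yield (
            d.gene_id,
            f"FUSION_{d.terminus}",
            p.name,
            p.display,
            len(p),
            len(p.genomic),
            len(p.adapter),
            f"{p.tm_genomic:.1f}",
            _warn_text(d.warnings),
        )


def _cloning_rows(d: CloningDesign) -> Iterable[tuple]:
    for p in (d.gene_arm_fwd, d.gene_arm_rev, d.utr_arm_fwd, d.utr_arm_rev):
        yield (
            d.gene_id,
            f"PLENT_{d.terminus}",
            p.name,
            p.display,
            len(p),
            len(p.genomic),
            len(p.adapter),
            f"{p.tm_genomic:.1f}",
            _warn_text(d.warnings),
        )


def designs_to_tsv(designs: list, header_comment: str | None = None) -> str:
    lines = []
    if header_comment:
        lines.extend(f"# {line}" for line in header_comment.splitlines())
    lines.append(TSV_HEADER)
    for d in designs:
        if isinstance(d, LongPrimerDesign):
            rows = _long_rows(d)
        elif isinstance(d, FusionDesign):
            rows = _fusion_rows(d)
        elif isinstance(d, CloningDesign):
            rows = _cloning_rows(d)
        else:
            raise TypeError(f"cannot serialize {type(d).__name__}")
        lines.extend("\t".join(str(x) for x in row) for row in rows)
    return "\n".join(lines) + "\n"


def designs_to_fasta(designs: list) -> str:
    out = []
    for d in designs:
        if isinstance(d, LongPrimerDesign):
            primers = [d.forward, d.reverse]
        elif isinstance(d, FusionDesign):
            primers = [
                d.gene_arm.forward,
                d.gene_arm.reverse,
                d.utr_arm.forward,
                d.utr_arm.reverse,
                d.nested_fwd,
                d.nested_rev,
            ]
        elif isinstance(d, CloningDesign):
            primers = [d.gene_arm_fwd, d.gene_arm_rev, d.utr_arm_fwd, d.utr_arm_rev]
        else:
            raise TypeError(f"cannot serialize {type(d).__name__}")
        for p in primers:
            out.append(f">{p.name}")
            out.append(p.display)
    return "\n".join(out) + "\n"


def _primer_dict(p: Primer | FusionPrimer) -> dict:
    if isinstance(p, Primer):
        return {
            "name": p.name,
            "sequence": p.display,
            "homology_segment": p.homology_segment,
            "anneal_segment": p.anneal_segment,
            "tm_anneal": round(p.tm_anneal, 2),
        }
    return {
        "name": p.name,
        "sequence": p.display,
        "adapter": p.adapter,
        "genomic": p.genomic,
        "tm_genomic": round(p.tm_genomic, 2),
    }


def design_record(d) -> dict:
    """JSON-serializable record with rebuild provenance."""
    if isinstance(d, LongPrimerDesign):
        rec = {
            "kind": "long",
            "gene_id": d.gene_id,
            "template": d.template.name if d.template else d.plasmid,
            "template_base": (d.plasmid.split("+", 1)[0]),
            "internal_insert": (
                {"side": d.template.internal_insert[0], "sequence": d.template.internal_insert[1]}
                if d.template is not None and d.template.internal_insert
                else None
            ),
            "strategy": d.strategy.value,
            "homology_length": d.homology_length,
            "truncation_point": d.truncation_point,
            "forward": _primer_dict(d.forward),
            "reverse": _primer_dict(d.reverse),
            "predicted_amplicon": d.predicted_amplicon,
            "warnings": [str(w) for w in d.warnings],
        }
        return rec
    if isinstance(d, FusionDesign):
        return {
            "kind": "fusion",
            "gene_id": d.gene_id,
            "template": d.template.name if d.template else None,
            "terminus": d.terminus,
            "arm_length": d.arm_length,
            "release_enzymes": list(d.release_enzymes),
            "central_fragment": d.central_fragment,
            "gene_arm": {
                "forward": _primer_dict(d.gene_arm.forward),
                "reverse": _primer_dict(d.gene_arm.reverse),
                "product": d.gene_arm.predicted_product,
            },
            "utr_arm": {
                "forward": _primer_dict(d.utr_arm.forward),
                "reverse": _primer_dict(d.utr_arm.reverse),
                "product": d.utr_arm.predicted_product,
            },
            "nested_fwd": _primer_dict(d.nested_fwd),
            "nested_rev": _primer_dict(d.nested_rev),
            "nested_insets": list(d.nested_insets),
            "predicted_final_amplicon": d.predicted_final_amplicon,
            "warnings": [str(w) for w in d.warnings],
        }
    if isinstance(d, CloningDesign):
        return {
            "kind": "plent_cloning",
            "gene_id": d.gene_id,
            "terminus": d.terminus,
            "arm_length": d.arm_length,
            "linearization_enzyme": d.linearization_enzyme,
            "primers": {
                "gene_arm_fwd": _primer_dict(d.gene_arm_fwd),
                "gene_arm_rev": _primer_dict(d.gene_arm_rev),
                "utr_arm_fwd": _primer_dict(d.utr_arm_fwd),
                "utr_arm_rev": _primer_dict(d.utr_arm_rev),
            },
            "gene_fragment": d.gene_fragment,
            "utr_fragment": d.utr_fragment,
            "predicted_linearized": d.predicted_linearized,
            "warnings": [str(w) for w in d.warnings],
        }
    raise TypeError(f"cannot serialize {type(d).__name__}")


def report_json(designs: list, config: dict, failures: list | None = None) -> str:
    payload = {
        "config": config,
        "designs": [design_record(d) for d in designs],
        "failures": [list(f) for f in (failures or [])],
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def validation_record(rep: ValidationReport) -> dict:
    return {
        "gene_id": rep.gene_id,
        "design_kind": rep.design_kind,
        "passed": rep.passed,
        "in_frame": rep.in_frame,
        "stop_check": rep.stop_check,
        "protein_length": rep.protein_length,
        "replaced_interval": list(rep.replaced_interval) if rep.replaced_interval else None,
        "errors": rep.errors,
        "warnings": [str(w) for w in rep.warnings],
    }
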