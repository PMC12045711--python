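"""Design of guides and minimal expression arrays for chosen target loci.

The design problem is the inverse of target search: for every footprint
window the unique guide whose spacers pair the two strands in the canonical
geometry is derived, then screened with rule-based warnings (no efficiency
model is attempted).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .seq import NucSeq, dna_to_rna_str, revcomp_str, has_ambiguity
from .grammar import RepeatSet, TIGRArrayModel, TIGRUnit, assemble_array
from .targets import GuidePair, find_sites, self_target_check

_HOMOPOLYMER = re.compile(r"(.)\1{5,}")


@dataclass
class DesignCandidate:
    """One designed guide with its construct and screening flags."""

    guide: GuidePair
    start: int
    end: int
    gap: int
    construct: NucSeq
    warnings: list[str] = field(default_factory=list)
    off_target_summary: dict[str, int] = field(default_factory=dict)


def build_expression_array(
    guide: GuidePair,
    repeat_set: RepeatSet,
    n_units: int = 3,
    with_terminator: bool = True,
) -> tuple[NucSeq, TIGRArrayModel]:
    """Minimal expression array: ``n_units`` identical units for one guide.

    Returns the assembled DNA plus its model (for annotation and round-trip
    parsing).  One to three units suffice for processing into mature guides.
    """
    sa = rna_to_dna(guide.spacer_a)
    sb = rna_to_dna(guide.spacer_b)
    if len(sa) != repeat_set.spacer_len_a or len(sb) != repeat_set.spacer_len_b:
        raise ValueError(
            f"guide spacer lengths ({len(sa)}, {len(sb)}) do not match repeat set "
            f"({repeat_set.spacer_len_a}, {repeat_set.spacer_len_b})"
        )
    units = [TIGRUnit(i + 1, sa, sb) for i in range(n_units)]
    model = TIGRArrayModel(repeat_set, units, has_terminator=with_terminator)
    seq = assemble_array(model)
    seq.id = guide.source_id or "expression_array"
    return seq, model


def rna_to_dna(spacer: str) -> str:
    return spacer.replace("U", "T")


def _spacer_warnings(name: str, spacer_dna: str) -> list[str]:
    out = []
    if _HOMOPOLYMER.search(spacer_dna):
        out.append(f"homopolymer_run_{name}")
    # spacer edges that visually extend the flanking box C ("CCA") / box D
    # ("TG") motifs can blur the processing grammar
    if spacer_dna.startswith("CCA") or spacer_dna.endswith("TG"):
        out.append(f"box_motif_extension_{name}")
    return out


def enumerate_guides(
    region: NucSeq,
    repeat_set: RepeatSet,
    max_gap: int = 2,
    check_self_target: bool = True,
    off_target_max_mm: int | None = None,
) -> list[DesignCandidate]:
    """All guide candidates targeting a region, one per footprint window/gap.

    For a window ``[s, s+a+g+b)`` the guide is: spacer A = the top strand of
    the left ``a`` bases (it pairs the bottom strand), spacer B = the reverse
    complement of the right ``b`` bases (it pairs the top strand).  Windows
    containing ambiguity codes are skipped.  Warnings flag homopolymer runs,
    box-motif-like spacer edges, palindromic spacer pairs, and self-targeting
    constructs.
    """
    sa_len = repeat_set.spacer_len_a
    sb_len = repeat_set.spacer_len_b
    if len(region) < sa_len + sb_len:
        raise ValueError(
            f"region length {len(region)} shorter than minimal footprint {sa_len + sb_len}"
        )
    s = region.seq
    out: list[DesignCandidate] = []
    for gap in range(max_gap + 1):
        w = sa_len + gap + sb_len
        for i in range(len(s) - w + 1):
            window = s[i : i + w]
            if has_ambiguity(window):
                continue
            a_dna = window[:sa_len]
            b_dna = revcomp_str(window[sa_len + gap :])
            guide = GuidePair(
                dna_to_rna_str(a_dna),
                dna_to_rna_str(b_dna),
                source_id=f"design_{region.id}_{i}_{gap}",
            )
            warnings = _spacer_warnings("A", a_dna) + _spacer_warnings("B", b_dna)
            if a_dna == revcomp_str(b_dna):
                warnings.append("palindromic_spacers")
            construct, _ = build_expression_array(guide, repeat_set)
            if check_self_target and self_target_check(guide, construct):
                warnings.append("self_target")
            cand = DesignCandidate(
                guide=guide,
                start=i,
                end=i + w,
                gap=gap,
                construct=construct,
                warnings=warnings,
            )
            if off_target_max_mm is not None:
                sites = find_sites(
                    region, guide, max_gap=max_gap, max_mm_per_region=off_target_max_mm
                )
                extra = [x for x in sites if (x.start, x.end) != (i, i + w)]
                cand.off_target_summary = {
                    "relaxed_sites_in_region": len(extra),
                }
            out.append(cand)
    return out
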