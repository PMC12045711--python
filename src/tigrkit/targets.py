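"""Tandem dual-strand target-site search and cleavage-geometry prediction.

A guide's two spacers act in tandem: one pairs each strand of the DNA
target over adjacent regions (0-2 bp apart), with spacer base 1 (the
box-C-proximal base) pairing the outer DNA base of its region.  Each matched
strand is cut 5' of the base pairing spacer base 5 (the "C - 5" placement;
of the two phrasings of the cut rule this is the one that reproduces the
8-nt 3' overhang on a perfect zero-gap 9+9 site).  Mismatch tolerance is a
literal rule table: seed positions {4, 5} abolish cleavage of both strands,
nickase positions {6, 7} abolish only the strand whose pairing is impaired,
and simultaneous mismatches at both 5'-edge positions {8, 9} of one region
abolish cleavage; other single mismatches are tolerated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seq import (
    NucSeq,
    RNA_BASES,
    WC_RNA_DNA,
    pairs_rna_dna,
    complement,
)

CUT_INDEX = 5  # spacer base whose paired DNA base sits immediately 3' of the nick


@dataclass(frozen=True)
class GuidePair:
    """The two spacers of a guide (RNA strings), the minimal targeting info."""

    spacer_a: str
    spacer_b: str
    source_id: str | None = None

    def __post_init__(self) -> None:
        for name, sp in (("spacer_a", self.spacer_a), ("spacer_b", self.spacer_b)):
            sp_up = sp.upper()
            object.__setattr__(self, name, sp_up)
            if not (8 <= len(sp_up) <= 12):
                raise ValueError(f"{name} length {len(sp_up)} outside 8-12")
            if set(sp_up) - RNA_BASES:
                raise ValueError(f"{name} must be unambiguous RNA: {sp_up}")

    def swapped(self) -> "GuidePair":
        return GuidePair(self.spacer_b, self.spacer_a, self.source_id)


@dataclass(frozen=True)
class MismatchModel:
    """Spacer-index rule table governing cleavage outcomes."""

    seed_positions: frozenset[int] = frozenset({4, 5})
    nickase_positions: frozenset[int] = frozenset({6, 7})
    edge5_positions: frozenset[int] = frozenset({8, 9})

    def __post_init__(self) -> None:
        sets = (self.seed_positions, self.nickase_positions, self.edge5_positions)
        if len(self.seed_positions | self.nickase_positions | self.edge5_positions) != sum(
            len(s) for s in sets
        ):
            raise ValueError("mismatch-model position sets must be disjoint")


DEFAULT_MISMATCH_MODEL = MismatchModel()


@dataclass
class TargetSite:
    """A tandem dual-strand match in canonical top-strand coordinates.

    ``region_a``/``region_b`` are (start, end, strand) where strand is the
    DNA strand paired by that spacer; the two regions lie on opposite
    strands with ``gap`` bp between their duplex footprints.  Mismatch lists
    hold 1-based spacer indices (1 = box-C-proximal, pairing the outer DNA
    base of the region).
    """

    contig: str
    start: int
    end: int
    gap: int
    region_a: tuple[int, int, str]
    region_b: tuple[int, int, str]
    mismatches_a: list[int]
    mismatches_b: list[int]
    footprint_seq: str = ""

    @property
    def total_mismatches(self) -> int:
        return len(self.mismatches_a) + len(self.mismatches_b)


@dataclass
class CleavageCall:
    """Predicted outcome and geometry for a target site.

    ``nick_a``/``nick_b`` are between-base top-strand coordinates of the
    nick on the A-matched / B-matched strand (None when that strand is not
    cleaved); ``outcome`` is ``dsb``, ``nick_A_strand`` (only the A-matched
    strand is cut), ``nick_B_strand``, or ``none``.  For a double-strand
    break the products carry 3' single-stranded overhangs of
    ``overhang_len`` nt (``footprint length - 2 * cut index``).
    """

    outcome: str
    nick_a: int | None
    nick_b: int | None
    overhang_len: int
    overhang_seq: str


@dataclass
class SsMatch:
    """A single-spacer match on single-stranded DNA."""

    spacer: str  # 'A' or 'B'
    start: int
    end: int
    nick: int
    mismatches: list[int]


def _allowed_top_bases(spacer: str, side: str, wobble: bool) -> list[set[str]]:
    """Top-strand bases compatible with each spacer base.

    ``side='left'``: the spacer pairs the bottom strand, base 1 at the
    region's left (outer) end; position j along the top strand pairs spacer
    base j+1, and pairing bottom base b means top base complement(b).
    ``side='right'``: the spacer pairs the top strand with base 1 at the
    right (outer) end; top position k pairs spacer base (len - k).
    """
    out: list[set[str]] = []
    if side == "left":
        for r in spacer:
            allowed = {complement(WC_RNA_DNA[r])}
            if wobble:
                if r == "G":
                    allowed.add("A")  # rG:dT on the bottom strand
                if r == "U":
                    allowed.add("C")  # rU:dG
            out.append(allowed)
    else:
        for r in reversed(spacer):
            allowed = {WC_RNA_DNA[r]}
            if wobble:
                if r == "G":
                    allowed.add("T")
                if r == "U":
                    allowed.add("G")
            out.append(allowed)
    return out


def _mismatch_indices(
    s: str, offset: int, allowed: list[set[str]], side: str, spacer_len: int
) -> list[int]:
    """1-based spacer indices mismatching at a genome offset."""
    out = []
    for j, ok in enumerate(allowed):
        if s[offset + j] not in ok:
            out.append(j + 1 if side == "left" else spacer_len - j)
    return sorted(out)


def _scan_pattern(s_arr: np.ndarray, allowed: list[set[str]], start_col: int, w: int) -> np.ndarray:
    """Mismatch counts for one region across all window offsets."""
    n = s_arr.size - w + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int32)
    mm = np.zeros(n, dtype=np.int32)
    for j, ok in enumerate(allowed):
        col = s_arr[start_col + j : start_col + j + n]
        good = np.zeros(n, dtype=bool)
        for b in ok:
            good |= col == ord(b)
        mm += ~good
    return mm


def find_sites(
    genome: NucSeq,
    guide: GuidePair,
    max_gap: int = 2,
    max_mm_per_region: int = 0,
    wobble: bool = False,
) -> list[TargetSite]:
    """All tandem dual-strand sites for a guide on double-stranded DNA.

    Both spacer arrangements (A-left/B-right and the C2-pseudosymmetric
    mirror) are scanned on top-strand coordinates so each physical site is
    reported exactly once; results are deduplicated by footprint and sorted
    by coordinate.
    """
    if genome.kind != "dna":
        raise ValueError("find_sites requires a DNA genome")
    s = genome.seq
    s_arr = np.frombuffer(s.encode(), dtype=np.uint8)
    found: dict[tuple[int, int], TargetSite] = {}
    for left_name in ("A", "B"):
        left_sp = guide.spacer_a if left_name == "A" else guide.spacer_b
        right_sp = guide.spacer_b if left_name == "A" else guide.spacer_a
        la, lb = len(left_sp), len(right_sp)
        allowed_left = _allowed_top_bases(left_sp, "left", wobble)
        allowed_right = _allowed_top_bases(right_sp, "right", wobble)
        for gap in range(max_gap + 1):
            w = la + gap + lb
            mm_left = _scan_pattern(s_arr, allowed_left, 0, w)
            mm_right = _scan_pattern(s_arr, allowed_right, la + gap, w)
            hits = np.flatnonzero(
                (mm_left <= max_mm_per_region) & (mm_right <= max_mm_per_region)
            )
            for i in map(int, hits):
                mml = _mismatch_indices(s, i, allowed_left, "left", la)
                mmr = _mismatch_indices(s, i + la + gap, allowed_right, "right", lb)
                region_left = (i, i + la, "-")
                region_right = (i + la + gap, i + w, "+")
                if left_name == "A":
                    site = TargetSite(
                        genome.id, i, i + w, gap, region_left, region_right,
                        mml, mmr, s[i : i + w],
                    )
                else:
                    site = TargetSite(
                        genome.id, i, i + w, gap, region_right, region_left,
                        mmr, mml, s[i : i + w],
                    )
                key = (i, i + w)
                prev = found.get(key)
                if prev is None or site.total_mismatches < prev.total_mismatches:
                    found[key] = site
    return [found[k] for k in sorted(found)]


def brute_force_find_sites(
    genome: NucSeq,
    guide: GuidePair,
    max_gap: int = 2,
    max_mm_per_region: int = 0,
    wobble: bool = False,
) -> list[TargetSite]:
    """Naive enumeration oracle: every offset, gap and strand assignment.

    Checks pairing base by base from first principles; must return the
    identical site set as :func:`find_sites` on all inputs.
    """
    s = genome.seq
    found: dict[tuple[int, int], TargetSite] = {}
    for left_name in ("A", "B"):
        left_sp = guide.spacer_a if left_name == "A" else guide.spacer_b
        right_sp = guide.spacer_b if left_name == "A" else guide.spacer_a
        la, lb = len(left_sp), len(right_sp)
        for gap in range(max_gap + 1):
            w = la + gap + lb
            for i in range(len(s) - w + 1):
                window = s[i : i + w]
                # ambiguity codes cannot pair and simply count as mismatches
                # left region: spacer pairs the bottom strand, base 1 at the
                # left end; bottom base under top coordinate i+j is the
                # complement of the top base.
                mm_left = []
                for j in range(la):
                    bottom = complement(window[j])
                    if not pairs_rna_dna(left_sp[j], bottom, wobble):
                        mm_left.append(j + 1)
                if len(mm_left) > max_mm_per_region:
                    continue
                # right region: spacer pairs the top strand, base 1 at the
                # right end (antiparallel: spacer runs right to left).
                mm_right = []
                for j in range(lb):
                    top = window[la + gap + j]
                    if not pairs_rna_dna(right_sp[lb - 1 - j], top, wobble):
                        mm_right.append(lb - j)
                if len(mm_right) > max_mm_per_region:
                    continue
                region_left = (i, i + la, "-")
                region_right = (i + la + gap, i + w, "+")
                if left_name == "A":
                    site = TargetSite(
                        genome.id, i, i + w, gap, region_left, region_right,
                        sorted(mm_left), sorted(mm_right), window,
                    )
                else:
                    site = TargetSite(
                        genome.id, i, i + w, gap, region_right, region_left,
                        sorted(mm_right), sorted(mm_left), window,
                    )
                key = (i, i + w)
                prev = found.get(key)
                if prev is None or site.total_mismatches < prev.total_mismatches:
                    found[key] = site
    return [found[k] for k in sorted(found)]


def _region_nick(region: tuple[int, int, str], site: TargetSite, cut_index: int) -> int:
    """Between-base top-strand coordinate of the nick on a region's strand.

    The matched strand is cut 5' of the base pairing spacer base
    ``cut_index``.  For the left region (spacer pairs the bottom strand,
    base 1 leftmost) that bond lies ``cut_index`` bases from the region
    start; for the right region it lies ``cut_index`` bases from the region
    end.
    """
    start, end, _ = region
    is_left = start == site.start
    return start + cut_index if is_left else end - cut_index


def predict_cleavage(
    site: TargetSite,
    model: MismatchModel | None = None,
    cut_index: int = CUT_INDEX,
) -> CleavageCall:
    """Classify the cleavage outcome of a site and place the nicks."""
    model = model or DEFAULT_MISMATCH_MODEL
    len_a = site.region_a[1] - site.region_a[0]
    len_b = site.region_b[1] - site.region_b[0]
    for mms, ln, name in ((site.mismatches_a, len_a, "A"), (site.mismatches_b, len_b, "B")):
        if any(i > ln for i in mms):
            raise ValueError(f"mismatch index exceeds spacer {name} length {ln}")
    killed = False
    for mms, ln in ((site.mismatches_a, len_a), (site.mismatches_b, len_b)):
        if any(i in model.seed_positions for i in mms):
            killed = True
        edge5 = {i for i in model.edge5_positions if i <= ln}
        if edge5 and edge5 <= set(mms):
            killed = True
    cleave_a = not killed and not any(
        i in model.nickase_positions for i in site.mismatches_a
    )
    cleave_b = not killed and not any(
        i in model.nickase_positions for i in site.mismatches_b
    )
    nick_a = _region_nick(site.region_a, site, cut_index) if cleave_a else None
    nick_b = _region_nick(site.region_b, site, cut_index) if cleave_b else None
    if cleave_a and cleave_b:
        outcome = "dsb"
        left_nick, right_nick = sorted((nick_a, nick_b))
        overhang_len = right_nick - left_nick
        overhang_seq = site.footprint_seq[left_nick - site.start : right_nick - site.start]
    else:
        outcome = (
            "nick_A_strand" if cleave_a else "nick_B_strand" if cleave_b else "none"
        )
        overhang_len = 0
        overhang_seq = ""
    return CleavageCall(outcome, nick_a, nick_b, overhang_len, overhang_seq)


def gap_scan(
    genome: NucSeq,
    guide: GuidePair,
    gaps: range | list[int] = range(7),
    model: MismatchModel | None = None,
) -> list[tuple[int, bool]]:
    """Cleavability per inter-region gap on a genome with planted sites.

    Sites are searched with the default ``max_gap=2`` (larger gaps are not
    sites at all), then classified; a gap is cleavable when some site with
    that gap yields a double-strand break.
    """
    sites = find_sites(genome, guide, max_gap=2)
    calls = [(s.gap, predict_cleavage(s, model).outcome) for s in sites]
    return [
        (g, any(gap == g and out == "dsb" for gap, out in calls)) for g in gaps
    ]


def ssdna_scan(
    strand_seq: NucSeq,
    guide: GuidePair,
    max_mm: int = 0,
    cut_index: int = CUT_INDEX,
) -> list[SsMatch]:
    """Independent per-spacer matches on single-stranded DNA.

    Each spacer can direct cleavage of a complementary single strand on its
    own; the nick keeps the same placement (5' of the base pairing spacer
    base ``cut_index``).  RNA input yields no matches (no activity on RNA).
    """
    if strand_seq.kind == "rna":
        return []
    s = strand_seq.seq
    out: list[SsMatch] = []
    for name, spacer in (("A", guide.spacer_a), ("B", guide.spacer_b)):
        L = len(spacer)
        for t in range(len(s) - L + 1):
            window = s[t : t + L]
            if any(c not in "ACGT" for c in window):
                continue
            # antiparallel: spacer base 1 pairs the 3'-most window base
            mms = [
                L - j
                for j in range(L)
                if not pairs_rna_dna(spacer[L - 1 - j], window[j])
            ]
            if len(mms) <= max_mm:
                out.append(SsMatch(name, t, t + L, t + L - cut_index, sorted(mms)))
    return sorted(out, key=lambda m: (m.start, m.spacer))


_SEVERITY = {"dsb": 0, "nick_A_strand": 1, "nick_B_strand": 1, "none": 2}


def off_target_scan(
    genome: NucSeq,
    guide: GuidePair,
    max_mm_per_region: int = 2,
    max_gap: int = 2,
    model: MismatchModel | None = None,
) -> list[tuple[TargetSite, CleavageCall]]:
    """Relaxed-mismatch site enumeration ranked by predicted severity.

    Deterministic order: outcome severity (dsb > nick > none), then total
    mismatches, then coordinate.
    """
    sites = find_sites(genome, guide, max_gap=max_gap, max_mm_per_region=max_mm_per_region)
    scored = [(site, predict_cleavage(site, model)) for site in sites]
    return sorted(
        scored,
        key=lambda sc: (_SEVERITY[sc[1].outcome], sc[0].total_mismatches, sc[0].start),
    )


def self_target_check(guide: GuidePair, construct_seq: NucSeq) -> bool:
    """True iff the guide finds a target site on its own expression construct.

    Tandem encoding places both spacers on the same strand, never in the
    dual-strand arrangement, so well-behaved guides return False; palindromic
    spacers are the corner case that can flip this.
    """
    return len(find_sites(construct_seq, guide, max_gap=2, max_mm_per_region=0)) > 0
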