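"""Seed-deterministic synthetic data: ground-truthed loci, genomes, reads.

Every generator takes a seed and reproduces byte-identical output for the
same seed.  Generated truth is sufficient to score detectors and scanners
without re-deriving anything.  Backgrounds are i.i.d. nucleotides (optional
GC bias); generators additionally guarantee that planted structure cannot be
coincidentally extended or duplicated by the background, so truth
coordinates are exact:

* locus boundaries: the background bases flanking a planted array never
  continue the truncated edge repeats;
* spacer columns are never constant across units (a constant column is
  indistinguishable from one more repeat base);
* target genomes are verified with the brute-force site oracle to contain
  exactly the planted sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seq import NucSeq, revcomp_str, transversion, rna_to_dna_str
from .grammar import (
    RepeatSet,
    TIGRArrayModel,
    TIGRUnit,
    TERMINATOR_CASSETTES,
    assemble_array,
)
from .processing import ReadEvidence, processing_sites
from .targets import GuidePair, brute_force_find_sites

#: Packaged default repeat set: edge 10 nt, loop 8 nt, 9+9-nt spacers,
#: processing offset 5 — one mature unit is exactly 36 nt.
TA_LIKE_REPEAT_SET = RepeatSet(
    edge_repeat="TGGATCGCCA",
    loop_repeat="TGAAACCA",
    spacer_len_a=9,
    spacer_len_b=9,
    processing_offset=5,
    enforce_boxes=True,
)

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


@dataclass
class LocusTruth:
    """Ground truth for a planted dual-repeat locus."""

    seq: NucSeq
    repeat_set: RepeatSet
    model: TIGRArrayModel
    array_start: int
    array_end: int
    strand: str
    mutations: list[tuple[int, str, str]]
    terminator: tuple[int, int] | None
    seed: int


@dataclass
class StemLoopLocusTruth:
    """Ground truth for a planted stem-loop locus."""

    seq: NucSeq
    unit_intervals: list[tuple[int, int]]
    subarray_sizes: tuple[int, ...]
    spacers: list[tuple[str, str]]
    seed: int


@dataclass
class PlantedSite:
    start: int
    end: int
    gap: int
    mismatches: list[tuple[str, int]]


@dataclass
class TargetGenomeTruth:
    seq: NucSeq
    guide: GuidePair
    sites: list[PlantedSite]
    seed: int


def make_repeat_set(
    seed: int, edge_len: int = 10, loop_len: int = 8, spacer_len: int = 9
) -> RepeatSet:
    """Random grammar-conformant repeat set: box motifs plus A-rich loop."""
    rng = np.random.default_rng(seed)
    while True:
        edge = "TG" + _random_seq(rng, edge_len - 5) + "CCA"
        interior = "".join(
            rng.choice(_BASES, p=[0.7, 0.1, 0.1, 0.1]) for _ in range(loop_len - 5)
        )
        if interior and interior.count("A") / len(interior) < 0.6:
            continue
        loop = "TG" + interior + "CCA"
        if edge != loop:
            return RepeatSet(
                edge, loop, spacer_len, spacer_len, edge_len // 2, enforce_boxes=True
            )


def _diverse_spacers(
    rng: np.random.Generator, n_units: int, length: int
) -> list[str]:
    """Random spacers whose columns are genuinely variable across units.

    No column's modal base may dominate: its count is capped at
    ``max(1, (n+1)//3)`` so a spacer column can never be mistaken for one
    more repeat column by an agreement-based detector (see the module
    docstring on exactness guarantees).
    """
    mat = rng.choice(_BASES, size=(n_units, length))
    if n_units >= 2:
        cap = max(1, (n_units + 1) // 3)
        for j in range(length):
            while True:
                col = mat[:, j]
                bases, counts = np.unique(col, return_counts=True)
                if counts.max() <= cap:
                    break
                modal = bases[np.argmax(counts)]
                rows = np.flatnonzero(col == modal)
                i = rows[int(rng.integers(rows.size))]
                rare = bases[np.argmin(counts)] if bases.size == 4 else next(
                    b for b in "ACGT" if b not in bases
                )
                mat[i, j] = rare
    return ["".join(row) for row in mat]


def make_locus(
    seed: int,
    repeat_set: RepeatSet | None = None,
    n_units: int = 8,
    background_len: int = 2000,
    per_copy_mutations: int = 0,
    with_terminator: bool = True,
    gc: float = 0.5,
    offset: int | None = None,
    stem_loop: bool = False,
    **stem_kwargs,
):
    """Plant one ground-truthed array in random background.

    Returns :class:`LocusTruth` (or :class:`StemLoopLocusTruth` when
    ``stem_loop`` is set).  ``per_copy_mutations`` substitutions are
    injected into every full loop copy and recorded.  Boundary background
    bases are constrained so the planted coordinates are unambiguous.
    """
    if stem_loop:
        return make_stem_loop_locus(seed, **stem_kwargs)
    rs = repeat_set or TA_LIKE_REPEAT_SET
    rng = np.random.default_rng(seed)
    spacers_a = _diverse_spacers(rng, n_units, rs.spacer_len_a)
    spacers_b = _diverse_spacers(rng, n_units, rs.spacer_len_b)
    units = [TIGRUnit(i + 1, spacers_a[i], spacers_b[i]) for i in range(n_units)]
    model = TIGRArrayModel(rs, units, has_terminator=with_terminator)
    cassette = None
    if with_terminator:
        p = rs.processing_offset
        cassette = next(
            cas for cas in TERMINATOR_CASSETTES if cas[0] != rs.edge_repeat[p]
        )
    body = assemble_array(
        TIGRArrayModel(
            rs, units, model.leading_edge_len, model.trailing_edge_len, False
        )
    ).seq
    insert = body + (cassette or "")

    mutations: list[tuple[int, str, str]] = []
    if per_copy_mutations:
        body_list = list(body)
        lead = model.leading_edge_len
        inner = rs.spacer_len_a + rs.loop_len + rs.spacer_len_b
        # spread mutated columns across copies so no loop column accumulates
        # several hits (keeps per-column agreement high for the detector)
        col_cycle: list[int] = []
        while len(col_cycle) < n_units * per_copy_mutations:
            col_cycle.extend(rng.permutation(rs.loop_len).tolist())
        for i in range(n_units):
            loop_start = lead + i * (inner + rs.edge_len) + rs.spacer_len_a
            positions = col_cycle[i * per_copy_mutations : (i + 1) * per_copy_mutations]
            for off in sorted(int(x) for x in positions):
                pos = loop_start + off
                ref = body_list[pos]
                alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
                body_list[pos] = alt
                mutations.append((pos, ref, alt))
        insert = "".join(body_list) + (cassette or "")

    if offset is None:
        offset = int(rng.integers(100, max(101, background_len - len(insert) - 100)))
    bg = list(_random_seq(rng, background_len, gc))
    if offset + len(insert) > background_len:
        raise ValueError("background too short for the planted array")
    # forbid coincidental edge-repeat extension at either boundary
    lead = model.leading_edge_len
    if 0 < lead < rs.edge_len and offset > 0:
        banned = rs.edge_repeat[rs.edge_len - lead - 1]
        if bg[offset - 1] == banned:
            bg[offset - 1] = "ACGT".replace(banned, "")[int(rng.integers(3))]
    if not with_terminator and offset + len(insert) < background_len:
        banned = rs.edge_repeat[model.trailing_edge_len]
        j = offset + len(insert)
        if model.trailing_edge_len < rs.edge_len and bg[j] == banned:
            bg[j] = "ACGT".replace(banned, "")[int(rng.integers(3))]
    genome = "".join(bg[:offset]) + insert + "".join(bg[offset + len(insert):])
    mutations = [(offset + pos, ref, alt) for pos, ref, alt in mutations]
    term_iv = None
    if with_terminator:
        term_iv = (offset + len(body), offset + len(insert))
    return LocusTruth(
        seq=NucSeq(f"locus_seed{seed}", genome, "dna"),
        repeat_set=rs,
        model=model,
        array_start=offset,
        array_end=offset + len(body),
        strand="+",
        mutations=mutations,
        terminator=term_iv,
        seed=seed,
    )


def _clean_mid(rng: np.random.Generator, length: int) -> str:
    """A/C linker free of 'CCA' and 'TG' so the unit grammar stays unambiguous."""
    while True:
        mid = "".join(rng.choice(["A", "C"], p=[0.7, 0.3]) for _ in range(length))
        if "CCA" not in mid:
            return mid


def make_stem_loop_locus(
    seed: int,
    subarray_sizes: tuple[int, ...] = (5, 4, 4),
    spacer_len: int = 9,
    arm_len: int = 6,
    long_linker: int = 450,
    short_linker: int = 8,
    flank: int = 300,
    break_palindromy_in: int | None = None,
) -> StemLoopLocusTruth:
    """Plant tandem stem-loop units organized into sub-arrays.

    Mirrors the canonical organization of stem-loop loci: several sub-arrays
    of hairpin units separated by long intergenic linkers.  Each unit is
    ``arm + CCA sA TG mid CCA sB TG + revcomp(arm)``.
    ``break_palindromy_in`` disrupts the innermost arm pair of that unit
    (0-based global index).
    """
    rng = np.random.default_rng(seed)
    parts: list[str] = [_random_seq(rng, flank)]
    unit_intervals: list[tuple[int, int]] = []
    spacers: list[tuple[str, str]] = []
    pos = flank
    idx = 0
    for s_i, size in enumerate(subarray_sizes):
        for u in range(size):
            arm = _random_seq(rng, arm_len)
            sa = _diverse_spacers(rng, 1, spacer_len)[0]
            sb = _diverse_spacers(rng, 1, spacer_len)[0]
            mid = _clean_mid(rng, 5)
            interior = "CCA" + sa + "TG" + mid + "CCA" + sb + "TG"
            arm3 = revcomp_str(arm)
            if idx == break_palindromy_in:
                # disrupt the innermost pair so the maximal arm shrinks to zero
                bad = transversion(arm3[0])
                arm3 = bad + arm3[1:]
            unit = arm + interior + arm3
            parts.append(unit)
            unit_intervals.append((pos, pos + len(unit)))
            spacers.append((sa, sb))
            pos += len(unit)
            idx += 1
            if u < size - 1:
                parts.append(_random_seq(rng, short_linker))
                pos += short_linker
        if s_i < len(subarray_sizes) - 1:
            parts.append(_random_seq(rng, long_linker))
            pos += long_linker
    parts.append(_random_seq(rng, flank))
    genome = list("".join(parts))
    # break any chance base pair between the flanks of a unit so the maximal
    # palindromic arm equals the planted arm exactly
    for a, b in unit_intervals:
        if a > 0 and b < len(genome) and genome[b] == transversion(genome[a - 1]):
            genome[b] = _nonpairing(rng, genome[a - 1])
    return StemLoopLocusTruth(
        seq=NucSeq(f"stemloop_seed{seed}", "".join(genome), "dna"),
        unit_intervals=unit_intervals,
        subarray_sizes=tuple(subarray_sizes),
        spacers=spacers,
        seed=seed,
    )


def _nonpairing(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != transversion(base)]
    return choices[int(rng.integers(len(choices)))]


def make_target_genome(
    seed: int,
    guide: GuidePair,
    n_sites: int = 1,
    gaps: tuple[int, ...] = (0,),
    mismatch_spec: list[list[tuple[str, int]]] | None = None,
    length: int = 10000,
    gc: float = 0.5,
    max_attempts: int = 50,
) -> TargetGenomeTruth:
    """Plant canonical-geometry target sites in random background.

    Site *i* uses ``gaps[i % len(gaps)]`` and, when given, the mismatches in
    ``mismatch_spec[i]`` (list of (region 'A'|'B', 1-based spacer index)):
    the paired DNA base is replaced by its transversion.  The genome is
    verified with the brute-force oracle to contain exactly the planted
    sites (resampling the background on collision).
    """
    a_dna = rna_to_dna_str(guide.spacer_a)
    b_dna = rna_to_dna_str(guide.spacer_b)
    la, lb = len(a_dna), len(b_dna)
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        genome = list(_random_seq(rng, length, gc))
        planted: list[PlantedSite] = []
        taken: list[tuple[int, int]] = []
        ok = True
        for i in range(n_sites):
            gap = gaps[i % len(gaps)]
            w = la + gap + lb
            mms = list(mismatch_spec[i]) if mismatch_spec else []
            for _try in range(200):
                start = int(rng.integers(50, length - w - 50))
                if all(start + w + 20 <= s or e + 20 <= start for s, e in taken):
                    break
            else:
                ok = False
                break
            window = a_dna + _random_seq(rng, gap) + revcomp_str(b_dna)
            wl = list(window)
            for region, idx in mms:
                if region == "A":
                    pos = idx - 1  # spacer base 1 pairs the left outer base
                else:
                    pos = la + gap + (lb - idx)  # base 1 pairs the right outer base
                wl[pos] = transversion(wl[pos])
            genome[start : start + w] = wl
            taken.append((start, start + w))
            planted.append(PlantedSite(start, start + w, gap, mms))
        if not ok:
            continue
        seq = NucSeq(f"target_genome_seed{seed}", "".join(genome), "dna")
        max_mm = max((len(p.mismatches) for p in planted), default=0)
        found = brute_force_find_sites(
            seq, guide, max_gap=max(gaps) if gaps else 2, max_mm_per_region=max_mm
        )
        expected = {(p.start, p.end) for p in planted}
        if {(s.start, s.end) for s in found} == expected:
            return TargetGenomeTruth(seq=seq, guide=guide, sites=planted, seed=seed)
    raise RuntimeError("could not plant unambiguous sites; widen the background")


def make_reads(
    array_model: TIGRArrayModel,
    completeness: float,
    n: int,
    boundary_jitter: int = 0,
    seed: int | None = None,
) -> tuple[ReadEvidence, list[tuple[int, int]]]:
    """Simulated processed-fragment read intervals on an array body.

    Returns (evidence, truth) where truth holds the exact pre-jitter
    fragment intervals.  ``boundary_jitter`` shifts each endpoint by a
    uniform integer in [-j, j] (clipped to the array).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    sites = processing_sites(array_model).sites
    inner = np.asarray(sites[1:-1])
    body = sites[-1]
    truth: list[tuple[int, int]] = []
    for _ in range(n):
        mask = rng.random(inner.size) < completeness
        cuts = [sites[0], *inner[mask].tolist(), sites[-1]]
        truth.extend(zip(cuts[:-1], cuts[1:]))
    intervals = []
    for s, e in truth:
        if boundary_jitter:
            s = int(np.clip(s + rng.integers(-boundary_jitter, boundary_jitter + 1), 0, body - 1))
            e = int(np.clip(e + rng.integers(-boundary_jitter, boundary_jitter + 1), s + 1, body))
        intervals.append((s, e))
    return ReadEvidence(intervals), truth
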