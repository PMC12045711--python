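"""De novo detection of dual-repeat and stem-loop TIGR arrays.

Dual-repeat detection is seeded by exact k-mer periodicity: a k-mer that
recurs at a near-constant period betrays the repeat scaffold, after which a
cyclic layout fit over the period separates the two repeat families from the
variable spacers and a grammar parse recovers the full model with exact
boundaries.  Stem-loop detection is grammar-first: box C/D-flanked dual
spacers are located by pattern matching and then validated by flanking
palindromic arms.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .seq import NucSeq, hamming, revcomp_str
from .grammar import (
    BOX_C_DNA,
    BOX_D_DNA,
    ParseError,
    RepeatSet,
    TIGRArrayModel,
    InvalidModelError,
    parse_array,
)

_IUPAC_FROM_SET = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M", frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass
class DetectionParams:
    """Tuning knobs for array detection (defaults follow the array grammar)."""

    k: int = 7
    period_range: tuple[int, int] = (30, 50)
    repeat_len_range: tuple[int, int] = (8, 12)
    spacer_len_range: tuple[int, int] = (8, 12)
    min_units: int = 3
    max_mismatch_per_copy: int = 2
    scan_both_strands: bool = True
    min_arm_len: int = 5
    max_stem_linker: int = 150
    max_spacer_identity: float = 0.9
    max_spacer_column_agreement: float = 0.85
    min_copy_identity: float = 0.85

    def __post_init__(self) -> None:
        min_period = 2 * self.repeat_len_range[0] + 2 * self.spacer_len_range[0]
        if self.period_range[0] < min_period - 2:
            raise ValueError(
                f"period_range min {self.period_range[0]} inconsistent with "
                f"repeat/spacer ranges (expected >= {min_period - 2})"
            )


@dataclass
class TerminatorCall:
    """A predicted rho-independent terminator (coordinates window-local)."""

    start: int
    end: int
    stem_len: int
    loop_len: int
    u_tract_len: int
    score: float


@dataclass
class ArrayCall:
    """A located dual-repeat array with its inferred genotype."""

    contig: str
    start: int
    end: int
    strand: str
    repeat_set: RepeatSet
    model: TIGRArrayModel
    per_copy_mismatches: list[int]
    score: float
    terminator: TerminatorCall | None = None

    @property
    def n_units(self) -> int:
        return self.model.n_units


@dataclass
class StemLoopUnit:
    """One palindromic stem-loop unit carrying a dual spacer."""

    start: int
    end: int
    arm_len: int
    arm5: tuple[int, int]
    arm3: tuple[int, int]
    boxC_offsets: tuple[int, int]
    boxD_offsets: tuple[int, int]
    spacer_a: str
    spacer_b: str


@dataclass
class StemLoopCall:
    contig: str
    start: int
    end: int
    strand: str
    units: list[StemLoopUnit]
    linkers: list[str]

    @property
    def n_units(self) -> int:
        return len(self.units)


@dataclass
class CovariationReport:
    """Edge/loop motif covariation across loci."""

    edge_motifs: list[str]
    loop_motifs: list[str]
    identity_covariation: float
    pair_complementarity: dict[tuple[int, int], dict[str, float]]


# ---------------------------------------------------------------------------
# terminator heuristic

_WC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def predict_terminator(
    seq: NucSeq, search_window: tuple[int, int] | None = None
) -> TerminatorCall | None:
    """Heuristic rho-independent terminator search.

    Requires a hairpin with stem >= 6 bp (at most one mismatch), loop of
    3-8 nt, and >= 4 T within the 8 nt immediately downstream; the
    highest-scoring candidate wins (stem length + U-tract length − mismatches,
    ties to the leftmost start).
    """
    lo, hi = search_window if search_window is not None else (0, len(seq))
    s = seq.seq[lo:hi]
    best: TerminatorCall | None = None
    for i in range(len(s)):
        for stem in range(6, 13):
            for loop in range(3, 9):
                j = i + stem + loop  # start of right arm
                end = j + stem
                if end > len(s):
                    continue
                left = s[i : i + stem]
                right = s[j : j + stem]
                mism = sum(
                    1 for a, b in zip(left, reversed(right)) if _WC.get(a) != b
                )
                if mism > 1:
                    continue
                tail = s[end : end + 8]
                if tail.count("T") < 4:
                    continue
                ut = 0
                for c in tail:
                    if c == "T":
                        ut += 1
                    else:
                        break
                score = stem + ut - 2 * mism + tail.count("T") * 0.1
                cand = TerminatorCall(lo + i, lo + end, stem, loop, ut, score)
                if best is None or cand.score > best.score or (
                    cand.score == best.score and cand.start < best.start
                ):
                    best = cand
    return best


# ---------------------------------------------------------------------------
# consensus / covariation

def build_consensus(units: list[str], threshold: float = 0.25) -> str:
    """Per-column IUPAC consensus covering residues at >= ``threshold`` frequency."""
    if not units:
        raise ValueError("cannot build a consensus from an empty list")
    length = len(units[0])
    if any(len(u) != length for u in units):
        raise ValueError("consensus requires equal-length copies")
    out = []
    n = len(units)
    for col in range(length):
        counts: dict[str, int] = defaultdict(int)
        for u in units:
            counts[u[col]] += 1
        keep = frozenset(b for b, c in counts.items() if c / n >= threshold)
        if not keep:  # no residue reaches threshold: fall back to the modal base
            keep = frozenset([max(counts, key=counts.get)])
        code = _IUPAC_FROM_SET.get(keep)
        if code is None:
            raise ValueError(f"non-ACGT residue in column {col}: {sorted(keep)}")
        out.append(code)
    return "".join(out)


def _extract_motif(repeat: str, positions: list[int]) -> str:
    out = []
    for p in positions:
        if not (-len(repeat) <= p < len(repeat)):
            raise IndexError(f"motif position {p} out of range for repeat {repeat}")
        out.append(repeat[p])
    return "".join(out)


def covariation_check(
    loci: list[tuple[str, str]],
    motif_positions: list[int],
    pair_positions: list[tuple[int, int]] | None = None,
) -> CovariationReport:
    """Identity covariation of edge/loop motifs plus intra-repeat pairing checks.

    ``motif_positions`` index into each repeat (negative indices allowed);
    identity covariation is the fraction of loci in which the edge and loop
    motifs are identical.  Each ``pair_positions`` entry is checked for
    Watson-Crick complementarity within the edge and within the loop repeat.
    """
    if len(loci) < 2:
        raise ValueError("covariation requires >= 2 loci")
    edge_motifs = [_extract_motif(e, motif_positions) for e, _ in loci]
    loop_motifs = [_extract_motif(l, motif_positions) for _, l in loci]
    ident = sum(1 for e, l in zip(edge_motifs, loop_motifs) if e == l) / len(loci)
    pairs: dict[tuple[int, int], dict[str, float]] = {}
    for i, j in pair_positions or []:
        res = {}
        for name, idx in (("edge", 0), ("loop", 1)):
            hits = 0
            for locus in loci:
                rep = locus[idx]
                if not (-len(rep) <= i < len(rep) and -len(rep) <= j < len(rep)):
                    raise IndexError(f"pair position ({i},{j}) out of range")
                hits += _WC.get(rep[i]) == rep[j]
            res[name] = hits / len(loci)
        pairs[(i, j)] = res
    return CovariationReport(edge_motifs, loop_motifs, ident, pairs)


# ---------------------------------------------------------------------------
# dual-repeat detection

def _kmer_chains(s: str, params: DetectionParams) -> list[tuple[int, list[int]]]:
    """Find k-mers recurring at a constant period; returns (period, positions)."""
    k = params.k
    pos_by_kmer: dict[str, list[int]] = defaultdict(list)
    for i in range(len(s) - k + 1):
        kmer = s[i : i + k]
        if "N" not in kmer:
            pos_by_kmer[kmer].append(i)
    dmin, dmax = params.period_range
    chains = []
    for positions in pos_by_kmer.values():
        if len(positions) < 2:
            continue
        pos_set = set(positions)
        for p in positions:
            for d in range(dmin, dmax + 1):
                if p - d in pos_set or p - 2 * d in pos_set:
                    continue  # not a chain start for this period
                if p + d not in pos_set and p + 2 * d not in pos_set:
                    continue
                chain = [p]
                q = p
                while True:
                    if q + d in pos_set:
                        q += d
                    elif q + 2 * d in pos_set:  # one mutated copy skipped
                        q += 2 * d
                    else:
                        break
                    chain.append(q)
                if len(chain) >= 2:
                    chains.append((d, chain))
    return chains


def _merge_chains(chains: list[tuple[int, list[int]]]) -> list[tuple[int, list[int]]]:
    by_period: dict[int, list[list[int]]] = defaultdict(list)
    for d, chain in chains:
        by_period[d].append(chain)
    groups = []
    for d, chain_list in by_period.items():
        chain_list.sort(key=lambda c: c[0])
        merged: list[list[list[int]]] = []
        for chain in chain_list:
            if merged and chain[0] <= max(p for c in merged[-1] for p in c) + 2 * d:
                merged[-1].append(chain)
            else:
                merged.append([chain])
        for cluster in merged:
            long_chains = [c for c in cluster if len(c) >= 3]
            keep = long_chains if long_chains else cluster
            positions = sorted({p for c in keep for p in c})
            groups.append((d, positions))
    return groups


#: A column joins a repeat segment only when it pays against this rent: true
#: repeat columns sit near 1.0 agreement (>= ~0.83 under the mismatch
#: budget), whereas variable spacer columns rarely exceed ~0.7.
_REPEAT_COLUMN_RENT = 0.76


def _fit_layout(
    agr: np.ndarray, d: int, params: DetectionParams
) -> tuple[int, int, int, int] | None:
    """Best cyclic (r1_off, r1_len, spacer1_len, r2_len) layout for the period.

    Maximizes summed repeat-column agreement above a fixed per-column rent,
    so low-agreement (variable) columns are never absorbed into a repeat.
    Returns None when no layout scores positive.
    """
    rlo, rhi = params.repeat_len_range
    slo, shi = params.spacer_len_range
    ext = np.concatenate([agr - _REPEAT_COLUMN_RENT, agr - _REPEAT_COLUMN_RENT])
    cs = np.concatenate([[0.0], np.cumsum(ext)])
    best_score = 0.0
    best = None
    for r1o in range(d):
        for r1l in range(rlo, rhi + 1):
            for s1 in range(slo, shi + 1):
                for r2l in range(rlo, rhi + 1):
                    s2 = d - r1l - s1 - r2l
                    if not (slo <= s2 <= shi):
                        continue
                    r2o = (r1o + r1l + s1) % d
                    score = (cs[r1o + r1l] - cs[r1o]) + (cs[r2o + r2l] - cs[r2o])
                    if score > best_score + 1e-9:
                        best_score = score
                        best = (r1o, r1l, s1, r2l)
    return best


def _majority_consensus(copies: list[str]) -> str:
    return "".join(
        max("ACGT", key=lambda b: sum(c[i] == b for c in copies))
        for i in range(len(copies[0]))
    )


def _extend_copies(
    s: str, first: int, step: int, length: int, cons: str, max_mm: int
) -> list[int]:
    """All consecutive copy positions of ``cons`` spaced by ``step`` around ``first``."""
    positions = [first]
    q = first - step
    while q >= 0 and hamming(s[q : q + length], cons) <= max_mm:
        positions.insert(0, q)
        q -= step
    q = first + step
    while q + length <= len(s) and hamming(s[q : q + length], cons) <= max_mm:
        positions.append(q)
        q += step
    return positions


def _mean_pairwise_identity(seqs: list[str]) -> float:
    pairs = [
        (a, b)
        for i, a in enumerate(seqs)
        for b in seqs[i + 1 :]
        if len(a) == len(b)
    ]
    if not pairs:
        return 0.0
    return float(np.mean([1 - hamming(a, b) / len(a) for a, b in pairs]))


def _parse_assignment(
    s: str,
    contig: str,
    edge_cons: str,
    loop_cons: str,
    sa_len: int,
    sb_len: int,
    lo: int,
    hi: int,
    params: DetectionParams,
) -> ArrayCall | None:
    """Parse a padded window under one edge/loop assignment; None on failure."""
    if edge_cons == loop_cons:
        return None
    mm = params.max_mismatch_per_copy
    try:
        rs = RepeatSet(edge_cons, loop_cons, sa_len, sb_len, enforce_boxes=False)
    except InvalidModelError:
        return None
    inner = sa_len + len(loop_cons) + sb_len + len(edge_cons)
    for _ in range(6):
        try:
            parsed = parse_array(NucSeq(contig, s[lo:hi], "dna"), rs, mm)
        except ParseError:
            return None
        model = parsed.model
        n = model.n_units
        if n <= params.min_units:
            break
        # a terminal unit whose loop copy plus adjacent edge copy accumulate
        # >= 3 substitutions is a chance boundary match, not a real unit:
        # drop it and re-parse on a narrowed window
        loop_mms, edge_mms = parsed.loop_mismatches, parsed.edge_mismatches
        first_loop = lo + parsed.start + model.leading_edge_len + sa_len
        last_loop = first_loop + (n - 1) * inner
        cost_l = loop_mms[0] + (edge_mms[0] if edge_mms else 0)
        cost_r = loop_mms[-1] + (edge_mms[-1] if edge_mms else 0)
        if cost_l >= 3 and cost_l >= cost_r:
            lo = first_loop + 1
            continue
        if cost_r >= 3:
            hi = last_loop + len(loop_cons) - 1
            continue
        break
    if model.n_units < params.min_units:
        return None
    # low-complexity guard: spacers must be genuinely variable
    spacers = [u.spacer_a for u in model.units] + [u.spacer_b for u in model.units]
    if _mean_pairwise_identity(spacers) > params.max_spacer_identity:
        return None
    # re-derive the processing offset from the measured trailing truncation
    trail = model.trailing_edge_len
    p = trail if 1 <= trail < len(edge_cons) else len(edge_cons) // 2
    rs2 = RepeatSet(edge_cons, loop_cons, sa_len, sb_len, p, enforce_boxes=False)
    model = TIGRArrayModel(
        rs2,
        model.units,
        leading_edge_len=model.leading_edge_len,
        trailing_edge_len=trail,
        has_terminator=model.has_terminator,
    )
    copy_mms = parsed.loop_mismatches + parsed.edge_mismatches
    rep_nt = model.n_units * len(loop_cons) + (model.n_units - 1) * len(edge_cons)
    score = 1.0 - sum(copy_mms) / rep_nt if rep_nt else 0.0
    if score < params.min_copy_identity:
        return None
    return ArrayCall(
        contig=contig,
        start=lo + parsed.start,
        end=lo + parsed.end,
        strand="+",
        repeat_set=rs2,
        model=model,
        per_copy_mismatches=copy_mms,
        score=score,
    )


def _candidate_from_group(
    s: str, contig: str, d: int, positions: list[int], params: DetectionParams
) -> ArrayCall | None:
    base, maxpos = positions[0], positions[-1]
    m = (maxpos - base) // d + 1
    if m < 3:
        return None
    rows = []
    for i in range(m - 1):  # last (possibly array-exiting) row excluded
        lo = base + i * d
        if lo + d > len(s):
            break
        rows.append(s[lo : lo + d])
    if len(rows) < 2:
        return None
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), d)
    agr = np.empty(d)
    for j in range(d):
        _, counts = np.unique(arr[:, j], return_counts=True)
        agr[j] = counts.max() / len(rows)
    layout = _fit_layout(agr, d, params)
    if layout is None:
        return None
    r1o, r1l, s1, r2l = layout
    s2 = d - r1l - s1 - r2l
    sp_cols = [
        j for j in range(d) if not _in_layout_repeat(j, r1o, r1l, r1o + r1l + s1, r2l, d)
    ]
    if sp_cols and float(np.mean(agr[sp_cols])) > params.max_spacer_column_agreement:
        return None

    def consensus(offset: int, length: int) -> str:
        copies = [
            s[base + i * d + offset : base + i * d + offset + length]
            for i in range(len(rows))
        ]
        return _majority_consensus(copies)

    cons1 = consensus(r1o, r1l)
    cons2 = consensus(r1o + r1l + s1, r2l)
    lo = max(0, base - 2 * d)
    hi = min(len(s), maxpos + 3 * d)
    # cyclic layout r1 [s1] r2 [s2]: if r1 is the loop, spacer B (after the
    # loop) has length s1 and spacer A has length s2, and vice versa.  The
    # edge/loop roles are not decidable from the period alone, so parse both
    # assignments and keep the cleaner one (higher mean copy identity, then
    # more units): the swapped reading systematically pays mismatches at the
    # truncated array boundaries.
    option_a = _parse_assignment(s, contig, cons2, cons1, s2, s1, lo, hi, params)
    option_b = _parse_assignment(s, contig, cons1, cons2, s1, s2, lo, hi, params)
    candidates = [c for c in (option_a, option_b) if c is not None]
    if not candidates:
        return None
    # under the true assignment both boundary truncations are strictly
    # partial edge copies (the swapped reading absorbs the outermost full
    # loop copies as full-length "truncations"), and the true reading always
    # explains one extra edge repeat's worth of sequence; mismatches are
    # penalized so chance boundary copies cannot inflate the coverage
    def canonical(c: ArrayCall) -> int:
        e = c.repeat_set.edge_len
        return (c.model.leading_edge_len < e) + (c.model.trailing_edge_len < e)

    def explained(c: ArrayCall) -> int:
        rs, m = c.repeat_set, c.model
        covered = (
            m.n_units * rs.loop_len
            + (m.n_units - 1) * rs.edge_len
            + m.leading_edge_len
            + m.trailing_edge_len
        )
        return covered - 4 * sum(c.per_copy_mismatches)

    return max(candidates, key=lambda c: (canonical(c), explained(c), -c.start))


def _in_layout_repeat(j: int, r1o: int, r1l: int, r2o: int, r2l: int, d: int) -> bool:
    for off, ln in ((r1o % d, r1l), (r2o % d, r2l)):
        if off + ln <= d:
            if off <= j < off + ln:
                return True
        elif j >= off or j < (off + ln) % d:
            return True
    return False


def _scan_one_strand(s: str, contig: str, params: DetectionParams) -> list[ArrayCall]:
    chains = _kmer_chains(s, params)
    calls = []
    for d, positions in _merge_chains(chains):
        call = _candidate_from_group(s, contig, d, positions, params)
        if call is not None:
            calls.append(call)
    return calls


def _box_conformity(rs: RepeatSet) -> int:
    score = 0
    for rep in (rs.edge_repeat, rs.loop_repeat):
        score += rep.startswith(BOX_D_DNA) + rep.endswith(BOX_C_DNA)
    return score


def _dedupe(calls: list[ArrayCall]) -> list[ArrayCall]:
    ranked = sorted(
        calls,
        key=lambda c: (-c.n_units, -c.score, -_box_conformity(c.repeat_set), c.strand, c.start),
    )
    kept: list[ArrayCall] = []
    for call in ranked:
        if any(call.start < other.end and other.start < call.end for other in kept):
            continue
        kept.append(call)
    return sorted(kept, key=lambda c: (c.start, c.end))


def detect_dual_repeat_arrays(seq: NucSeq, params: DetectionParams | None = None) -> list[ArrayCall]:
    """Locate dual-repeat arrays de novo; empty list when none qualify.

    Calls are non-overlapping, sorted by coordinate, and each embeds the
    parsed model (which re-assembles to the called region within the allowed
    per-copy mismatches).  Reverse-strand arrays are reported with
    plus-strand coordinates and ``strand='-'``; their models describe the
    reverse-complement orientation.
    """
    params = params or DetectionParams()
    s = seq.seq
    calls = _scan_one_strand(s, seq.id, params)
    if params.scan_both_strands:
        rc = revcomp_str(s)
        for call in _scan_one_strand(rc, seq.id, params):
            call.start, call.end = len(s) - call.end, len(s) - call.start
            call.strand = "-"
            calls.append(call)
    calls = _dedupe(calls)
    for call in calls:
        # terminator sits immediately downstream of the array 3' end, which
        # on the minus strand maps to upstream of call.start in plus coords
        window_seq = s if call.strand == "+" else revcomp_str(s)
        w_start = call.end if call.strand == "+" else len(s) - call.start
        if w_start >= len(s):
            continue
        hit = predict_terminator(
            NucSeq(seq.id, window_seq, "dna"),
            (w_start, min(len(s), w_start + 60)),
        )
        if hit is not None and hit.start - w_start <= 5:
            call.terminator = hit
            call.model.has_terminator = True
    return calls


# ---------------------------------------------------------------------------
# stem-loop detection

_MAX_STEM_MID = 40


def _units_on_strand(s: str, params: DetectionParams) -> list[StemLoopUnit]:
    """Enumerate box C/D dual-spacer interiors and validate flanking arms.

    Every split ``CCA sA TG mid CCA sB TG`` (spacers 8-12 nt) is tried at
    every "CCA" anchor; a candidate becomes a unit when the sequences
    flanking the interior form a palindromic stem of >= ``min_arm_len`` bp.
    Overlapping interpretations are resolved in favor of the longest arms.
    """
    slo, shi = params.spacer_len_range
    candidates: list[StemLoopUnit] = []
    i = s.find("CCA")
    while i != -1:
        for sa_len in range(slo, shi + 1):
            d1 = i + 3 + sa_len
            if s[d1 : d1 + 2] != "TG":
                continue
            sa = s[i + 3 : d1]
            if "N" in sa:
                continue
            for mid_len in range(_MAX_STEM_MID + 1):
                c2 = d1 + 2 + mid_len
                if s[c2 : c2 + 3] != "CCA":
                    continue
                for sb_len in range(slo, shi + 1):
                    d2 = c2 + 3 + sb_len
                    if s[d2 : d2 + 2] != "TG":
                        continue
                    sb = s[c2 + 3 : d2]
                    if "N" in sb:
                        continue
                    j = d2 + 2  # interior end
                    arm = 0
                    while (
                        i - arm - 1 >= 0
                        and j + arm < len(s)
                        and _WC.get(s[i - arm - 1]) == s[j + arm]
                    ):
                        arm += 1
                    if arm < params.min_arm_len:
                        continue
                    candidates.append(
                        StemLoopUnit(
                            start=i - arm,
                            end=j + arm,
                            arm_len=arm,
                            arm5=(i - arm, i),
                            arm3=(j, j + arm),
                            boxC_offsets=(i, c2),
                            boxD_offsets=(d1, d2),
                            spacer_a=sa,
                            spacer_b=sb,
                        )
                    )
        i = s.find("CCA", i + 1)
    # resolve overlapping interpretations: longest arms, then leftmost start
    candidates.sort(key=lambda u: (-u.arm_len, u.start, u.end))
    kept: list[StemLoopUnit] = []
    for u in candidates:
        if any(u.start < k.end and k.start < u.end for k in kept):
            continue
        kept.append(u)
    return sorted(kept, key=lambda u: u.start)


def detect_stem_loop_arrays(seq: NucSeq, params: DetectionParams | None = None) -> list[StemLoopCall]:
    """Find tandem arrays of palindromic stem-loop units with box C/D spacers.

    Units separated by more than ``params.max_stem_linker`` nt start a new
    call (sub-arrays); calls require at least ``params.min_units`` units.
    """
    params = params or DetectionParams()
    calls: list[StemLoopCall] = []
    strands = [("+", seq.seq)]
    if params.scan_both_strands:
        strands.append(("-", revcomp_str(seq.seq)))
    for strand, s in strands:
        units = _units_on_strand(s, params)
        group: list[StemLoopUnit] = []

        def flush() -> None:
            if len(group) >= params.min_units:
                linkers = [
                    s[a.end : b.start] for a, b in zip(group, group[1:])
                ]
                calls.append(
                    StemLoopCall(seq.id, group[0].start, group[-1].end, strand, list(group), linkers)
                )

        for u in units:
            if group and u.start - group[-1].end > params.max_stem_linker:
                flush()
                group = []
            group.append(u)
        flush()
    # map minus-strand coordinates back to the plus strand
    L = len(seq)
    for call in calls:
        if call.strand == "-":
            call.start, call.end = L - call.end, L - call.start
    return sorted(calls, key=lambda c: (c.start, c.end))


def stem_loop_mature_intervals(call: StemLoopCall, slop: int = 3) -> list[tuple[int, int]]:
    """Mature-unit intervals for a stem-loop call: the hairpin plus flank slop.

    Processing boundaries of stem-loop units are variable, so mature RNAs are
    modelled as the intact hairpin with up to ``slop`` nt of flanking
    sequence rather than a fixed cut.
    """
    return [(max(call.start, u.start - slop), u.end + slop) for u in call.units]
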