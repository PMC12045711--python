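"""Maturation of array transcripts into guides and processing-site scoring.

Processing is modelled as deterministic cuts at ``processing_offset`` inside
every full edge repeat (the responsible host RNase is unknown, so no
enzymology is attempted): each cut sits one repeat period from the next, and
mature guides span mid-edge to mid-edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seq import dna_to_rna_str
from .grammar import TIGRArrayModel, TigRNA, unit_period


@dataclass
class ProcessingSiteSet:
    """Predicted cut coordinates on an array body (termini included)."""

    sites: list[int]
    period: int

    def __post_init__(self) -> None:
        if sorted(self.sites) != self.sites:
            raise ValueError("processing sites must be sorted")


@dataclass
class ReadEvidence:
    """Aligned small-RNA read intervals on an array (0-based half-open)."""

    intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        for s, e in self.intervals:
            if e <= s:
                raise ValueError(f"degenerate read interval ({s}, {e})")

    @property
    def lengths(self) -> list[int]:
        return [e - s for s, e in self.intervals]


def processing_sites(model: TIGRArrayModel) -> ProcessingSiteSet:
    """All predicted cuts: both termini plus one per full edge repeat."""
    rs = model.repeat_set
    period = unit_period(rs)
    inner = rs.spacer_len_a + rs.loop_len + rs.spacer_len_b
    sites = [0]
    for i in range(1, model.n_units):
        edge_start = model.leading_edge_len + i * inner + (i - 1) * rs.edge_len
        sites.append(edge_start + rs.processing_offset)
    sites.append(model.body_length)
    return ProcessingSiteSet(sites=sites, period=period)


def extract_tigRNAs(model: TIGRArrayModel) -> list[TigRNA]:
    """Mature guides of an array, one per unit, each one period long."""
    rs = model.repeat_set
    e, p = rs.edge_len, rs.processing_offset
    edge3 = dna_to_rna_str(rs.edge_repeat[p:])
    edge5 = dna_to_rna_str(rs.edge_repeat[:p])
    loop = dna_to_rna_str(rs.loop_repeat)
    out = []
    for unit in model.units:
        boxC1 = len(edge3) - 3
        boxC2 = len(edge3) + rs.spacer_len_a + rs.loop_len - 3
        boxD1 = len(edge3) + rs.spacer_len_a
        boxD2 = len(edge3) + rs.spacer_len_a + rs.loop_len + rs.spacer_len_b
        out.append(
            TigRNA(
                id=f"tigRNA{unit.index}",
                edge_3part=edge3,
                spacer_a=dna_to_rna_str(unit.spacer_a),
                loop=loop,
                spacer_b=dna_to_rna_str(unit.spacer_b),
                edge_5part=edge5,
                boxC_positions=(boxC1, boxC2),
                boxD_positions=(boxD1, boxD2),
            )
        )
    return out


def simulate_partial_processing(
    model: TIGRArrayModel,
    completeness: float,
    n: int,
    seed: int | None = None,
) -> list[int]:
    """Fragment lengths from ``n`` transcripts cut independently per site.

    Each internal processing site is cut with probability ``completeness``;
    both termini are always processed, so every fragment length is a sum of
    consecutive inter-site distances (multiples of the unit period when the
    boundary truncations together make up one full edge repeat).
    """
    if not (0.0 <= completeness <= 1.0):
        raise ValueError("completeness must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sites = np.asarray(processing_sites(model).sites)
    inner = sites[1:-1]
    lengths: list[int] = []
    cut_draws = rng.random((n, inner.size)) < completeness
    for row in cut_draws:
        cuts = np.concatenate(([sites[0]], inner[row], [sites[-1]]))
        lengths.extend(np.diff(cuts).tolist())
    return lengths


def processing_concordance(
    evidence: ReadEvidence, sites: ProcessingSiteSet, tol: int = 0
) -> float:
    """Fraction of reads whose start AND end both fall within ``tol`` of cuts."""
    if tol < 0:
        raise ValueError("tol must be >= 0")
    if not evidence.intervals:
        raise ValueError("empty read evidence")
    cuts = np.asarray(sites.sites)

    def near(x: int) -> bool:
        return bool(np.min(np.abs(cuts - x)) <= tol)

    hits = sum(1 for s, e in evidence.intervals if near(s) and near(e))
    return hits / len(evidence.intervals)


def read_evidence_from_bed(path: str) -> ReadEvidence:
    """Load read intervals from a BED file (first three columns used)."""
    intervals = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            intervals.append((int(fields[1]), int(fields[2])))
    return ReadEvidence(intervals)


def read_evidence_from_sam(path: str) -> ReadEvidence:
    """Load aligned read intervals from a SAM file (array as reference)."""
    import pysam

    intervals = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            intervals.append((aln.reference_start, aln.reference_end))
    return ReadEvidence(intervals)
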