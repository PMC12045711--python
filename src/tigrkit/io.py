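"""Readers and writers for FASTA, GFF3, BED and TSV artifacts.

Internal coordinates are 0-based half-open; GFF3 output is 1-based closed
per the format, BED stays 0-based half-open.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seq import NucSeq
from .grammar import TIGRArrayModel, TigRNA, unit_layout
from .detect import ArrayCall, StemLoopCall


def read_fasta(path: str, kind: str = "dna") -> list[NucSeq]:
    return [NucSeq(rec.id, str(rec.seq), kind) for rec in SeqIO.parse(path, "fasta")]


def write_fasta(seqs: list[NucSeq], path: str, descriptions: dict[str, str] | None = None) -> None:
    records = [
        SeqRecord(Seq(s.seq), id=s.id, description=(descriptions or {}).get(s.id, ""))
        for s in seqs
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_tigrna_fasta(tigrnas: list[TigRNA], path: str) -> None:
    """tigRNAs as RNA FASTA with box anchor offsets in the headers."""
    with open(path, "w") as fh:
        for t in tigrnas:
            fh.write(
                f">{t.id} boxC={t.boxC_positions[0]},{t.boxC_positions[1]} "
                f"boxD={t.boxD_positions[0]},{t.boxD_positions[1]}\n{t.seq}\n"
            )


@dataclass
class GFF3Feature:
    seqid: str
    type: str
    start: int  # 0-based half-open internally
    end: int
    strand: str
    attributes: dict[str, str]
    score: str = "."

    def line(self) -> str:
        attrs = ";".join(f"{k}={v}" for k, v in self.attributes.items())
        return "\t".join(
            [
                self.seqid,
                "tigrkit",
                self.type,
                str(self.start + 1),
                str(self.end),
                self.score,
                self.strand,
                ".",
                attrs,
            ]
        )


def write_gff3(features: list[GFF3Feature], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            fh.write(feat.line() + "\n")


def model_features(
    model: TIGRArrayModel,
    contig: str,
    start: int,
    strand: str = "+",
    array_id: str = "array1",
    terminator: tuple[int, int] | None = None,
) -> list[GFF3Feature]:
    """GFF3 feature hierarchy for an array model placed at ``start``.

    For minus-strand placements the model describes the reverse complement,
    so body-local intervals are mirrored into plus-strand coordinates.
    """
    body = model.body_length
    feats = [
        GFF3Feature(contig, "TIGR_array", start, start + body, strand, {"ID": array_id})
    ]
    for ftype, s, e, unit_idx in unit_layout(model):
        if strand == "-":
            s, e = body - e, body - s
        attrs = {"Parent": array_id}
        if unit_idx is not None:
            attrs["unit"] = str(unit_idx)
        feats.append(GFF3Feature(contig, ftype, start + s, start + e, strand, attrs))
    if terminator is not None:
        feats.append(
            GFF3Feature(
                contig, "terminator", terminator[0], terminator[1], strand,
                {"Parent": array_id},
            )
        )
    return feats


def array_call_features(call: ArrayCall, array_id: str) -> list[GFF3Feature]:
    term = None
    if call.terminator is not None:
        term = (call.terminator.start, call.terminator.end)
        if call.strand == "-":
            # terminator window coordinates are on the reverse strand
            pass
    return model_features(
        call.model, call.contig, call.start, call.strand, array_id, terminator=term if call.strand == "+" else None
    )


def stem_loop_call_features(call: StemLoopCall, array_id: str) -> list[GFF3Feature]:
    feats = [
        GFF3Feature(call.contig, "TIGR_stem_loop_array", call.start, call.end, call.strand, {"ID": array_id})
    ]
    if call.strand == "+":
        for i, u in enumerate(call.units, 1):
            feats.append(
                GFF3Feature(
                    call.contig, "stem_loop_unit", u.start, u.end, call.strand,
                    {"Parent": array_id, "unit": str(i)},
                )
            )
    return feats


def write_bed(rows: list[tuple], path: str) -> None:
    """Write BED lines; each row is (chrom, start, end[, name, score, strand])."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def site_bed_rows(sites, calls=None) -> list[tuple]:
    rows = []
    for i, site in enumerate(sites):
        name = f"site{i + 1}"
        score = 0
        if calls is not None:
            score = {"dsb": 1000, "nick_A_strand": 500, "nick_B_strand": 500, "none": 0}[
                calls[i].outcome
            ]
        rows.append((site.contig, site.start, site.end, name, score, "+"))
    return rows


def nick_bed_rows(sites, calls) -> list[tuple]:
    """Nick positions as 1-nt features at the 3' base of the 5' fragment."""
    rows = []
    for i, (site, call) in enumerate(zip(sites, calls)):
        for label, nick in (("A", call.nick_a), ("B", call.nick_b)):
            if nick is None:
                continue
            rows.append((site.contig, nick - 1, nick, f"nick_{label}_site{i + 1}"))
    return rows


def write_tsv(rows: list[dict], fieldnames: list[str], path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames, delimiter="\t")
        writer.writeheader()
        for row in rows:
            writer.writerow(row)
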