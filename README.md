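# tigrkit

Toolkit for Tandem Interspaced Guide RNA (TIGR) arrays: de novo detection of
dual-repeat and stem-loop guide arrays in nucleotide sequence, derivation of
mature 36-nt-class guides (tigRNAs), prediction of tandem dual-strand DNA
target sites with full cleavage geometry, and design of guides plus minimal
expression arrays for user-chosen targets.

## The model in one paragraph

A dual-repeat array alternates two short repeats (the *edge* and *loop*
repeats, 8–12 nt, both bounded by a box D "TG"/box C "CCA" motif pair)
separated by two variable spacers per unit (typically 9 nt).  Arrays begin
and end with truncated edge repeats and are followed by a rho-independent
terminator.  Transcripts are processed at a fixed offset inside each edge
repeat into mature guides of exactly one repeat period (36 nt for the
packaged default: edge 10 + loop 8 + 2×9 spacers).  Each guide targets
double-stranded DNA through both spacers acting in tandem — spacer A pairs
one strand, spacer B the other, over adjacent regions 0–2 bp apart — and
each matched strand is nicked 5′ of the base pairing spacer base 5 (counted
from box C), leaving 8-nt 3′ overhangs on a perfect zero-gap 9+9 site.
Mismatches at spacer positions {4,5} (seed) abolish cleavage of both
strands; positions {6,7} abolish only the impaired strand (nickase);
simultaneous mismatches at both 5′-edge positions {8,9} of one region
abolish cleavage; other single mismatches are tolerated.  No target-adjacent
motif is required, and the tandem encoding means guides never target their
own expression arrays.

## Layout

| module | contents |
| --- | --- |
| `tigrkit.seq` | `NucSeq`, reverse complement, DNA/RNA transliteration, pairing rules |
| `tigrkit.grammar` | `RepeatSet`, `TIGRArrayModel`, `TigRNA`, assembly/parsing, config + GFF3 layout |
| `tigrkit.detect` | dual-repeat and stem-loop array detectors, terminator heuristic, consensus, covariation |
| `tigrkit.processing` | tigRNA extraction, partial-processing simulation, read-boundary concordance |
| `tigrkit.targets` | `find_sites` + brute-force oracle, cleavage prediction, gap/ssDNA/off-target scans |
| `tigrkit.design` | guide enumeration for a region, minimal expression-array construction |
| `tigrkit.fixtures` | seed-deterministic synthetic loci, target genomes, and reads with ground truth |
| `tigrkit.io` / `tigrkit.cli` | FASTA/GFF3/BED/TSV writers and the `tigrkit` command line |

## Command line

```sh
# detect arrays and write GFF3 (+ optional TSV summary)
tigrkit detect --fasta contigs.fa --out calls.gff3 --tsv calls.tsv
tigrkit detect --fasta contigs.fa --out stems.gff3 --stem-loop

# scan a genome for target sites of one guide (spacers may be DNA or RNA)
tigrkit scan --fasta genome.fa --spacer-a ACGUACGUA --spacer-b GGAUCCGGA \
    --out sites.bed --nicks nicks.bed --report report.tsv

# design guides + expression constructs for a target region
tigrkit design --fasta region.fa --repeat-config ta_like.cfg \
    --out designs.tsv --constructs constructs.fa

# synthetic fixtures with ground truth
tigrkit simulate locus --seed 1 --fasta locus.fa --gff3 truth.gff3 --truth truth.json
tigrkit simulate genome --seed 1 --spacer-a ACGUACGUA --spacer-b GGAUCCGGA \
    --fasta genome.fa --bed sites.bed
tigrkit simulate reads --seed 1 --completeness 0.5 --bed reads.bed
```

## Conventions

Coordinates are 0-based half-open internally and in BED output; GFF3 output
is 1-based closed.  Nick positions are between-base coordinates (the number
of bases to their left); BED nick features mark the 3′ base of the 5′
fragment.  Minus-strand array calls are reported in plus-strand coordinates
with `strand='-'`; their embedded models describe the reverse-complement
orientation.
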