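"""Standard-format readers and writers: FASTQ, SAM, BedGraph.

SAM goes through pysam; FASTQ through Biopython.  Coordinates are converted
to each format's convention at the boundary (SAM/BedGraph writers emit what
their standards require; everything in memory stays 0-based half-open).
"""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np
import pysam
from Bio import SeqIO

from .mapping import AlignmentRecord, MappedPair, PairClass, pair_reads

__all__ = [
    "write_fastq_pairs",
    "iter_fastq_pairs",
    "write_sam",
    "read_sam",
    "write_bedgraph",
    "read_bedgraph",
]

_PHRED40 = 40  # constant base quality for simulated reads


def write_fastq_pairs(records, path1, path2) -> None:
    """Write simulated ReadPairRecords as two mate FASTQ files (constant
    Phred 40 qualities — simulated reads are error-free)."""
    with open(path1, "w") as h1, open(path2, "w") as h2:
        for rec in records:
            q1 = chr(_PHRED40 + 33) * len(rec.mate1)
            q2 = chr(_PHRED40 + 33) * len(rec.mate2)
            h1.write(f"@{rec.read_id}\n{rec.mate1}\n+\n{q1}\n")
            h2.write(f"@{rec.read_id}\n{rec.mate2}\n+\n{q2}\n")


def iter_fastq_pairs(path1, path2):
    """Yield (read_id, seq1, seq2) from two mate FASTQ files."""
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    for r1, r2 in itertools.zip_longest(it1, it2):
        if r1 is None or r2 is None:
            raise ValueError("mate FASTQ files differ in length")
        if r1.id != r2.id:
            raise ValueError(f"mate ids differ: {r1.id} vs {r2.id}")
        yield r1.id, str(r1.seq).upper(), str(r2.seq).upper()


def _sam_header(chromosome_lengths: dict) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": n, "LN": int(l)} for n, l in chromosome_lengths.items()],
        }
    )


def write_sam(mapped_pairs, chromosome_lengths: dict, path) -> None:
    """Write mate pairs to SAM.  Mapped mates carry an NH tag with the
    perfect-match locus count; unmapped mates are emitted with the unmapped
    flag so totals stay auditable."""
    header = _sam_header(chromosome_lengths)
    refs = list(chromosome_lengths)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for mp in mapped_pairs:
            for mate_idx, (aln, other) in enumerate(
                ((mp.aln1, mp.aln2), (mp.aln2, mp.aln1))
            ):
                seg = pysam.AlignedSegment(header)
                seg.query_name = mp.read_id
                flag = 0x1 | (0x40 if mate_idx == 0 else 0x80)
                if aln is None:
                    flag |= 0x4
                    seg.flag = flag
                    seg.reference_id = -1
                    seg.reference_start = -1
                    out.write(seg)
                    continue
                if aln.strand == "-":
                    flag |= 0x10
                if other is None:
                    flag |= 0x8
                elif other.strand == "-":
                    flag |= 0x20
                if mp.pair_class is PairClass.CONCORDANT:
                    flag |= 0x2
                seg.flag = flag
                seg.reference_id = refs.index(aln.chromosome)
                seg.reference_start = aln.start
                seg.mapping_quality = 255
                seg.cigarstring = f"{aln.length}M"
                if other is not None:
                    seg.next_reference_id = refs.index(other.chromosome)
                    seg.next_reference_start = other.start
                seg.set_tag("NH", aln.n_hits)
                out.write(seg)


def read_sam(path) -> tuple:
    """Read a SAM file back into (mapped_pairs, chromosome_lengths).

    Pair classification is recomputed from the two mates, so a pipeline fed
    its own SAM output reproduces its reports exactly.
    """
    pairs: dict[str, list] = {}
    with pysam.AlignmentFile(str(path), "r") as sam:
        lengths = dict(zip(sam.references, sam.lengths))
        for seg in sam.fetch(until_eof=True):
            slot = pairs.setdefault(seg.query_name, [None, None])
            idx = 1 if seg.is_read2 else 0
            if seg.is_unmapped:
                continue
            slot[idx] = AlignmentRecord(
                read_id=seg.query_name,
                chromosome=seg.reference_name,
                start=seg.reference_start,
                length=seg.query_length or seg.infer_query_length() or 0,
                strand="-" if seg.is_reverse else "+",
                n_hits=int(seg.get_tag("NH")) if seg.has_tag("NH") else 1,
            )
    if not pairs:
        raise ValueError(f"SAM file {path} contains no reads")
    mapped = [
        MappedPair(rid, a1, a2, pair_reads(a1, a2)) for rid, (a1, a2) in pairs.items()
    ]
    return mapped, lengths


def write_bedgraph(track_values: dict, path) -> None:
    """Write per-base values as BedGraph (runs of equal value merged)."""
    with open(path, "w") as out:
        for chrom, values in track_values.items():
            values = np.asarray(values)
            if values.size == 0:
                continue
            change = np.nonzero(np.diff(values))[0] + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [values.size]))
            for s, e in zip(starts, ends):
                v = values[s]
                out.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path, chromosome_lengths: dict) -> dict:
    out = {c: np.zeros(l) for c, l in chromosome_lengths.items()}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("track", "#")):
            continue
        chrom, s, e, v = line.split("\t")
        out[chrom][int(s): int(e)] = float(v)
    return out
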