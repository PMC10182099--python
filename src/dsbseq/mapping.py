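"""Zero-mismatch end-to-end read mapping.

Implements a Bowtie-style strict alignment contract (``-v 0``, end-to-end,
multi-mapped reads removed) as an exact-match k-mer index: every
read either matches the reference perfectly somewhere or is unmapped.  For
coverage work, reads with more than one perfect locus are dropped entirely,
which is deterministic and — on a repeat-free reference — identical to
keeping one arbitrary locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .reference import GenomeMap, revcomp

__all__ = [
    "AlignmentRecord",
    "ExactMatchIndex",
    "PairClass",
    "map_read",
    "pair_reads",
    "naive_scan",
]

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    chromosome: str
    start: int  # 0-based leftmost reference coordinate
    length: int
    strand: str  # '+' or '-'
    n_hits: int

    @property
    def unique(self) -> bool:
        return self.n_hits == 1

    @property
    def end(self) -> int:
        return self.start + self.length


class PairClass(str, Enum):
    CONCORDANT = "concordant"
    DISCORDANT = "discordant"
    PARTIAL = "partial"
    UNMAPPED = "unmapped"


class ExactMatchIndex:
    """Hash index of every length-k reference substring.

    Only the forward strand is stored; a read is located by looking up both
    the read and its reverse complement, so each genomic locus is reported
    once per orientation.
    """

    def __init__(self, genome: GenomeMap, k: int = 75):
        if k > min(len(s) for s in genome.chromosomes.values()):
            raise ValueError("k exceeds the shortest chromosome")
        self.k = k
        self.genome = genome
        table: dict[str, list] = {}
        for name, seq in genome.chromosomes.items():
            for i in range(len(seq) - k + 1):
                table.setdefault(seq[i: i + k], []).append((name, i))
        self._table = table

    def locate(self, read: str) -> list:
        """All perfect-match loci of ``read`` as (chromosome, start, strand)."""
        hits = [(c, p, "+") for c, p in self._table.get(read, ())]
        rc = revcomp(read)
        hits += [(c, p, "-") for c, p in self._table.get(rc, ())]
        return hits


def map_read(read: str, index: ExactMatchIndex, read_id: str = "") -> AlignmentRecord | None:
    """Map one read under the 0-mismatch contract; None if unmapped.

    Reads whose length differs from the index k are rejected (callers count
    them in totals); reads containing non-ACGT symbols never match.
    """
    if len(read) != index.k:
        return None
    if not _ACGT.issuperset(read):
        return None
    hits = index.locate(read)
    if not hits:
        return None
    chrom, pos, strand = hits[0]
    return AlignmentRecord(
        read_id=read_id, chromosome=chrom, start=pos, length=index.k,
        strand=strand, n_hits=len(hits),
    )


def pair_reads(aln1: AlignmentRecord | None, aln2: AlignmentRecord | None,
               insert_bounds: tuple = (50, 2000)) -> PairClass:
    """Classify a mate pair from its two single-end alignments.

    Discordant means both mates are uniquely mapped on *different*
    chromosomes — the filter used for gene-conversion boundary mapping.
    Concordant requires the same chromosome, opposite strands and an insert
    within bounds; everything else with at least one usable mate is partial.
    """
    if aln1 is None and aln2 is None:
        return PairClass.UNMAPPED
    if aln1 is None or aln2 is None or not (aln1.unique and aln2.unique):
        return PairClass.PARTIAL
    if aln1.chromosome != aln2.chromosome:
        return PairClass.DISCORDANT
    if aln1.strand == aln2.strand:
        return PairClass.PARTIAL
    left, right = sorted((aln1, aln2), key=lambda a: a.start)
    insert = right.end - left.start
    if insert_bounds[0] <= insert <= insert_bounds[1] and left.strand == "+":
        return PairClass.CONCORDANT
    return PairClass.PARTIAL


@dataclass(frozen=True)
class MappedPair:
    read_id: str
    aln1: AlignmentRecord | None
    aln2: AlignmentRecord | None
    pair_class: PairClass


def map_pairs(pairs, index: ExactMatchIndex, insert_bounds: tuple = (50, 2000)):
    """Map an iterable of (read_id, seq1, seq2) mate pairs.

    Returns (mapped_pairs, counters).  ``counters['total_reads']`` counts
    every read seen before any filtering — the denominator for
    discordant-pair fractions.
    """
    out = []
    counters = {"total_reads": 0, "mapped": 0, "multimapped": 0,
                "unmapped": 0, "wrong_length": 0}
    for read_id, s1, s2 in pairs:
        alns = []
        for mate, seq in enumerate((s1, s2), start=1):
            counters["total_reads"] += 1
            if len(seq) != index.k:
                counters["wrong_length"] += 1
                alns.append(None)
                continue
            a = map_read(seq, index, read_id=read_id)
            if a is None:
                counters["unmapped"] += 1
            elif not a.unique:
                counters["multimapped"] += 1
            else:
                counters["mapped"] += 1
            alns.append(a)
        cls = pair_reads(alns[0], alns[1], insert_bounds)
        out.append(MappedPair(read_id, alns[0], alns[1], cls))
    return out, counters


def naive_scan(read: str, genome: GenomeMap) -> list:
    """Brute-force O(n*k) exact search over both strands (test oracle)."""
    hits = []
    rc = revcomp(read)
    for name, seq in genome.chromosomes.items():
        start = seq.find(read)
        while start != -1:
            hits.append((name, start, "+"))
            start = seq.find(read, start + 1)
        start = seq.find(rc)
        while start != -1:
            hits.append((name, start, "-"))
            start = seq.find(rc, start + 1)
    return hits
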