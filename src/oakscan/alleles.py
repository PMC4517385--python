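"""Tentative possible-allele discovery from read alignments.

Independently of any genotyper, each surviving alignment is broken into
maximal runs of four types — insert-to-reference, delete-from-reference,
1:1-and-different (mismatch), 1:1-and-identical — and the identical runs
dropped.  Each distinct quintuple (run type, contig, position, reference
sequence, read sequence; all on the + strand) is counted over the read
pool; quintuples seen at least five times, with unambiguous read
sequence, become tentative alleles.  These are converted to VCF loci
(indels grown one nucleotide upstream for non-empty alleles) and chains
of overlapping loci merged into single records.

Soft-clipped bases are not part of any run: they are not in 1:1
correspondence with the reference.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AlignmentRun",
    "Quintuple",
    "prefilter_alignments",
    "decompose_alignment",
    "count_and_threshold",
    "quintuples_to_vcf",
    "read_sam",
    "FLAG_MASK",
    "MIN_MAPQ",
    "MIN_COUNT",
]

FLAG_MASK = 0x704
MIN_MAPQ = 20
MIN_COUNT = 5

INSERT = "I"
DELETE = "D"
MISMATCH = "X"

_UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class AlignmentRun:
    """A maximal non-identical run of one alignment, on the + strand.

    ``pos`` is the 0-based reference start of the run; for inserts it is
    the between-base index (the run sits before reference base ``pos``).
    Insert runs have empty ``ref``; delete runs have empty ``read``.
    """

    run_type: str
    contig: str
    pos: int
    ref: str
    read: str

    def __post_init__(self) -> None:
        if self.run_type == INSERT and self.ref:
            raise ValueError("insert runs carry no reference sequence")
        if self.run_type == DELETE and self.read:
            raise ValueError("delete runs carry no read sequence")
        if self.run_type == MISMATCH and len(self.ref) != len(self.read):
            raise ValueError("mismatch runs must be 1:1")


@dataclass(frozen=True)
class Quintuple:
    run: AlignmentRun
    count: int


@dataclass
class Alignment:
    """Minimal alignment record (what the discovery filters inspect)."""

    qname: str
    flag: int
    contig: str
    pos: int  # 0-based leftmost reference position
    mapq: int
    cigar: list[tuple[str, int]]  # (op, length)
    seq: str


def read_sam(path: str) -> list[Alignment]:
    """Parse a SAM file via pysam into Alignment records."""
    import pysam

    out = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.cigartuples is None:
                continue
            cigar = [
                ("MIDNSHP=X"[op], length) for op, length in read.cigartuples
            ]
            out.append(
                Alignment(
                    qname=read.query_name,
                    flag=read.flag,
                    contig=read.reference_name,
                    pos=read.reference_start,
                    mapq=read.mapping_quality,
                    cigar=cigar,
                    seq=read.query_sequence or "",
                )
            )
    return out


def prefilter_alignments(alignments: Iterable[Alignment]) -> list[Alignment]:
    """Retain alignments with MAPQ >= 20 and FLAG & 0x704 == 0."""
    return [
        a for a in alignments if a.mapq >= MIN_MAPQ and (a.flag & FLAG_MASK) == 0
    ]


def decompose_alignment(aln: Alignment, ref_seq: str) -> list[AlignmentRun]:
    """Maximal non-identical runs of one alignment (identical runs dropped).

    Adjacent events of the same type coalesce into one run.  SAM stores
    reverse-strand reads already on the + strand, so no re-orientation is
    needed.  Raises ValueError when CIGAR and sequence lengths disagree.
    """
    consumed = sum(n for op, n in aln.cigar if op in "MIS=X")
    if consumed != len(aln.seq):
        raise ValueError(
            f"CIGAR consumes {consumed} read bases but sequence has {len(aln.seq)}"
        )
    events: list[list] = []  # mutable [type, pos, ref, read]

    def emit(run_type: str, pos: int, ref: str, read: str) -> None:
        if events:
            prev = events[-1]
            if prev[0] == run_type == MISMATCH and prev[1] + len(prev[2]) == pos:
                prev[2] += ref
                prev[3] += read
                return
            if prev[0] == run_type == DELETE and prev[1] + len(prev[2]) == pos:
                prev[2] += ref
                return
            if prev[0] == run_type == INSERT and prev[1] == pos:
                prev[3] += read
                return
        events.append([run_type, pos, ref, read])

    rpos = aln.pos
    qpos = 0
    for op, length in aln.cigar:
        if op in "M=X":
            for k in range(length):
                rb = ref_seq[rpos + k].upper()
                qb = aln.seq[qpos + k].upper()
                if rb != qb:
                    emit(MISMATCH, rpos + k, rb, qb)
            rpos += length
            qpos += length
        elif op == "I":
            emit(INSERT, rpos, "", aln.seq[qpos : qpos + length].upper())
            qpos += length
        elif op in "DN":
            emit(DELETE, rpos, ref_seq[rpos : rpos + length].upper(), "")
            rpos += length
        elif op == "S":
            qpos += length
        # H and P consume nothing we track
    return [
        AlignmentRun(t, aln.contig, p, ref, read) for t, p, ref, read in events
    ]


def count_and_threshold(
    runs: Iterable[AlignmentRun], min_count: int = MIN_COUNT
) -> list[Quintuple]:
    """Count identical runs pooled over all reads; retain those seen at
    least ``min_count`` times whose read sequence has no IUPAC ambiguity
    codes.  Counting is order-independent."""
    counter = Counter(runs)
    out = []
    for run, count in counter.items():
        if count < min_count:
            continue
        if any(b not in _UNAMBIGUOUS for b in run.read):
            continue
        out.append(Quintuple(run=run, count=count))
    out.sort(key=lambda q: (q.run.contig, q.run.pos, q.run.run_type, q.run.read))
    return out


def _tentative_locus(run: AlignmentRun, contig_seq: str) -> tuple[int, int, str]:
    """(start, end, alt) of one event, grown upstream for indels.

    Coordinates are 0-based half-open on the contig.
    """
    n = len(contig_seq)
    if run.run_type == MISMATCH:
        if not (0 <= run.pos and run.pos + len(run.ref) <= n):
            raise ValueError(f"run at {run.pos} outside contig of length {n}")
        return (run.pos, run.pos + len(run.ref), run.read)
    if run.run_type == INSERT:
        if not (1 <= run.pos <= n):
            raise ValueError(f"insert at {run.pos} lacks an upstream anchor base")
        anchor = contig_seq[run.pos - 1].upper()
        return (run.pos - 1, run.pos, anchor + run.read)
    # delete
    if not (1 <= run.pos and run.pos + len(run.ref) <= n):
        raise ValueError(f"deletion at {run.pos} lacks an upstream anchor base")
    anchor = contig_seq[run.pos - 1].upper()
    return (run.pos - 1, run.pos + len(run.ref), anchor)


def quintuples_to_vcf(
    quintuples: Sequence[Quintuple],
    contigs: Mapping[str, str],
) -> list[tuple[str, int, str, tuple[str, ...]]]:
    """Candidate VCF loci (contig, POS 1-based, REF, ALTs) from quintuples.

    Indel events are grown one nucleotide upstream so no allele is empty.
    Chains of loci whose reference spans overlap or abut are merged into
    a single record spanning the chain, every alternate rewritten against
    the grown span (its event spliced in, all other positions at
    reference).
    """
    by_contig: dict[str, list[tuple[int, int, str]]] = {}
    for q in quintuples:
        seq = contigs[q.run.contig]
        by_contig.setdefault(q.run.contig, []).append(_tentative_locus(q.run, seq))
    records = []
    for contig in sorted(by_contig):
        seq = contigs[contig].upper()
        loci = sorted(set(by_contig[contig]))
        chain: list[tuple[int, int, str]] = []
        chain_end = -1

        def flush() -> None:
            if not chain:
                return
            start = min(s for s, _, _ in chain)
            end = max(e for _, e, _ in chain)
            ref = seq[start:end]
            alts = []
            for s, e, alt in chain:
                rewritten = seq[start:s] + alt + seq[e:end]
                if rewritten != ref and rewritten not in alts:
                    alts.append(rewritten)
            if alts:
                records.append((contig, start + 1, ref, tuple(sorted(alts))))

        for locus in loci:
            if chain and locus[0] <= chain_end:
                chain.append(locus)
                chain_end = max(chain_end, locus[1])
            else:
                flush()
                chain = [locus]
                chain_end = locus[1]
        flush()
    records.sort(key=lambda r: (r[0], r[1]))
    return records
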