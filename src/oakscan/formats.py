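"""Plain-text writers for the formats the pipeline exchanges.

Reading goes through pysam / gffutils / Biopython elsewhere; writing is
deliberately simple text emission so outputs are deterministic at the
byte level for identical inputs.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .genes import GeneModel
from .variants import SiteRecord

__all__ = ["write_fasta", "write_gff", "write_vcf", "write_sam", "read_fasta"]


def write_fasta(path: str, contigs: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in contigs:
            fh.write(f">{name}\n")
            seq = contigs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def _gff_line(contig, source, ftype, start0, end0, strand, phase, attrs) -> str:
    attr = ";".join(f"{k}={v}" for k, v in attrs.items())
    return f"{contig}\t{source}\t{ftype}\t{start0 + 1}\t{end0}\t.\t{strand}\t{phase}\t{attr}\n"


def write_gff(path: str, models: Sequence[GeneModel], source: str = "oakscan") -> None:
    """Write gene models as GFF3 (1-based inclusive coordinates).

    mRNA features carry ``has_start``/``has_stop`` attributes recording
    model completeness; CDS phase follows the GFF convention.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.contig, m.cds[0][0])):
            spans = list(m.cds) + list(m.introns) + list(m.utr5) + list(m.utr3)
            start = min(s for s, _ in spans)
            end = max(e for _, e in spans)
            gid = m.gene_id
            fh.write(
                _gff_line(m.contig, source, "gene", start, end, m.strand, ".", {"ID": f"{gid}.g"})
            )
            fh.write(
                _gff_line(
                    m.contig, source, "mRNA", start, end, m.strand, ".",
                    {
                        "ID": gid,
                        "Parent": f"{gid}.g",
                        "has_start": int(m.has_start),
                        "has_stop": int(m.has_stop),
                    },
                )
            )
            for s, e in m.utr5:
                fh.write(
                    _gff_line(m.contig, source, "five_prime_UTR", s, e, m.strand, ".", {"Parent": gid})
                )
            # CDS phases accumulate along the transcript
            walked = 0
            phases = {}
            for s, e in m.cds_in_transcript_order():
                phases[(s, e)] = (3 - ((walked - m.phase) % 3)) % 3 if walked else m.phase
                walked += e - s
            for s, e in m.cds:
                fh.write(
                    _gff_line(m.contig, source, "CDS", s, e, m.strand, phases[(s, e)], {"Parent": gid})
                )
            for s, e in m.introns:
                fh.write(
                    _gff_line(m.contig, source, "intron", s, e, m.strand, ".", {"Parent": gid})
                )
            for s, e in m.utr3:
                fh.write(
                    _gff_line(m.contig, source, "three_prime_UTR", s, e, m.strand, ".", {"Parent": gid})
                )


_INFO_ORDER = (
    "AC",
    "BaseQRankSum",
    "DP",
    "Dels",
    "FS",
    "HaplotypeScore",
    "MQ",
    "MQRankSum",
    "ReadPosRankSum",
    "SB",
)

_VCF_HEADER_META = """##fileformat=VCFv4.2
##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count in genotypes, for each ALT allele">
##INFO=<ID=BaseQRankSum,Number=1,Type=Float,Description="Z-score of base quality rank sum test">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Combined depth across samples">
##INFO=<ID=Dels,Number=1,Type=Float,Description="Fraction of reads containing spanning deletions">
##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand bias Fisher test p-value">
##INFO=<ID=HaplotypeScore,Number=1,Type=Float,Description="Consistency with at most two segregating haplotypes">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Z-score of mapping quality rank sum test">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Z-score of read position rank sum test">
##INFO=<ID=SB,Number=1,Type=Float,Description="Strand bias">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""


def _fmt_num(x: float) -> str:
    if float(x) == int(x):
        return str(int(x))
    return f"{x:.4f}".rstrip("0").rstrip(".")


def write_vcf(
    path: str,
    records: Sequence[SiteRecord],
    samples: Sequence[str],
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER_META)
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for rec in sorted(records, key=lambda r: (r.contig, r.pos)):
            info_parts = []
            for key in _INFO_ORDER:
                if key not in rec.info:
                    continue
                value = rec.info[key]
                if isinstance(value, (tuple, list)):
                    info_parts.append(f"{key}=" + ",".join(_fmt_num(v) for v in value))
                else:
                    info_parts.append(f"{key}={_fmt_num(value)}")
            gts = []
            for g in rec.genotypes:
                if g.alleles is None:
                    gt = "./."
                else:
                    gt = f"{g.alleles[0]}/{g.alleles[1]}"
                dp = "." if g.dp is None else str(g.dp)
                gq = "." if g.gq is None else str(g.gq)
                gts.append(f"{gt}:{dp}:{gq}")
            fh.write(
                "\t".join(
                    [
                        rec.contig,
                        str(rec.pos),
                        ".",
                        rec.ref,
                        ",".join(rec.alts),
                        _fmt_num(rec.qual),
                        "PASS",
                        ";".join(info_parts) or ".",
                        "GT:DP:GQ",
                    ]
                    + gts
                )
                + "\n"
            )


def write_sam(
    path: str,
    contig_lengths: Mapping[str, int],
    records: Sequence[tuple],
) -> None:
    """Write SAM records given as (qname, flag, contig, pos1, mapq, cigar, seq)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in contig_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for qname, flag, contig, pos1, mapq, cigar, seq in records:
            qual = "I" * len(seq) if seq != "*" else "*"
            fh.write(
                f"{qname}\t{flag}\t{contig}\t{pos1}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t{qual}\n"
            )
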