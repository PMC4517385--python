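"""Site- and genotype-level hard filters and diallelic SNP extraction.

The filters reproduce the hard-threshold regime used for RNA-seq variant
calls in a non-model transcriptome: a conjunction of inequalities on the
site-level INFO metrics, a per-genotype depth/quality rule, and a final
restriction to loci where exactly two single-nucleotide alleles (one of
them the reference) are represented among the surviving genotype calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Genotype",
    "SiteRecord",
    "SnpLocus",
    "SITE_FILTER_BOUNDS",
    "filter_sites",
    "filter_genotypes",
    "extract_diallelic_snps",
    "ts_tv_ratio",
    "read_vcf",
]

# genotype codes used throughout the package
HOM_REF = 0
HET = 1
HOM_VAR = 2
UNCALLED = -1

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@dataclass(frozen=True)
class Genotype:
    """One individual's diploid call at a site.

    ``alleles`` holds two allele indices into [REF] + ALT, or ``None``
    when the genotype is uncalled.  DP/GQ may be ``None`` when absent.
    """

    alleles: tuple[int, int] | None
    dp: int | None = None
    gq: int | None = None

    @property
    def called(self) -> bool:
        return self.alleles is not None


@dataclass
class SiteRecord:
    """A parsed VCF record restricted to the fields the filters inspect."""

    contig: str
    pos: int  # 1-based, as in VCF
    ref: str
    alts: tuple[str, ...]
    qual: float
    info: dict[str, float | tuple[float, ...]] = field(default_factory=dict)
    genotypes: list[Genotype] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or any(not a for a in self.alts):
            raise ValueError("allele strings must be non-empty")


@dataclass
class SnpLocus:
    """A filtered diallelic SNP: reference vs one variant nucleotide.

    ``gt`` is an int8 vector over individuals with codes 0 (hom-ref),
    1 (het), 2 (hom-var), -1 (uncalled), aligned with ``samples``.
    """

    contig: str
    pos: int
    ref: str
    var: str
    gt: np.ndarray
    samples: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.var) != 1:
            raise ValueError("SnpLocus alleles must be single nucleotides")
        if self.ref == self.var:
            raise ValueError("reference and variant allele are identical")
        for allele in (self.ref, self.var):
            if allele not in "ACGT":
                raise ValueError(f"non-ACGT allele {allele!r}")
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if len(self.gt) != len(self.samples):
            raise ValueError("genotype vector does not match sample list")
        called = self.gt[self.gt != UNCALLED]
        if called.size:
            present = set()
            if np.any((called == HOM_REF) | (called == HET)):
                present.add(self.ref)
            if np.any((called == HOM_VAR) | (called == HET)):
                present.add(self.var)
            if present != {self.ref, self.var}:
                raise ValueError(
                    "called genotypes must represent exactly the reference "
                    "and the variant allele"
                )

    @property
    def is_transition(self) -> bool:
        return frozenset((self.ref, self.var)) in _TRANSITIONS

    def allele_counts(self, indices: Sequence[int] | None = None) -> tuple[int, int]:
        """(ref, var) allele counts over called genotypes of ``indices``."""
        gt = self.gt if indices is None else self.gt[list(indices)]
        n_ref = int(2 * np.sum(gt == HOM_REF) + np.sum(gt == HET))
        n_var = int(2 * np.sum(gt == HOM_VAR) + np.sum(gt == HET))
        return n_ref, n_var


# Site-level bounds: INFO key -> (test, description). "AC" is handled
# separately because its bound depends on the sample size.
SITE_FILTER_BOUNDS = {
    "QUAL": lambda x: 17.0 <= x < 100000.0,
    "BaseQRankSum": lambda x: -3.5 < x < 7.0,
    "DP": lambda x: x >= 5,
    "Dels": lambda x: x < 0.1,
    "FS": lambda x: x < 90.0,
    "HaplotypeScore": lambda x: x < 25.0,
    "MQ": lambda x: x >= 20.0,
    "MQRankSum": lambda x: -25.0 < x < 10.0,
    "ReadPosRankSum": lambda x: -3.5 < x < 9.0,
    "SB": lambda x: x < 3.0,
}


def _scalar(value, key: str) -> float:
    if isinstance(value, (tuple, list)):
        if len(value) != 1:
            raise ValueError(f"INFO field {key} is not scalar: {value!r}")
        value = value[0]
    try:
        return float(value)
    except (TypeError, ValueError) as exc:  # pragma: no cover - defensive
        raise ValueError(f"malformed numeric INFO field {key}: {value!r}") from exc


def site_passes(record: SiteRecord, n_individuals: int) -> bool:
    """Does ``record`` satisfy every site-level inequality?

    Metrics absent from INFO are treated as passing: rank-sum annotations
    are undefined at sites without heterozygotes, and an absent value
    cannot violate an inequality.  Total AC must not be 0 or
    2*n_individuals (no variant allele present, or no reference allele).
    """
    if not SITE_FILTER_BOUNDS["QUAL"](float(record.qual)):
        return False
    ac = record.info.get("AC")
    if ac is not None:
        total = sum(ac) if isinstance(ac, (tuple, list)) else float(ac)
        if total == 0 or total == 2 * n_individuals:
            return False
    for key, test in SITE_FILTER_BOUNDS.items():
        if key == "QUAL":
            continue
        value = record.info.get(key)
        if value is None:
            continue
        if not test(_scalar(value, key)):
            return False
    return True


def filter_sites(records: Iterable[SiteRecord], n_individuals: int) -> list[SiteRecord]:
    """Return, in input order, the records meeting every site-level bound."""
    return [r for r in records if site_passes(r, n_individuals)]


def filter_genotypes(record: SiteRecord) -> SiteRecord:
    """Set genotypes failing DP <= 100 or GQ >= 20 to uncalled.

    Genotypes lacking DP or GQ values are kept (the condition they could
    fail is not evaluable); already-uncalled genotypes pass through.
    """
    new = []
    for g in record.genotypes:
        if not g.called:
            new.append(g)
            continue
        fail_dp = g.dp is not None and g.dp > 100
        fail_gq = g.gq is not None and g.gq < 20
        if fail_dp or fail_gq:
            new.append(Genotype(None, g.dp, g.gq))
        else:
            new.append(g)
    return replace(record, genotypes=new)


def extract_diallelic_snps(
    records: Iterable[SiteRecord], samples: Sequence[str]
) -> list[SnpLocus]:
    """Extract loci with exactly two represented alleles, one the reference.

    A multi-allelic record qualifies when, across *called* genotypes, only
    the reference and one single-nucleotide alternate are represented; the
    record's other alternates play no role.  Both alleles must be single
    nucleotides.  Records failing the rule are skipped.
    """
    samples = tuple(samples)
    out: list[SnpLocus] = []
    for rec in records:
        alleles = [rec.ref, *rec.alts]
        represented: set[int] = set()
        for g in rec.genotypes:
            if g.called:
                represented.update(g.alleles)
        if len(represented) != 2 or 0 not in represented:
            continue
        var_idx = (represented - {0}).pop()
        var = alleles[var_idx]
        if len(rec.ref) != 1 or len(var) != 1:
            continue
        if rec.ref not in "ACGT" or var not in "ACGT":
            continue
        gt = np.full(len(samples), UNCALLED, dtype=np.int8)
        for i, g in enumerate(rec.genotypes):
            if not g.called:
                continue
            n_var = sum(1 for a in g.alleles if a == var_idx)
            gt[i] = (HOM_REF, HET, HOM_VAR)[n_var]
        out.append(SnpLocus(rec.contig, rec.pos, rec.ref, var, gt, samples))
    return out


def ts_tv_ratio(snps: Sequence[SnpLocus]) -> float:
    """Transition:transversion ratio over SNP loci (A<->G, C<->T vs rest).

    Returns ``math.inf`` when there are no transversions.
    """
    if not snps:
        raise ValueError("ts_tv_ratio requires a non-empty SNP list")
    ts = sum(1 for s in snps if s.is_transition)
    tv = len(snps) - ts
    if tv == 0:
        return math.inf
    return ts / tv


def read_vcf(path: str) -> tuple[list[SiteRecord], tuple[str, ...]]:
    """Read a VCF into SiteRecords via pysam; returns (records, samples)."""
    import pysam

    records: list[SiteRecord] = []
    with pysam.VariantFile(path) as vf:
        samples = tuple(vf.header.samples)
        for rec in vf:
            info: dict[str, float | tuple[float, ...]] = {}
            for key, value in rec.info.items():
                if isinstance(value, tuple):
                    info[key] = tuple(float(v) for v in value)
                elif isinstance(value, (int, float)):
                    info[key] = float(value)
            genotypes = []
            for name in samples:
                call = rec.samples[name]
                alleles = call.get("GT")
                if alleles is None or any(a is None for a in alleles):
                    gt = None
                else:
                    gt = (int(alleles[0]), int(alleles[1]))
                dp = call.get("DP")
                gq = call.get("GQ")
                genotypes.append(
                    Genotype(
                        gt,
                        None if dp is None else int(dp),
                        None if gq is None else int(gq),
                    )
                )
            records.append(
                SiteRecord(
                    contig=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    qual=float(rec.qual) if rec.qual is not None else 0.0,
                    info=info,
                    genotypes=genotypes,
                )
            )
    return records, samples
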