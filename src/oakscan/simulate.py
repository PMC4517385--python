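"""Seeded synthetic transcriptomes, genotypes and alignments.

The generator emulates the statistical structure the divergence scan
assumes — 22 ingroup + 1 outgroup (+1 optional hybrid) diploids, ~1.2-1.5%
SNP density, transition:transversion imbalance, per-gene-class dN/dS
(omega) and derived-allele spectra — so every downstream stage can be
tested end to end without external data.  It is a stand-in chosen to
exercise the statistics, not a model of oak biology: sites are
unlinked, there is no coalescent tree and no read-level error model.

Mutation model: candidate sites are proposed independently per base
(probability ``theta_site`` for ingroup polymorphisms and
``outgroup_divergence`` for fixed interspecific differences); the
alternate base is a transition with probability kappa/(kappa+2).  In
coding sequence a nonsynonymous proposal is accepted with probability
min(1, omega) and a synonymous one with min(1, 1/omega), so realized
dN/dS tracks omega on both sides of 1; proposals creating or destroying
stop codons are rejected.  Ingroup derived-allele counts follow
xi_i proportional to 1/i (neutral) or a mixture placing extra mass on
counts >= n-4 (sweep).  Every emitted variant has a truth entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._codons import AA_BY_INDEX, codon_index, complement_base, revcomp
from .alleles import Alignment, AlignmentRun, DELETE, INSERT, MISMATCH
from .formats import write_fasta, write_gff, write_vcf
from .genes import GeneModel
from .variants import Genotype, SiteRecord

__all__ = [
    "ClassSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "TruthSite",
    "SyntheticDataset",
    "simulate_transcriptome",
    "simulate_genotypes",
    "simulate_alignments",
    "simulate_dataset",
    "write_dataset",
]

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)

# INFO metric draws for passing sites, and one failing value per metric
_FAIL_VALUES = {
    "QUAL": 5.0,
    "BaseQRankSum": 8.0,
    "DP": 2.0,
    "Dels": 0.5,
    "FS": 200.0,
    "HaplotypeScore": 40.0,
    "MQ": 10.0,
    "MQRankSum": 20.0,
    "ReadPosRankSum": 10.0,
    "SB": 5.0,
}


@dataclass(frozen=True)
class ClassSpec:
    """A gene class: Pfam-style label, target omega, and SFS shape."""

    label: str
    omega: float
    sfs_shape: str = "neutral"

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.sfs_shape not in ("neutral", "sweep"):
            raise ValueError("sfs_shape must be 'neutral' or 'sweep'")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 50
    cds_length_range: tuple[int, int] = (300, 1500)
    n_ingroup: int = 22
    include_outgroup: bool = True
    include_hybrid: bool = False
    kappa: float = 3.8  # ts:tv rate ratio; implied count ratio is kappa/2
    theta_site: float = 0.013
    outgroup_divergence: float = 0.05
    class_specs: tuple[ClassSpec, ...] = (ClassSpec("PF00000", 1.0, "neutral"),)
    contamination: float = 0.1  # fraction of sites given one failing INFO metric
    intron_prob: float = 0.2
    intron_length: int = 90
    utr_length_range: tuple[int, int] = (60, 300)
    missing_rate: float = 0.02
    geno_fail_rate: float = 0.03  # genotypes given failing DP or GQ
    hybrid_het_fraction: float = 0.8
    sweep_mass: float = 0.5
    minus_strand_prob: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.cds_length_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid CDS length range {self.cds_length_range}")
        if lo < 9:
            raise ValueError("CDS length must allow start + interior + stop codons")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        for name in ("theta_site", "outgroup_divergence"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")
        if not self.class_specs:
            raise ValueError("need at least one class spec")
        self.class_specs = tuple(
            c if isinstance(c, ClassSpec) else ClassSpec(*c) for c in self.class_specs
        )

    @property
    def samples(self) -> tuple[str, ...]:
        names = [f"lob{i + 1:02d}" for i in range(self.n_ingroup)]
        if self.include_outgroup:
            names.append("gar01")
        if self.include_hybrid:
            names.append("hyb01")
        return tuple(names)


@dataclass(frozen=True)
class TruthSite:
    contig: str
    pos: int  # 1-based, matches the VCF
    ancestral: str
    derived: str
    derived_count: int  # derived alleles among called emitted ingroup genotypes
    kind: str  # 'poly' or 'fixed'
    effect: str  # 'synonymous' / 'nonsynonymous' / 'noncoding'
    planted_fail: str | None = None  # INFO metric set to a failing value


@dataclass
class SyntheticTruth:
    omega: dict[str, float]
    gene_class: dict[str, str]
    sfs_shape: dict[str, str]
    sites: list[TruthSite] = field(default_factory=list)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    contigs: dict[str, str]
    models: list[GeneModel]
    records: list[SiteRecord]
    samples: tuple[str, ...]
    truth: SyntheticTruth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def simulate_transcriptome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Contig sequences and gene models, one complete model per contig.

    Coding sequence is drawn codon-wise uniformly over non-stop codons
    (no internal stops by construction), flanked by UTRs; a fraction of
    genes receives one GT..AG intron at a codon boundary; about half the
    models sit on the minus strand.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.cds_length_range
    contigs: dict[str, str] = {}
    models: list[GeneModel] = []
    for i in range(config.n_genes):
        contig_id = f"ctg{i + 1:05d}"
        gene_id = f"g{i + 1:05d}"
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        n_codons = max(n_codons, 3)
        interior = rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
        cds = "ATG" + "".join(_SENSE_CODONS[j] for j in interior) + _STOPS[
            int(rng.integers(0, 3))
        ]
        u5 = int(rng.integers(config.utr_length_range[0], config.utr_length_range[1] + 1))
        u3 = int(rng.integers(config.utr_length_range[0], config.utr_length_range[1] + 1))
        utr5 = _random_seq(rng, u5)
        utr3 = _random_seq(rng, u3)
        has_intron = rng.random() < config.intron_prob and n_codons >= 4
        if has_intron:
            cut_codon = int(rng.integers(1, n_codons - 1))
            cut = 3 * cut_codon
            intron = "GT" + _random_seq(rng, config.intron_length - 4) + "AG"
            sense = utr5 + cds[:cut] + intron + cds[cut:] + utr3
            cds_iv = [(u5, u5 + cut), (u5 + cut + len(intron), u5 + len(cds) + len(intron))]
            intron_iv = [(u5 + cut, u5 + cut + len(intron))]
        else:
            sense = utr5 + cds + utr3
            cds_iv = [(u5, u5 + len(cds))]
            intron_iv = []
        total = len(sense)
        utr5_iv = [(0, u5)]
        utr3_iv = [(total - u3, total)]
        strand = "-" if rng.random() < config.minus_strand_prob else "+"
        if strand == "-":
            flip = lambda iv: (total - iv[1], total - iv[0])
            contig_seq = revcomp(sense)
            cds_iv = sorted(flip(iv) for iv in cds_iv)
            intron_iv = sorted(flip(iv) for iv in intron_iv)
            utr5_iv = [flip(utr5_iv[0])]
            utr3_iv = [flip(utr3_iv[0])]
        else:
            contig_seq = sense
        contigs[contig_id] = contig_seq
        models.append(
            GeneModel(
                gene_id=gene_id,
                contig=contig_id,
                strand=strand,
                cds=tuple(cds_iv),
                introns=tuple(intron_iv),
                utr5=tuple(utr5_iv),
                utr3=tuple(utr3_iv),
                has_start=True,
                has_stop=True,
                phase=0,
            )
        )
    return contigs, models


def _propose_alt(rng: np.random.Generator, ref: str, kappa: float) -> str:
    if rng.random() < kappa / (kappa + 2.0):
        return _TRANSITION[ref]
    others = [b for b in _BASES if b != ref and b != _TRANSITION[ref]]
    return others[int(rng.integers(0, 2))]


def _coding_change(
    model: GeneModel, cds_seq: str, pos: int, ref: str, alt: str
) -> str | None:
    """'synonymous' / 'nonsynonymous' / None (off-CDS) / 'stop' (rejected)."""
    t = model.cds_transcript_index(pos)
    if t is None:
        return None
    if model.strand == "-":
        alt_t = complement_base(alt)
    else:
        alt_t = alt
    codon_i = t // 3
    codon = cds_seq[3 * codon_i : 3 * codon_i + 3]
    within = t - 3 * codon_i
    alt_codon = codon[:within] + alt_t + codon[within + 1 :]
    ref_aa = AA_BY_INDEX[codon_index(codon)]
    alt_aa = AA_BY_INDEX[codon_index(alt_codon)]
    if ref_aa == "*" or alt_aa == "*":
        return "stop"
    return "synonymous" if ref_aa == alt_aa else "nonsynonymous"


def _draw_derived_count(
    rng: np.random.Generator, n_alleles: int, shape: str, sweep_mass: float
) -> int:
    if shape == "sweep" and rng.random() < sweep_mass:
        return int(rng.integers(n_alleles - 4, n_alleles))
    weights = 1.0 / np.arange(1, n_alleles)
    weights /= weights.sum()
    return int(rng.choice(np.arange(1, n_alleles), p=weights))


def simulate_genotypes(
    contigs: dict[str, str],
    models: Sequence[GeneModel],
    config: SimulationConfig,
) -> tuple[list[SiteRecord], SyntheticTruth]:
    """VCF-shaped site records plus the generating truth.

    Gene classes are assigned round-robin from ``config.class_specs``.
    Per-genotype DP/GQ and the site INFO metrics are drawn from
    pass-region distributions, with a ``contamination`` fraction of sites
    given one failing metric so the hard filters have work to do.
    """
    rng = np.random.default_rng([config.seed, 1])
    samples = config.samples
    n_in = config.n_ingroup
    n_alleles = 2 * n_in
    out_idx = n_in if config.include_outgroup else None
    hyb_idx = (n_in + (1 if config.include_outgroup else 0)) if config.include_hybrid else None

    truth = SyntheticTruth(omega={}, gene_class={}, sfs_shape={})
    records: list[SiteRecord] = []
    for gi, model in enumerate(models):
        spec = config.class_specs[gi % len(config.class_specs)]
        truth.omega[model.gene_id] = spec.omega
        truth.gene_class[model.gene_id] = spec.label
        truth.sfs_shape[model.gene_id] = spec.sfs_shape
        contig_seq = contigs[model.contig]
        cds_seq = model.cds_sequence(contig_seq)
        L = len(contig_seq)
        u_div = rng.random(L)
        u_poly = rng.random(L)
        div_sites = np.flatnonzero(u_div < config.outgroup_divergence)
        poly_sites = np.flatnonzero(
            (u_poly < config.theta_site) & (u_div >= config.outgroup_divergence)
        )
        events: list[tuple[int, str, str, str, str]] = []  # pos, alt, kind, effect
        for kind, positions in (("fixed", div_sites), ("poly", poly_sites)):
            for pos in positions:
                pos = int(pos)
                ref = contig_seq[pos]
                alt = _propose_alt(rng, ref, config.kappa)
                change = _coding_change(model, cds_seq, pos, ref, alt)
                if change == "stop":
                    continue
                if change is None:
                    effect = "noncoding"
                else:
                    effect = change
                    if effect == "nonsynonymous":
                        if rng.random() >= min(1.0, spec.omega):
                            continue
                    else:
                        if spec.omega > 1.0 and rng.random() >= 1.0 / spec.omega:
                            continue
                events.append((pos, ref, alt, kind, effect))
        events.sort()
        for pos, ref, alt, kind, effect in events:
            # allele index per sample slot: 0 = ref, 1 = alt
            gt_codes = np.zeros(len(samples), dtype=np.int8)  # alt-allele dose
            if kind == "fixed":
                if out_idx is not None:
                    gt_codes[out_idx] = 2
                if hyb_idx is not None and rng.random() < config.hybrid_het_fraction:
                    gt_codes[hyb_idx] = 1
                derived_for_truth = alt  # derived on the outgroup lineage
            else:
                k = _draw_derived_count(rng, n_alleles, spec.sfs_shape, config.sweep_mass)
                slots = rng.permutation(n_alleles)[:k]
                for s in slots:
                    gt_codes[s // 2] += 1
                derived_for_truth = alt
            genotypes: list[Genotype] = []
            dp_draw = rng.integers(10, 61, size=len(samples))
            gq_draw = rng.integers(60, 100, size=len(samples))
            u_missing = rng.random(len(samples))
            u_fail = rng.random(len(samples))
            fail_mode = rng.integers(0, 2, size=len(samples))
            for si in range(len(samples)):
                if u_missing[si] < config.missing_rate:
                    genotypes.append(Genotype(None, None, None))
                    continue
                dose = int(gt_codes[si])
                alleles = ((0, 0), (0, 1), (1, 1))[dose]
                dp = int(dp_draw[si])
                gq = int(gq_draw[si])
                if u_fail[si] < config.geno_fail_rate:
                    if fail_mode[si] == 0:
                        gq = int(rng.integers(0, 20))
                    else:
                        dp = int(rng.integers(101, 200))
                genotypes.append(Genotype(alleles, dp, gq))
            called_in = [
                g for g in genotypes[:n_in] if g.called
            ]
            derived_count = sum(g.alleles.count(1) for g in called_in)
            ac = sum(g.alleles.count(1) for g in genotypes if g.called)
            if ac == 0:
                continue  # the variant allele vanished; emit nothing
            info: dict[str, float | tuple[float, ...]] = {
                "AC": (float(ac),),
                "BaseQRankSum": round(float(rng.normal(0.0, 1.0)), 3),
                "DP": float(sum(g.dp for g in genotypes if g.dp is not None)),
                "Dels": 0.0,
                "FS": round(float(rng.uniform(0.0, 10.0)), 3),
                "HaplotypeScore": round(float(rng.uniform(0.0, 5.0)), 3),
                "MQ": round(float(rng.uniform(40.0, 60.0)), 3),
                "MQRankSum": round(float(rng.normal(0.0, 1.0)), 3),
                "ReadPosRankSum": round(float(rng.normal(0.0, 1.0)), 3),
                "SB": round(float(rng.uniform(-2.0, 1.0)), 3),
            }
            qual = round(float(rng.uniform(50.0, 1000.0)), 1)
            planted_fail = None
            if rng.random() < config.contamination:
                planted_fail = list(_FAIL_VALUES)[int(rng.integers(0, len(_FAIL_VALUES)))]
                if planted_fail == "QUAL":
                    qual = _FAIL_VALUES["QUAL"]
                else:
                    info[planted_fail] = _FAIL_VALUES[planted_fail]
            records.append(
                SiteRecord(
                    contig=model.contig,
                    pos=pos + 1,
                    ref=ref,
                    alts=(alt,),
                    qual=qual,
                    info=info,
                    genotypes=genotypes,
                )
            )
            truth.sites.append(
                TruthSite(
                    contig=model.contig,
                    pos=pos + 1,
                    ancestral=ref if kind == "poly" else ref,
                    derived=derived_for_truth,
                    derived_count=derived_count,
                    kind=kind,
                    effect=effect,
                    planted_fail=planted_fail,
                )
            )
    return records, truth


def simulate_alignments(
    contig_id: str,
    contig_seq: str,
    events: Sequence[AlignmentRun],
    depth: int,
    read_len: int = 60,
    include_decoys: bool = True,
    rng: np.random.Generator | None = None,
) -> list[Alignment]:
    """Reads supporting each variant event ``depth`` times.

    Each event (mismatch / insert / delete run) is embedded in reads with
    staggered starts so quintuple counting sees ``depth`` copies.  With
    ``include_decoys`` two extra copies carry a failing MAPQ (10) and a
    secondary-alignment FLAG (0x100) so the prefilter has something to
    remove.  Raises ValueError for depth < 1 or events off the contig.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = rng or np.random.default_rng(0)
    out: list[Alignment] = []
    counter = 0
    for ev in events:
        if not (0 <= ev.pos <= len(contig_seq)):
            raise ValueError(f"event at {ev.pos} outside contig {contig_id}")
        span = len(ev.ref)
        if ev.pos + span > len(contig_seq):
            raise ValueError(f"event at {ev.pos} overruns contig {contig_id}")
        copies = depth + (2 if include_decoys else 0)
        for j in range(copies):
            left = min(ev.pos, max(4, read_len // 2 - 2 + (j % 7)))
            start = ev.pos - left
            right_ref_start = ev.pos + span
            right = min(len(contig_seq) - right_ref_start, read_len - left - len(ev.read))
            right = max(right, 0)
            pieces = []
            cigar = []
            if left:
                pieces.append(contig_seq[start : ev.pos])
                cigar.append(("M", left))
            if ev.run_type == MISMATCH:
                pieces.append(ev.read)
                cigar.append(("M", len(ev.read)))
            elif ev.run_type == INSERT:
                pieces.append(ev.read)
                cigar.append(("I", len(ev.read)))
            elif ev.run_type == DELETE:
                cigar.append(("D", span))
            if right:
                pieces.append(contig_seq[right_ref_start : right_ref_start + right])
                cigar.append(("M", right))
            # merge adjacent M ops
            merged: list[tuple[str, int]] = []
            for op, n in cigar:
                if merged and merged[-1][0] == op:
                    merged[-1] = (op, merged[-1][1] + n)
                else:
                    merged.append((op, n))
            flag, mapq = 0, 60
            if include_decoys and j == depth:
                mapq = 10
            elif include_decoys and j == depth + 1:
                flag = 0x100
            counter += 1
            out.append(
                Alignment(
                    qname=f"read{counter:06d}",
                    flag=flag,
                    contig=contig_id,
                    pos=start,
                    mapq=mapq,
                    cigar=merged,
                    seq="".join(pieces),
                )
            )
    return out


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Transcriptome + genotypes + truth in one deterministic call."""
    contigs, models = simulate_transcriptome(config)
    records, truth = simulate_genotypes(contigs, models, config)
    return SyntheticDataset(
        config=config,
        contigs=contigs,
        models=models,
        records=records,
        samples=config.samples,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA / GFF3 / VCF / truth TSV / gene-class TSV to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "contigs.fa",
        "gff": outdir / "models.gff3",
        "vcf": outdir / "genotypes.vcf",
        "truth": outdir / "truth_sites.tsv",
        "pfam": outdir / "gene_classes.tsv",
    }
    write_fasta(paths["fasta"], dataset.contigs)
    write_gff(paths["gff"], dataset.models)
    lengths = {name: len(seq) for name, seq in dataset.contigs.items()}
    write_vcf(paths["vcf"], dataset.records, dataset.samples, lengths)
    with open(paths["truth"], "w") as fh:
        fh.write(
            "contig\tpos\tancestral\tderived\tderived_count\tkind\teffect\tplanted_fail\n"
        )
        for s in dataset.truth.sites:
            fh.write(
                f"{s.contig}\t{s.pos}\t{s.ancestral}\t{s.derived}\t{s.derived_count}"
                f"\t{s.kind}\t{s.effect}\t{s.planted_fail or '.'}\n"
            )
    with open(paths["pfam"], "w") as fh:
        fh.write("gene\taccession\n")
        for gene, acc in dataset.truth.gene_class.items():
            fh.write(f"{gene}\t{acc}\n")
    return paths
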