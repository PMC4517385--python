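"""Gene models and the mapping of SNP loci onto them.

A :class:`GeneModel` holds CDS/intron/UTR intervals on a contig.  SNP loci
are classified into region classes (start codon, stop codon, interior
codon, intron, 5'-UTR, 3'-UTR, other) and, within codons, annotated with
the coding effect of the variant allele under the standard genetic code.

Coordinates: GFF and VCF are 1-based at the file boundary; everything in
memory is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._codons import AA_BY_INDEX, codon_index, complement_base, revcomp
from .variants import SnpLocus

__all__ = [
    "GeneModel",
    "read_gff",
    "classify_region",
    "coding_effect",
    "region_rate_table",
    "label_array",
    "REGION_LABELS",
]

REGION_LABELS = (
    "other",
    "interior codon",
    "start codon",
    "stop codon",
    "intron",
    "5'-UTR",
    "3'-UTR",
)

Interval = tuple[int, int]  # 0-based half-open


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    cds: tuple[Interval, ...]  # sorted ascending by contig coordinate
    introns: tuple[Interval, ...] = ()
    utr5: tuple[Interval, ...] = ()
    utr3: tuple[Interval, ...] = ()
    has_start: bool = True
    has_stop: bool = True
    phase: int = 0  # bases before the first complete codon, transcript order

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.cds = tuple(sorted(tuple(iv) for iv in self.cds))
        spans = sorted(
            list(self.cds) + list(self.introns) + list(self.utr5) + list(self.utr3)
        )
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping intervals in model {self.gene_id}")
        if self.has_start and self.has_stop and self.cds_length % 3 != 0:
            raise ValueError(
                f"complete model {self.gene_id} has CDS length "
                f"{self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def cds_in_transcript_order(self) -> list[Interval]:
        return list(self.cds) if self.strand == "+" else list(reversed(self.cds))

    def cds_transcript_index(self, pos: int) -> int | None:
        """Transcript-orientation CDS coordinate of contig position ``pos``.

        Returns None when ``pos`` is not in any CDS interval.
        """
        t = 0
        for s, e in self.cds_in_transcript_order():
            if s <= pos < e:
                return t + (pos - s if self.strand == "+" else e - 1 - pos)
            t += e - s
        return None

    def cds_sequence(self, contig_seq: str) -> str:
        """CDS nucleotides concatenated in transcript orientation."""
        parts = [contig_seq[s:e] for s, e in self.cds]
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)


def _in_any(pos: int, intervals: Iterable[Interval]) -> bool:
    return any(s <= pos < e for s, e in intervals)


def classify_region(locus_pos: int, model: GeneModel) -> str:
    """Region label of 0-based contig position ``locus_pos`` for ``model``.

    Start/stop-codon labels are only assigned when the model annotates the
    corresponding end as complete; in incomplete models those positions
    are interior codons.
    """
    t = model.cds_transcript_index(locus_pos)
    if t is not None:
        if model.has_start and t < 3:
            return "start codon"
        if model.has_stop and t >= model.cds_length - 3:
            return "stop codon"
        return "interior codon"
    if _in_any(locus_pos, model.introns):
        return "intron"
    if _in_any(locus_pos, model.utr5):
        return "5'-UTR"
    if _in_any(locus_pos, model.utr3):
        return "3'-UTR"
    return "other"


def coding_effect(
    locus: SnpLocus,
    model: GeneModel,
    contig_seq: str,
    snp_positions: Iterable[int] | None = None,
) -> str:
    """Effect of the variant allele on the codon containing the locus.

    Returns one of ``synonymous``, ``nonsynonymous``, ``stop-gain``,
    ``stop-loss`` or ``excluded``.  A codon containing two or more
    filtered SNP loci is excluded, as are partial codons of incomplete
    models.  ``snp_positions`` is the set of 0-based positions of all
    filtered diallelic SNPs on the contig (defaults to just this locus).

    Raises ValueError when the locus reference allele disagrees with the
    contig sequence.
    """
    pos = locus.pos - 1
    if contig_seq[pos].upper() != locus.ref:
        raise ValueError(
            f"reference allele {locus.ref} at {locus.contig}:{locus.pos} "
            f"disagrees with contig base {contig_seq[pos]!r}"
        )
    t = model.cds_transcript_index(pos)
    if t is None:
        return "excluded"
    offset = model.phase
    if t < offset:
        return "excluded"
    codon_i = (t - offset) // 3
    codon_start = offset + 3 * codon_i
    if codon_start + 3 > model.cds_length:
        return "excluded"
    others = set(snp_positions) if snp_positions is not None else {pos}
    others.discard(pos)
    for other in others:
        ot = model.cds_transcript_index(other)
        if ot is not None and codon_start <= ot < codon_start + 3:
            return "excluded"
    cds = model.cds_sequence(contig_seq).upper()
    ref_codon = cds[codon_start : codon_start + 3]
    if any(b not in "ACGT" for b in ref_codon):
        return "excluded"
    within = t - codon_start
    alt_base = locus.var if model.strand == "+" else complement_base(locus.var)
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = AA_BY_INDEX[codon_index(ref_codon)]
    alt_aa = AA_BY_INDEX[codon_index(alt_codon)]
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "stop-gain"
    if ref_aa == "*":
        return "stop-loss"
    return "nonsynonymous"


def label_array(contig_len: int, models: Sequence[GeneModel]) -> np.ndarray:
    """Per-base region label codes (indices into REGION_LABELS) for a contig.

    Every base receives exactly one label; with multiple models on one
    contig (rare), later models overwrite earlier ones.
    """
    labels = np.zeros(contig_len, dtype=np.int8)
    for m in models:
        for s, e in m.utr5:
            labels[s:e] = REGION_LABELS.index("5'-UTR")
        for s, e in m.utr3:
            labels[s:e] = REGION_LABELS.index("3'-UTR")
        for s, e in m.introns:
            labels[s:e] = REGION_LABELS.index("intron")
        for s, e in m.cds:
            labels[s:e] = REGION_LABELS.index("interior codon")
        # start/stop codons override interior positions
        positions: list[int] = []
        for s, e in m.cds_in_transcript_order():
            rng = range(s, e) if m.strand == "+" else range(e - 1, s - 1, -1)
            positions.extend(rng)
        if m.has_start:
            for p in positions[:3]:
                labels[p] = REGION_LABELS.index("start codon")
        if m.has_stop:
            for p in positions[-3:]:
                labels[p] = REGION_LABELS.index("stop codon")
    return labels


def region_rate_table(
    snps: Sequence[SnpLocus],
    models_by_contig: Mapping[str, Sequence[GeneModel]],
    contig_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Per-region SNP rates (loci per bp) across all contigs.

    Region classes with zero bp get a NaN rate (undefined, not zero).
    """
    bp = {label: 0 for label in REGION_LABELS}
    counts = {label: 0 for label in REGION_LABELS}
    arrays = {}
    for contig, length in contig_lengths.items():
        arr = label_array(length, models_by_contig.get(contig, ()))
        arrays[contig] = arr
        codes, n = np.unique(arr, return_counts=True)
        for c, k in zip(codes, n):
            bp[REGION_LABELS[c]] += int(k)
    for locus in snps:
        arr = arrays.get(locus.contig)
        if arr is None:
            counts["other"] += 1
            continue
        counts[REGION_LABELS[arr[locus.pos - 1]]] += 1
    rows = []
    for label in REGION_LABELS:
        rate = counts[label] / bp[label] if bp[label] > 0 else float("nan")
        rows.append({"region": label, "n_loci": counts[label], "bp": bp[label], "rate": rate})
    return pd.DataFrame(rows)


def read_gff(path: str) -> dict[str, list[GeneModel]]:
    """Read gene models from GFF3 into per-contig lists.

    Expects mRNA features with CDS / intron / five_prime_UTR /
    three_prime_UTR children (the layout this package writes).  Model
    completeness is taken from ``has_start`` / ``has_stop`` attributes on
    the mRNA when present, else assumed complete.
    """
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out: dict[str, list[GeneModel]] = {}
    for mrna in db.features_of_type("mRNA"):
        cds, introns, utr5, utr3 = [], [], [], []
        phase = None
        children = sorted(db.children(mrna.id), key=lambda f: f.start)
        for child in children:
            iv = (child.start - 1, child.end)
            if child.featuretype == "CDS":
                cds.append((iv, child.frame))
            elif child.featuretype == "intron":
                introns.append(iv)
            elif child.featuretype == "five_prime_UTR":
                utr5.append(iv)
            elif child.featuretype == "three_prime_UTR":
                utr3.append(iv)
        if not cds:
            continue
        strand = mrna.strand if mrna.strand in "+-" else "+"
        first = cds[0] if strand == "+" else cds[-1]
        try:
            phase = int(first[1])
        except (TypeError, ValueError):
            phase = 0

        def _attr_flag(name: str) -> bool:
            vals = mrna.attributes.get(name)
            return True if not vals else vals[0] not in ("0", "false", "False")

        model = GeneModel(
            gene_id=mrna.id,
            contig=mrna.seqid,
            strand=strand,
            cds=tuple(iv for iv, _ in cds),
            introns=tuple(introns),
            utr5=tuple(utr5),
            utr3=tuple(utr3),
            has_start=_attr_flag("has_start"),
            has_stop=_attr_flag("has_stop"),
            phase=phase,
        )
        out.setdefault(model.contig, []).append(model)
    return out
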