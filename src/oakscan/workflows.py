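"""In-memory stage helpers shared by the pipeline, examples and scripts."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .genes import GeneModel
from .molevol import build_haplotypes, compare_to_outgroup, summarize_gene
from .sfs import h_with_replicates, locus_derived_data
from .variants import (
    SiteRecord,
    SnpLocus,
    extract_diallelic_snps,
    filter_genotypes,
    filter_sites,
)

__all__ = ["filtered_snps", "group_by_contig", "gene_dnds", "contig_faywu"]


def filtered_snps(
    records: Sequence[SiteRecord], samples: Sequence[str]
) -> list[SnpLocus]:
    """Site filters, genotype filters, then diallelic SNP extraction."""
    surviving = filter_sites(records, n_individuals=len(samples))
    surviving = [filter_genotypes(r) for r in surviving]
    return extract_diallelic_snps(surviving, samples)


def group_by_contig(snps: Sequence[SnpLocus]) -> dict[str, list[SnpLocus]]:
    out: dict[str, list[SnpLocus]] = {}
    for s in snps:
        out.setdefault(s.contig, []).append(s)
    return out


def gene_dnds(
    model: GeneModel,
    contig_seq: str,
    contig_snps: Sequence[SnpLocus],
    ingroup_idx: Sequence[int],
    outgroup_idx: int,
    min_substitutions: int = 6,
) -> tuple[float | None, int]:
    """(geometric-mean dN/dS, n qualifying comparisons) for one gene.

    Each ingroup individual's haplotype pair is compared to the
    outgroup's; only comparisons with >= ``min_substitutions`` observed
    differences enter the summary.  Returns (None, 0) when no comparison
    qualifies.
    """
    loci = [
        l for l in contig_snps if model.cds_transcript_index(l.pos - 1) is not None
    ]
    out_pair = build_haplotypes(model, loci, outgroup_idx, contig_seq)
    ratios = []
    for idx in ingroup_idx:
        pair = build_haplotypes(model, loci, idx, contig_seq)
        est = compare_to_outgroup(pair, out_pair, min_substitutions=min_substitutions)
        if est.qualifying:
            ratios.append(est.ratio)
    if not ratios:
        return None, 0
    return summarize_gene(ratios), len(ratios)


def contig_faywu(
    contig_snps: Sequence[SnpLocus],
    ingroup_idx: Sequence[int],
    outgroup_idx: int,
    rng: np.random.Generator,
    replicates: int = 10,
) -> float | None:
    """Median Fay & Wu's H for one contig's filtered diallelic SNPs."""
    n_total = 2 * len(ingroup_idx)
    data = [locus_derived_data(l, outgroup_idx, ingroup_idx) for l in contig_snps]
    if not data:
        return None
    return h_with_replicates(
        data, replicates=replicates, rng=rng, n_total=n_total, n_target=n_total - 4
    )
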