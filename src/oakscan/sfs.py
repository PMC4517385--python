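"""Fay & Wu's H from derived-allele frequencies, with outgroup polarization.

For a sample of n alleles and unfolded spectrum xi_i (number of
segregating sites with derived-allele count i):

    theta_pi = sum_i 2 i (n-i) xi_i / (n (n-1))
    theta_H  = sum_i 2 i^2     xi_i / (n (n-1))
    H = theta_pi - theta_H

H is negative when high-frequency derived alleles are in excess, the
hitchhiking signature of a selective sweep.  The ancestral allele is the
outgroup's homozygous call, or, when that is missing (or heterozygous),
the most common allele in the ingroup — a fallback that biases H toward
positive values and hence is conservative for inferring sweeps.  Missing
data are handled by resampling a fixed number of alleles (40 of up to 44)
without replacement at every locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .variants import HET, HOM_REF, HOM_VAR, UNCALLED, SnpLocus

__all__ = [
    "DerivedSFS",
    "ancestral_allele",
    "locus_derived_data",
    "resampled_sfs",
    "fay_wu_h",
    "h_with_replicates",
    "synonymous_diversity",
]


@dataclass
class DerivedSFS:
    """Unfolded site-frequency spectrum: counts xi[i] for i = 1..n-1."""

    n: int
    xi: np.ndarray  # length n+1; indices 0 and n unused (kept zero)

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=np.int64)
        if len(self.xi) != self.n + 1:
            raise ValueError("xi must have length n+1")
        if self.xi[0] != 0 or self.xi[self.n] != 0:
            raise ValueError("fixed sites (count 0 or n) do not belong in the SFS")
        if np.any(self.xi < 0):
            raise ValueError("negative SFS counts")

    def theta_pi(self) -> float:
        i = np.arange(1, self.n)
        return float(np.sum(2.0 * i * (self.n - i) * self.xi[1 : self.n]) / (self.n * (self.n - 1)))

    def theta_h(self) -> float:
        i = np.arange(1, self.n)
        return float(np.sum(2.0 * i * i * self.xi[1 : self.n]) / (self.n * (self.n - 1)))


def fay_wu_h(sfs: DerivedSFS) -> float:
    """H = theta_pi - theta_H; 0 for an empty spectrum."""
    if sfs.n < 2:
        raise ValueError("need at least 2 sampled alleles")
    return sfs.theta_pi() - sfs.theta_h()


def ancestral_allele(
    locus: SnpLocus,
    outgroup_index: int,
    ingroup_indices: Sequence[int],
) -> str:
    """Ancestral allele of a diallelic locus.

    The outgroup's homozygous call wins; when the outgroup is uncalled or
    heterozygous (which determines no single ancestral allele), the most
    common allele among the ingroup individuals is used, ties broken
    toward the reference allele.
    """
    out_code = int(locus.gt[outgroup_index])
    if out_code == HOM_REF:
        return locus.ref
    if out_code == HOM_VAR:
        return locus.var
    n_ref, n_var = locus.allele_counts(ingroup_indices)
    return locus.var if n_var > n_ref else locus.ref


def locus_derived_data(
    locus: SnpLocus,
    outgroup_index: int,
    ingroup_indices: Sequence[int],
) -> tuple[int, int]:
    """(derived count, called allele count) over the ingroup at a locus."""
    anc = ancestral_allele(locus, outgroup_index, ingroup_indices)
    n_ref, n_var = locus.allele_counts(ingroup_indices)
    derived = n_var if anc == locus.ref else n_ref
    return derived, n_ref + n_var


def resampled_sfs(
    loci: Iterable[tuple[int, int]],
    n_total: int = 44,
    n_target: int = 40,
    max_missing: int = 4,
    rng: np.random.Generator | None = None,
) -> DerivedSFS:
    """Build a derived SFS by resampling ``n_target`` alleles per locus.

    ``loci`` yields (derived count, called allele count) pairs as from
    :func:`locus_derived_data`.  Loci with more than ``max_missing`` of
    ``n_total`` alleles missing are excluded; at each surviving locus
    ``n_target`` alleles are drawn without replacement from the called
    pool, and loci monomorphic after resampling are dropped.
    """
    rng = rng or np.random.default_rng()
    xi = np.zeros(n_target + 1, dtype=np.int64)
    for derived, called in loci:
        if n_total - called > max_missing:
            continue
        if called < n_target:
            continue
        k = int(rng.hypergeometric(derived, called - derived, n_target)) if called > n_target else derived
        if 0 < k < n_target:
            xi[k] += 1
    return DerivedSFS(n=n_target, xi=xi)


def h_with_replicates(
    loci: Sequence[tuple[int, int]],
    replicates: int = 10,
    rng: np.random.Generator | None = None,
    n_total: int = 44,
    n_target: int = 40,
    max_missing: int = 4,
) -> float | None:
    """Median Fay & Wu's H over resampling replicates for one contig.

    Returns None when no locus is usable (all excluded or fixed).
    """
    rng = rng or np.random.default_rng()
    values = []
    for _ in range(replicates):
        sfs = resampled_sfs(
            loci, n_total=n_total, n_target=n_target, max_missing=max_missing, rng=rng
        )
        if sfs.xi.sum() == 0:
            continue
        values.append(fay_wu_h(sfs))
    if not values:
        return None
    return float(np.median(values))


def synonymous_diversity(
    derived_counts: Sequence[int],
    n: int,
    synonymous_sites: float,
) -> float:
    """Per-site nucleotide diversity at synonymous positions (pi_S).

    theta_pi over synonymous-labelled loci divided by the effective
    synonymous site count of the region.
    """
    if synonymous_sites <= 0:
        raise ValueError("synonymous site count must be positive")
    total = sum(2.0 * k * (n - k) / (n * (n - 1)) for k in derived_counts)
    return total / synonymous_sites
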