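"""Pairwise dN/dS by the Pamilo-Bianchi-Li (PBL) method.

The estimator tracks three codon degeneracy classes (0-, 2- and 4-fold)
and corrects each class's transition and transversion difference
proportions with the Kimura two-parameter model:

    A_i = 1/2 ln(1/(1-2P_i-Q_i)) - 1/4 ln(1/(1-2Q_i))   (transitions)
    B_i = 1/2 ln(1/(1-2Q_i))                              (transversions)

    dS = (L2 A2 + L4 A4)/(L2 + L4) + B4
    dN = A0 + (L0 B0 + L2 B2)/(L0 + L2)

Comparisons are made between per-individual pseudo-haplotype pairs: for a
diploid individual the two coding sequences carry the called genotype at
every filtered diallelic SNP (phase-free), with uncalled genotypes
replaced by ambiguity.  Against the outgroup the pairs are concatenated
h1 h1 h2 h2 vs g1 g2 g1 g2 so every coding position enters once per
haplotype pairing.  Sentinel ratios: dN = 0 -> ratio 0; dS = 0 (dN > 0)
-> ratio 10.  Only comparisons with at least six observed substitutions
of either kind qualify for gene summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from ._codons import AMBIG, DEGENERACY, STOP_INDEX, complement_base, encode
from .genes import GeneModel
from .variants import HET, HOM_REF, HOM_VAR, UNCALLED, SnpLocus

__all__ = [
    "build_haplotypes",
    "codon_degeneracy",
    "count_substitutions",
    "k2p_components",
    "pbl_rates",
    "compare_to_outgroup",
    "summarize_gene",
    "calibrate_tails",
    "synonymous_site_count",
    "SubstitutionCounts",
    "RateEstimate",
    "TailCalibration",
    "CalibrationError",
    "SENTINEL_HIGH",
    "ZERO_FLOOR",
]

SENTINEL_HIGH = 10.0
ZERO_FLOOR = 2.0 ** -10
CLASSES = (0, 2, 4)


def codon_degeneracy(codon: str, position: int) -> int:
    """Degeneracy class (0, 2 or 4) of ``position`` (1-based) in ``codon``.

    4-fold: every single-base change at the position is synonymous;
    0-fold: none is; otherwise 2-fold.  Stop codons are rejected (they
    are excluded upstream of any rate computation).
    """
    if position not in (1, 2, 3):
        raise ValueError("position must be 1, 2 or 3")
    arr = encode(codon)
    if len(arr) != 3 or np.any(arr >= AMBIG):
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    idx = 16 * int(arr[0]) + 4 * int(arr[1]) + int(arr[2])
    if STOP_INDEX[idx]:
        raise ValueError(f"stop codon {codon!r} has no degeneracy class here")
    return int(DEGENERACY[idx, position - 1])


@dataclass
class SubstitutionCounts:
    """Per-degeneracy-class site and difference tallies for one pair."""

    L: dict[int, float]
    ts: dict[int, float]
    tv: dict[int, float]
    n_diff: int
    n_codons: int

    def P(self, cls: int) -> float:
        return self.ts[cls] / self.L[cls] if self.L[cls] > 0 else 0.0

    def Q(self, cls: int) -> float:
        return self.tv[cls] / self.L[cls] if self.L[cls] > 0 else 0.0


def count_substitutions(seq_a, seq_b) -> SubstitutionCounts:
    """Tally sites and differences by degeneracy class for two sequences.

    Sequences may be strings or int8 arrays (A,C,G,T -> 0..3, 4 ambiguous)
    of equal codon-multiple length.  Codon columns containing ambiguity in
    either sequence, or where either codon is a stop, are excluded
    entirely.  Site counts are averaged over the two sequences; a
    difference whose degeneracy class differs between the sequences
    contributes half to each class.
    """
    a = encode(seq_a) if isinstance(seq_a, str) else np.asarray(seq_a, dtype=np.int8)
    b = encode(seq_b) if isinstance(seq_b, str) else np.asarray(seq_b, dtype=np.int8)
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if len(a) % 3 != 0:
        raise ValueError("sequence length is not a multiple of 3")
    n = len(a) // 3
    a3 = a.reshape(n, 3)
    b3 = b.reshape(n, 3)
    clean = ((a3 < AMBIG) & (b3 < AMBIG)).all(axis=1)
    idx_a = np.zeros(n, dtype=np.int32)
    idx_b = np.zeros(n, dtype=np.int32)
    if clean.any():
        ia = a3[clean].astype(np.int32)
        ib = b3[clean].astype(np.int32)
        idx_a[clean] = 16 * ia[:, 0] + 4 * ia[:, 1] + ia[:, 2]
        idx_b[clean] = 16 * ib[:, 0] + 4 * ib[:, 1] + ib[:, 2]
    valid = clean & ~STOP_INDEX[idx_a] & ~STOP_INDEX[idx_b]

    deg_a = DEGENERACY[idx_a]  # (n, 3)
    deg_b = DEGENERACY[idx_b]
    vpos = np.repeat(valid, 3).reshape(n, 3)

    L = {c: 0.0 for c in CLASSES}
    ts = {c: 0.0 for c in CLASSES}
    tv = {c: 0.0 for c in CLASSES}
    for c in CLASSES:
        L[c] = 0.5 * float(((deg_a == c) & vpos).sum()) + 0.5 * float(
            ((deg_b == c) & vpos).sum()
        )
    diff = (a3 != b3) & vpos
    n_diff = int(diff.sum())
    if n_diff:
        pa = a3[diff].astype(np.int16)
        pb = b3[diff].astype(np.int16)
        is_ts = np.isin(pa + pb, (2, 4))  # A+G=2, C+T=4
        ca = deg_a[diff]
        cb = deg_b[diff]
        for c in CLASSES:
            ts[c] = 0.5 * float(((ca == c) & is_ts).sum()) + 0.5 * float(
                ((cb == c) & is_ts).sum()
            )
            tv[c] = 0.5 * float(((ca == c) & ~is_ts).sum()) + 0.5 * float(
                ((cb == c) & ~is_ts).sum()
            )
    return SubstitutionCounts(L=L, ts=ts, tv=tv, n_diff=n_diff, n_codons=int(valid.sum()))


def k2p_components(P: float, Q: float) -> tuple[float, float]:
    """Kimura two-parameter distance components (A, B) from (P, Q).

    Returns (nan, nan) when the proportions are outside the model's
    domain (1-2P-Q <= 0 or 1-2Q <= 0), where the distance is undefined.
    """
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return (math.nan, math.nan)
    A = 0.5 * math.log(1.0 / w1) - 0.25 * math.log(1.0 / w2)
    B = 0.5 * math.log(1.0 / w2)
    return (A, B)


@dataclass
class RateEstimate:
    """PBL dN, dS and their ratio for one pairwise comparison."""

    dn: float
    ds: float
    ratio: float
    n_diff: int
    qualifying: bool
    valid: bool
    A: dict[int, float] = field(default_factory=dict)
    B: dict[int, float] = field(default_factory=dict)
    var_dn: float = math.nan
    var_ds: float = math.nan


def _delta_variances(counts: SubstitutionCounts, A, B) -> tuple[float, float]:
    # Delta-method variances treating each class's (P, Q) as multinomial
    # proportions over L_i sites; reported for reference, unused downstream.
    L = counts.L
    var_ds = 0.0
    var_dn = 0.0
    ws = L[2] + L[4]
    wn = L[0] + L[2]
    for c in CLASSES:
        if L[c] <= 0:
            continue
        P, Q = counts.P(c), counts.Q(c)
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        if w1 <= 0 or w2 <= 0:
            return (math.nan, math.nan)
        a = 1.0 / w1
        b = 1.0 / w2
        cc = 0.5 * (a - b)
        cov = np.array(
            [[P * (1 - P), -P * Q], [-P * Q, Q * (1 - Q)]]
        ) / L[c]
        # gradients of dS and dN wrt (P_c, Q_c)
        gs = np.zeros(2)
        gn = np.zeros(2)
        if c in (2, 4) and ws > 0:
            gs += (L[c] / ws) * np.array([a, cc])
        if c == 4:
            gs += np.array([0.0, b])
        if c == 0:
            gn += np.array([a, cc])
        if c in (0, 2) and wn > 0:
            gn += (L[c] / wn) * np.array([0.0, b])
        var_ds += float(gs @ cov @ gs)
        var_dn += float(gn @ cov @ gn)
    return (var_dn, var_ds)


def pbl_rates(counts: SubstitutionCounts, min_substitutions: int = 6) -> RateEstimate:
    """PBL dN/dS from class tallies, with sentinel and qualifying rules.

    The estimate is invalid (NaN rates, non-qualifying) when a needed
    site class is empty or a K2P proportion falls outside its domain.
    Sentinels: dN = 0 -> ratio 0; dS = 0 with dN > 0 -> ratio 10.  The
    comparison qualifies when valid and at least ``min_substitutions``
    differences of either kind were observed.
    """
    L = counts.L
    invalid = RateEstimate(
        dn=math.nan, ds=math.nan, ratio=math.nan,
        n_diff=counts.n_diff, qualifying=False, valid=False,
    )
    if L[0] <= 0 or L[4] <= 0:
        return invalid
    A: dict[int, float] = {}
    B: dict[int, float] = {}
    for c in CLASSES:
        if L[c] > 0:
            A[c], B[c] = k2p_components(counts.P(c), counts.Q(c))
            if math.isnan(A[c]):
                return invalid
        else:
            A[c], B[c] = 0.0, 0.0
    ds = (L[2] * A[2] + L[4] * A[4]) / (L[2] + L[4]) + B[4]
    dn = A[0] + (L[0] * B[0] + L[2] * B[2]) / (L[0] + L[2])
    if dn == 0.0:
        ratio = 0.0
    elif ds == 0.0:
        ratio = SENTINEL_HIGH
    else:
        ratio = dn / ds
    var_dn, var_ds = _delta_variances(counts, A, B)
    return RateEstimate(
        dn=dn, ds=ds, ratio=ratio, n_diff=counts.n_diff,
        qualifying=counts.n_diff >= min_substitutions, valid=True,
        A=A, B=B, var_dn=var_dn, var_ds=var_ds,
    )


def build_haplotypes(
    model: GeneModel,
    snps: Iterable[SnpLocus],
    sample_index: int,
    contig_seq: str,
) -> tuple[np.ndarray, np.ndarray]:
    """The two coding pseudo-haplotypes of one individual for one gene.

    Both sequences equal the contig CDS (transcript orientation) except
    at filtered diallelic SNPs, where they jointly represent the called
    genotype: heterozygotes place one allele in each sequence (phase is
    arbitrary and immaterial to PBL), uncalled genotypes become ambiguous
    in both.  Ends are padded with ambiguity to the codon boundary, which
    also covers the partial first codon of 5'-incomplete models.
    """
    base = encode(model.cds_sequence(contig_seq))
    seq_a = base.copy()
    seq_b = base.copy()
    for locus in snps:
        pos = locus.pos - 1
        t = model.cds_transcript_index(pos)
        if t is None:
            continue
        if contig_seq[pos].upper() != locus.ref:
            raise ValueError(
                f"SNP reference allele {locus.ref} at {locus.contig}:{locus.pos} "
                "is inconsistent with the contig sequence"
            )
        if model.strand == "+":
            ref_t, var_t = locus.ref, locus.var
        else:
            ref_t, var_t = complement_base(locus.ref), complement_base(locus.var)
        ref_code = encode(ref_t)[0]
        var_code = encode(var_t)[0]
        code = int(locus.gt[sample_index])
        if code == UNCALLED:
            seq_a[t] = AMBIG
            seq_b[t] = AMBIG
        elif code == HOM_REF:
            seq_a[t] = ref_code
            seq_b[t] = ref_code
        elif code == HET:
            seq_a[t] = ref_code
            seq_b[t] = var_code
        elif code == HOM_VAR:
            seq_a[t] = var_code
            seq_b[t] = var_code
    head = (3 - model.phase) % 3 if model.phase else 0
    tail = (3 - (head + len(seq_a)) % 3) % 3
    if head or tail:
        seq_a = np.concatenate(
            [np.full(head, AMBIG, np.int8), seq_a, np.full(tail, AMBIG, np.int8)]
        )
        seq_b = np.concatenate(
            [np.full(head, AMBIG, np.int8), seq_b, np.full(tail, AMBIG, np.int8)]
        )
    return seq_a, seq_b


def compare_to_outgroup(
    pair_a: tuple[np.ndarray, np.ndarray],
    pair_b: tuple[np.ndarray, np.ndarray],
    min_substitutions: int = 6,
) -> RateEstimate:
    """PBL estimate between two individuals' haplotype pairs.

    Haplotypes are concatenated so each coding position contributes once
    per pairing: h1 h1 h2 h2 against g1 g2 g1 g2.
    """
    h1, h2 = pair_a
    g1, g2 = pair_b
    s1 = np.concatenate([h1, h1, h2, h2])
    s2 = np.concatenate([g1, g2, g1, g2])
    return pbl_rates(count_substitutions(s1, s2), min_substitutions=min_substitutions)


def summarize_gene(ratios: Sequence[float], zero_floor: float = ZERO_FLOOR) -> float:
    """Geometric mean of qualifying per-individual dN/dS ratios.

    Sentinel zeros are floored at ``zero_floor`` (2^-10) inside the log
    mean so the summary stays finite and rank-preserving; the high
    sentinel (10) enters as-is.
    """
    vals = [max(r, zero_floor) for r in ratios]
    if not vals:
        raise ValueError("no qualifying ratios to summarize")
    return float(2.0 ** np.mean(np.log2(vals)))


class CalibrationError(ValueError):
    """Raised when the truncated-normal tail calibration cannot be fit."""


@dataclass
class TailCalibration:
    """Truncated-normal fit to log2 dN/dS summaries on [-5, 1]."""

    mu: float
    sigma: float
    window: tuple[float, float]
    n_used: int

    def threshold(self, alpha: float) -> float:
        """Linear-scale ratio above which the upper tail prob is < alpha."""
        return float(2.0 ** (self.mu + self.sigma * stats.norm.ppf(1.0 - alpha)))

    def upper_tail_prob(self, ratio: float) -> float:
        if ratio <= 0.0:
            return 1.0
        return float(stats.norm.sf((math.log2(ratio) - self.mu) / self.sigma))


def calibrate_tails(
    ratios: Sequence[float],
    window: tuple[float, float] = (-5.0, 1.0),
    min_in_window: int = 30,
) -> TailCalibration:
    """ML fit of a normal truncated to ``window`` on log2 ratios.

    Values outside the window (including sentinel 0s and 10s) are ignored
    during the fit; tail probabilities of the untruncated log-normal then
    measure how unusual each ratio is.
    """
    lo, hi = window
    x = np.array([math.log2(r) for r in ratios if r > 0.0])
    x = x[(x >= lo) & (x <= hi)]
    if len(x) < min_in_window:
        raise CalibrationError(
            f"only {len(x)} in-window values; need >= {min_in_window}"
        )
    if np.ptp(x) == 0.0:
        raise CalibrationError("degenerate data: all in-window values equal")
    n = len(x)
    sx = float(x.sum())
    sxx = float((x * x).sum())

    def nll(params: np.ndarray) -> float:
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        z = stats.norm.cdf((hi - mu) / sigma) - stats.norm.cdf((lo - mu) / sigma)
        if z <= 0.0:
            return 1e300
        return (
            n * log_sigma
            + (sxx - 2 * mu * sx + n * mu * mu) / (2 * sigma * sigma)
            + n * math.log(z)
        )

    x0 = np.array([float(x.mean()), math.log(float(x.std()) + 1e-9)])
    res = optimize.minimize(nll, x0, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10})
    if not res.success:  # pragma: no cover - Nelder-Mead rarely fails here
        raise CalibrationError(f"truncated-normal fit failed: {res.message}")
    mu, sigma = float(res.x[0]), float(math.exp(res.x[1]))
    return TailCalibration(mu=mu, sigma=sigma, window=window, n_used=n)


def synonymous_site_count(cds_seq: str) -> float:
    """Effective synonymous site count of a CDS.

    Each complete non-stop codon contributes 1 per 4-fold position and
    1/3 per 2-fold position (one of three changes synonymous).
    """
    arr = encode(cds_seq)
    n = len(arr) // 3
    total = 0.0
    for i in range(n):
        c = arr[3 * i : 3 * i + 3]
        if np.any(c >= AMBIG):
            continue
        idx = 16 * int(c[0]) + 4 * int(c[1]) + int(c[2])
        if STOP_INDEX[idx]:
            continue
        for p in range(3):
            d = DEGENERACY[idx, p]
            if d == 4:
                total += 1.0
            elif d == 2:
                total += 1.0 / 3.0
    return total
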