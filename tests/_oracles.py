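"""Independent brute-force reference implementations used only by tests.

Each oracle is written as a straight-line transcription of the method's
definition, sharing no code with the package implementation it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

from Bio.Seq import Seq

_STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def _degeneracy(codon: str, pos: int) -> int:
    syn = 0
    for alt in "ACGT":
        if alt == codon[pos]:
            continue
        other = codon[:pos] + alt + codon[pos + 1 :]
        if _aa(other) == _aa(codon):
            syn += 1
    if syn == 3:
        return 4
    if syn == 0:
        return 0
    return 2


def pbl_oracle(seq1: str, seq2: str) -> tuple[float, float]:
    """Naive PBL (dN, dS) for two codon-aligned unambiguous-ish strings."""
    assert len(seq1) == len(seq2) and len(seq1) % 3 == 0
    L = {0: 0.0, 2: 0.0, 4: 0.0}
    ts = {0: 0.0, 2: 0.0, 4: 0.0}
    tv = {0: 0.0, 2: 0.0, 4: 0.0}
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3].upper(), seq2[i : i + 3].upper()
        if any(b not in "ACGT" for b in c1 + c2):
            continue
        if c1 in _STOPS or c2 in _STOPS:
            continue
        for p in range(3):
            d1, d2 = _degeneracy(c1, p), _degeneracy(c2, p)
            L[d1] += 0.5
            L[d2] += 0.5
            if c1[p] != c2[p]:
                transition = {c1[p], c2[p]} in ({"A", "G"}, {"C", "T"})
                bucket = ts if transition else tv
                bucket[d1] += 0.5
                bucket[d2] += 0.5
    A = {}
    B = {}
    for c in (0, 2, 4):
        P = ts[c] / L[c] if L[c] else 0.0
        Q = tv[c] / L[c] if L[c] else 0.0
        A[c] = 0.5 * math.log(1 / (1 - 2 * P - Q)) - 0.25 * math.log(1 / (1 - 2 * Q))
        B[c] = 0.5 * math.log(1 / (1 - 2 * Q))
    ds = (L[2] * A[2] + L[4] * A[4]) / (L[2] + L[4]) + B[4]
    dn = A[0] + (L[0] * B[0] + L[2] * B[2]) / (L[0] + L[2])
    return dn, ds


def wilcoxon_exact_oracle(x: list[float], y: list[float]) -> float:
    """Two-sided exact rank-sum p by full enumeration of group assignments."""
    pooled = list(x) + list(y)
    n, n1 = len(pooled), len(x)
    # midranks
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    w_obs = sum(ranks[:n1])
    sums = [sum(ranks[i] for i in idx) for idx in combinations(range(n), n1)]
    p_lo = sum(1 for s in sums if s <= w_obs + 1e-9) / len(sums)
    p_hi = sum(1 for s in sums if s >= w_obs - 1e-9) / len(sums)
    return min(1.0, 2.0 * min(p_lo, p_hi))


def rbh_oracle(
    hits_ab: list[tuple[str, str, float]], hits_ba: list[tuple[str, str, float]]
) -> set[tuple[str, str]]:
    """Direct transcription of the reciprocal-best-hit procedure."""

    def reduce(hits):
        best: dict[tuple[str, str], float] = {}
        for q, s, b in hits:
            key = (q, s)
            if key not in best or b > best[key]:
                best[key] = b
        rows = [(q, s, b) for (q, s), b in best.items()]
        top_q: dict[str, float] = {}
        for q, s, b in rows:
            top_q[q] = max(top_q.get(q, 0.0), b)
        rows = [(q, s, b) for q, s, b in rows if b >= 0.99 * top_q[q]]
        top_s: dict[str, float] = {}
        for q, s, b in rows:
            top_s[s] = max(top_s.get(s, 0.0), b)
        rows = [(q, s, b) for q, s, b in rows if b >= 0.99 * top_s[s]]
        return rows

    ab = reduce(hits_ab)
    ba = reduce(hits_ba)

    def unique_arcs(rows):
        targets: dict[str, set[str]] = {}
        for q, s, _ in rows:
            targets.setdefault(q, set()).add(s)
        return {q: next(iter(ss)) for q, ss in targets.items() if len(ss) == 1}

    arcs_a = unique_arcs(ab)
    arcs_b = unique_arcs(ba)
    return {(a, b) for a, b in arcs_a.items() if arcs_b.get(b) == a}
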