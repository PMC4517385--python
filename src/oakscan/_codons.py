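"""Genetic-code tables shared by the coding-effect and dN/dS machinery.

Sequences are manipulated as int8 arrays with A,C,G,T -> 0..3 and 4 for an
ambiguous base (any IUPAC ambiguity or padding).  The translation table is
the standard universal code (NCBI #1), taken from Biopython.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
AMBIG = 4
_CODE = {ord(b): i for i, b in enumerate(BASES)}
_CODE.update({ord(b.lower()): i for i, b in enumerate(BASES)})

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)

# amino acid per codon index (16*c0 + 4*c1 + c2), '*' for stop
AA_BY_INDEX = np.empty(64, dtype="<U1")
for _i0, _b0 in enumerate(BASES):
    for _i1, _b1 in enumerate(BASES):
        for _i2, _b2 in enumerate(BASES):
            _cod = _b0 + _b1 + _b2
            _idx = 16 * _i0 + 4 * _i1 + _i2
            AA_BY_INDEX[_idx] = "*" if _cod in STOP_CODONS else _TABLE.forward_table[_cod]

# degeneracy class (0, 2 or 4) per codon index and codon position:
# 4-fold if all three single-base changes at the position are synonymous,
# 0-fold if none are, else 2-fold.  Changes to/from stop count as
# non-synonymous for this purpose.
DEGENERACY = np.zeros((64, 3), dtype=np.int8)
for _idx in range(64):
    _d = [(_idx >> 4) & 3, (_idx >> 2) & 3, _idx & 3]
    for _pos in range(3):
        _syn = 0
        for _alt in range(4):
            if _alt == _d[_pos]:
                continue
            _alt_idx = _idx + (_alt - _d[_pos]) * (4 ** (2 - _pos))
            if AA_BY_INDEX[_alt_idx] == AA_BY_INDEX[_idx]:
                _syn += 1
        DEGENERACY[_idx, _pos] = 4 if _syn == 3 else (0 if _syn == 0 else 2)

STOP_INDEX = np.array([AA_BY_INDEX[i] == "*" for i in range(64)])

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string; unknown characters become ambiguous."""
    out = np.full(len(seq), AMBIG, dtype=np.int8)
    for i, ch in enumerate(seq):
        out[i] = _CODE.get(ord(ch), AMBIG)
    return out


def decode(arr: np.ndarray) -> str:
    return "".join((BASES + "N")[int(x)] for x in arr)


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


def complement_base(base: str) -> str:
    return COMPLEMENT.get(base.upper(), "N")


def codon_index(codon: str) -> int:
    i0, i1, i2 = (BASES.index(b) for b in codon.upper())
    return 16 * i0 + 4 * i1 + i2


def translate_codon(codon: str) -> str:
    """Amino acid ('*' for stop) of a codon over A/C/G/T."""
    return str(AA_BY_INDEX[codon_index(codon)])
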