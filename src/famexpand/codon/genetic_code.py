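"""Universal genetic code tables for the 61 sense codons.

Codons are ordered alphabetically over A, C, G, T with the three stop
codons (TAA, TAG, TGA) removed.  Precomputed arrays identify, for every
ordered pair of codons differing at exactly one position, whether the
change is a transition and whether it is synonymous — the ingredients of
the Goldman–Yang style codon rate matrix.
"""

from __future__ import annotations

import itertools

import numpy as np

NUCLEOTIDES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")

CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3) if "".join(c) not in STOP_CODONS
)
N_CODONS = len(CODONS)  # 61
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

AMINO_ACIDS: tuple[str, ...] = tuple(_CODON_TABLE[c] for c in CODONS)

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _pair_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Index arrays over single-nucleotide codon pairs (i, j, is_ts, is_syn)."""
    ii, jj, ts, syn = [], [], [], []
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            ii.append(i)
            jj.append(j)
            ts.append(frozenset(diffs[0]) in _TRANSITIONS)
            syn.append(AMINO_ACIDS[i] == AMINO_ACIDS[j])
    return (
        np.asarray(ii, dtype=np.intp),
        np.asarray(jj, dtype=np.intp),
        np.asarray(ts, dtype=bool),
        np.asarray(syn, dtype=bool),
    )


PAIR_I, PAIR_J, PAIR_IS_TRANSITION, PAIR_IS_SYNONYMOUS = _pair_tables()

# per-codon nucleotide index at each of the 3 positions, for F3x4 frequencies
CODON_POS_NUC = np.array(
    [[NUCLEOTIDES.index(c[k]) for k in range(3)] for c in CODONS], dtype=np.intp
)


def codon_to_index(codon: str) -> int:
    """Index of a sense codon; -1 for gaps, stops or ambiguity (missing data)."""
    return CODON_INDEX.get(codon.upper().replace("U", "T"), -1)
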