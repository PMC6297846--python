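"""Codon alignments: construction, I/O and column cleaning.

Sequences are stored as integer codon states over the 61 sense codons;
gaps and ambiguous codons are missing data (state −1) and contribute a
partial likelihood of one — they are not deleted, so site coordinates stay
auditable.  Column cleaning (gap-fraction filter) is a separate, explicit
step that returns the mapping back to original codon positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import AlignIO

from ..family_data import FamilyDataError, read_fasta
from .genetic_code import CODON_INDEX, STOP_CODONS

__all__ = ["CodonAlignment", "clean_alignment", "read_codon_alignment"]

_VALID_NUC = set("ACGT")


@dataclass
class CodonAlignment:
    """Gap-aware alignment over sense codons.

    ``codons`` has shape (n_taxa, n_codons) with values in [0, 61) or −1
    for missing (gap/ambiguity).
    """

    taxa: list[str]
    codons: np.ndarray

    def __post_init__(self) -> None:
        self.codons = np.asarray(self.codons, dtype=np.int16)
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.taxa):
            raise ValueError("codons must be (n_taxa, n_codons)")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return self.codons.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.codons[self.taxa.index(taxon)]

    @classmethod
    def from_sequences(cls, records: Sequence[tuple[str, str]]) -> "CodonAlignment":
        """Build from aligned nucleotide sequences (lengths divisible by 3)."""
        taxa, rows = [], []
        length = None
        for name, seq in records:
            seq = seq.upper().replace("U", "T")
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise FamilyDataError(
                    f"sequence {name!r} has length {len(seq)}, expected {length}"
                )
            if len(seq) % 3 != 0:
                raise FamilyDataError(f"sequence {name!r} length not divisible by 3")
            states = []
            for k in range(0, len(seq), 3):
                codon = seq[k : k + 3]
                if codon in STOP_CODONS:
                    raise FamilyDataError(
                        f"stop codon {codon} in {name!r} at codon position {k // 3 + 1}"
                    )
                if set(codon) <= _VALID_NUC:
                    states.append(CODON_INDEX[codon])
                else:
                    states.append(-1)  # gap or ambiguity -> missing
            taxa.append(name)
            rows.append(states)
        return cls(taxa, np.asarray(rows, dtype=np.int16))

    def to_sequences(self) -> list[tuple[str, str]]:
        from .genetic_code import CODONS

        out = []
        for name, row in zip(self.taxa, self.codons):
            seq = "".join(CODONS[s] if s >= 0 else "---" for s in row)
            out.append((name, seq))
        return out

    def subset(self, taxa: Sequence[str]) -> "CodonAlignment":
        idx = [self.taxa.index(t) for t in taxa]
        return CodonAlignment(list(taxa), self.codons[idx].copy())


def read_codon_alignment(path: str, fmt: str = "fasta") -> CodonAlignment:
    """Read a codon alignment from FASTA or sequential PHYLIP."""
    if fmt == "fasta":
        return CodonAlignment.from_sequences(read_fasta(path))
    if fmt in {"phylip", "phylip-sequential"}:
        aln = AlignIO.read(path, "phylip-sequential")
        return CodonAlignment.from_sequences([(r.id, str(r.seq)) for r in aln])
    raise ValueError(f"unknown alignment format {fmt!r}")


def clean_alignment(
    aln: CodonAlignment, max_gap_fraction: float = 0.5
) -> tuple[CodonAlignment, np.ndarray]:
    """Drop codon columns whose missing fraction exceeds the threshold.

    Returns the cleaned alignment and an index map: entry *k* is the
    original (0-based) column index of cleaned column *k*, so flagged sites
    can be reported in original coordinates.
    """
    gap_frac = (aln.codons < 0).mean(axis=0)
    keep = np.flatnonzero(gap_frac <= max_gap_fraction)
    if keep.size == 0:
        raise FamilyDataError(
            f"all {aln.n_codons} columns exceed gap fraction {max_gap_fraction}"
        )
    return CodonAlignment(list(aln.taxa), aln.codons[:, keep].copy()), keep
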