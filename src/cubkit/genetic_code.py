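"""Bacterial genetic code (NCBI translation table 11) and codon bookkeeping.

All downstream indices partition the 64 codons into 61 sense codons and the
3 stop codons {TAA, TAG, TGA}, and group sense codons into synonymous
families.  Met (ATG) and Trp (TGG) form single-codon families and are
excluded from every synonymous-usage statistic, leaving the 59 codons on
which RSCU, CAI weights and correspondence analysis operate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

BASES = "TCAG"
ALL_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(BASES, repeat=3)
)

# Kyte-Doolittle hydropathy, standard one-letter amino-acid keys.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

AROMATIC = frozenset("FYW")


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> amino-acid map plus the synonymous-family structure.

    Attributes
    ----------
    table_id : NCBI translation table number (11, bacterial).
    codon_to_aa : map over the 61 sense codons (one-letter amino acids).
    families : amino acid -> tuple of its synonymous codons.
    stop_codons : the 3 termination codons.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    families: dict[str, tuple[str, ...]]
    stop_codons: frozenset[str]
    synonymous_codons: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        syn = tuple(
            c for c in ALL_CODONS
            if c in self.codon_to_aa and len(self.families[self.codon_to_aa[c]]) > 1
        )
        object.__setattr__(self, "synonymous_codons", syn)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if c in self.codon_to_aa)

    def degeneracy(self, codon: str) -> int:
        return len(self.families[self.codon_to_aa[codon]])

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.codon_to_aa[codon]]

    def families_by_degeneracy(self, k: int) -> list[tuple[str, ...]]:
        return [f for f in self.families.values() if len(f) == k]


@lru_cache(maxsize=None)
def bacterial_code(table_id: int = 11) -> GeneticCode:
    """Build the table-11 :class:`GeneticCode` from Biopython's codon tables."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    codon_to_aa = dict(table.forward_table)
    families: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        aa = codon_to_aa.get(codon)
        if aa is not None:
            families.setdefault(aa, []).append(codon)
    return GeneticCode(
        table_id=table_id,
        codon_to_aa=codon_to_aa,
        families={aa: tuple(v) for aa, v in families.items()},
        stop_codons=frozenset(table.stop_codons),
    )


def to_rna(codon: str) -> str:
    """DNA codon label -> RNA label (T -> U), as used in context reports."""
    return codon.replace("T", "U")
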