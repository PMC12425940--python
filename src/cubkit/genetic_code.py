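"""Standard nuclear genetic code and its degeneracy structure.

Everything downstream (RSCU, ENC, composition indices, the 56-codon analysis
set) is driven by the synonymous-family structure defined here.  The code is
fixed to the standard nuclear table (NCBI translation table 1); the gene sets
this package targets are nuclear plant CDS, so no other table is exposed.

Codons are stored internally in the DNA alphabet (``T``); report-facing
functions convert to RNA (``U``) because codon-usage tables are conventionally
printed that way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

BASES = ("T", "C", "A", "G")

ALL_CODONS: tuple[str, ...] = tuple(
    b1 + b2 + b3 for b1 in BASES for b2 in BASES for b3 in BASES
)


def to_rna(codon: str) -> str:
    """DNA codon -> RNA codon (ACGT -> ACGU)."""
    return codon.replace("T", "U")


def to_dna(codon: str) -> str:
    """RNA codon -> DNA codon (ACGU -> ACGT)."""
    return codon.upper().replace("U", "T")


@dataclass(frozen=True, eq=False)  # identity hash: instances are cached singletons
class GeneticCode:
    """The standard genetic code plus the derived structures CUB analysis needs.

    Attributes
    ----------
    codon_to_aa
        Maps each of the 64 DNA codons to a one-letter amino acid, with stop
        codons mapped to ``*``.
    stop_codons
        The three stop codons (TAA, TAG, TGA).
    degeneracy
        Synonymous-family size per amino acid: 1 (Met, Trp), 2 (nine amino
        acids), 3 (Ile), 4 (five amino acids) or 6 (Leu, Ser, Arg).
    families
        Amino acid -> ordered tuple of its codons.
    analysis_set
        The 56 codons retained for RSCU reporting and PCA: all 64 minus the
        initiation codon ATG, the tryptophan codon TGG, the three isoleucine
        codons and the three stop codons.
    """

    codon_to_aa: dict[str, str]
    stop_codons: frozenset[str]
    degeneracy: dict[str, int]
    families: dict[str, tuple[str, ...]]
    analysis_set: tuple[str, ...]
    name: str = field(default="standard", compare=False)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if c not in self.stop_codons)

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(self.families)

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.codon_to_aa[codon]]

    def synonymous_codons(self) -> tuple[str, ...]:
        """Sense codons of amino acids with at least two synonymous codons."""
        return tuple(
            c for c in self.sense_codons if self.degeneracy[self.codon_to_aa[c]] >= 2
        )


@lru_cache(maxsize=1)
def standard_code() -> GeneticCode:
    """Build the standard nuclear code (translation table 1) from Biopython."""
    table = CodonTable.unambiguous_dna_by_id[1]
    codon_to_aa: dict[str, str] = {}
    for codon in ALL_CODONS:
        if codon in table.stop_codons:
            codon_to_aa[codon] = "*"
        else:
            codon_to_aa[codon] = table.forward_table[codon]
    stops = frozenset(table.stop_codons)

    families: dict[str, tuple[str, ...]] = {}
    for aa in sorted(set(codon_to_aa.values()) - {"*"}):
        families[aa] = tuple(c for c in ALL_CODONS if codon_to_aa[c] == aa)
    degeneracy = {aa: len(fam) for aa, fam in families.items()}

    excluded = {"ATG", "TGG"} | set(families["I"]) | set(stops)
    analysis = tuple(c for c in ALL_CODONS if c not in excluded)
    return GeneticCode(
        codon_to_aa=codon_to_aa,
        stop_codons=stops,
        degeneracy=degeneracy,
        families=families,
        analysis_set=analysis,
    )
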