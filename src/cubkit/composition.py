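"""Per-gene nucleotide-composition indices.

GC content overall and by codon position (GC1, GC2, GC3, and their mean
GC12), GC at synonymous third positions (GC3s), and the per-base synonymous
third-position frequencies A3s/T3s/G3s/C3s.

Two conventions deserve care:

* GC3 is computed over ALL sense codons (including Met and Trp) and feeds the
  neutrality plot; GC3s is restricted to codons of amino acids with at least
  two synonymous codons and feeds the ENC-plot.  The two are never aliased.
* X3s uses the CodonW convention: the numerator counts synonymous codons
  whose third base is x, while the denominator counts synonymous codons of
  amino acids that possess at least one synonymous codon ending in x.  The
  denominators therefore differ between the four bases and the four X3s do
  not generally sum to 1.  A ``strict`` dialect (single denominator: all
  synonymous codons) is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal

from .genetic_code import GeneticCode, standard_code
from .seqio import CodonCountTable

X3sDialect = Literal["codonw", "strict"]


@dataclass(frozen=True)
class CompositionProfile:
    gene_id: str
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc3s: float
    a3s: float
    t3s: float
    g3s: float
    c3s: float
    n_codons: int
    ok: bool = True


@lru_cache(maxsize=4)
def _x3s_denominator_codons(code: GeneticCode) -> dict[str, frozenset[str]]:
    """For each base x, the synonymous codons of amino acids able to end in x."""
    out: dict[str, frozenset[str]] = {}
    for base in "ACGT":
        members: set[str] = set()
        for aa, fam in code.families.items():
            if code.degeneracy[aa] < 2:
                continue
            if any(c[2] == base for c in fam):
                members.update(fam)
        out[base] = frozenset(members)
    return out


def composition_profile(
    counts: CodonCountTable,
    code: GeneticCode | None = None,
    x3s_dialect: X3sDialect = "codonw",
) -> CompositionProfile:
    """Compute all composition indices for one gene from its codon counts.

    With zero usable codons every field is NaN and ``ok`` is False.
    """
    code = code or standard_code()
    if counts.total_codons == 0:
        nan = math.nan
        return CompositionProfile(
            counts.gene_id, nan, nan, nan, nan, nan, nan, nan, nan, nan, nan, 0, ok=False
        )

    gc_pos = [0, 0, 0]
    total = 0
    for codon in code.sense_codons:
        n = counts.counts[codon]
        if n == 0:
            continue
        total += n
        for pos in range(3):
            if codon[pos] in "GC":
                gc_pos[pos] += n

    syn = code.synonymous_codons()
    syn_total = sum(counts.counts[c] for c in syn)
    syn_gc3 = sum(counts.counts[c] for c in syn if c[2] in "GC")

    third_counts = {b: sum(counts.counts[c] for c in syn if c[2] == b) for b in "ACGT"}
    if x3s_dialect == "codonw":
        denoms = _x3s_denominator_codons(code)
        x3s = {}
        for b in "ACGT":
            denom = sum(counts.counts[c] for c in denoms[b])
            x3s[b] = third_counts[b] / denom if denom else math.nan
    else:
        x3s = {
            b: (third_counts[b] / syn_total if syn_total else math.nan) for b in "ACGT"
        }

    gc1 = gc_pos[0] / total
    gc2 = gc_pos[1] / total
    gc3 = gc_pos[2] / total
    return CompositionProfile(
        gene_id=counts.gene_id,
        gc=(gc_pos[0] + gc_pos[1] + gc_pos[2]) / (3 * total),
        gc1=gc1,
        gc2=gc2,
        gc3=gc3,
        gc12=(gc1 + gc2) / 2,
        gc3s=syn_gc3 / syn_total if syn_total else math.nan,
        a3s=x3s["A"],
        t3s=x3s["T"],
        g3s=x3s["G"],
        c3s=x3s["C"],
        n_codons=total,
    )
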