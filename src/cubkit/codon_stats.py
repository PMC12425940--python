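"""Relative synonymous codon usage and Wright's effective number of codons.

RSCU for codon *c* of an amino acid with family count :math:`n_a` and
degeneracy :math:`k_a` is :math:`\\mathrm{RSCU}(c) = k_a \\, n_c / n_a` —
the observed count relative to the count expected under uniform synonymous
usage.  Family values sum to the degeneracy, so the within-family mean is 1.

Wright's ENC estimates how many codons are effectively in use.  Per amino
acid used :math:`n \\ge 2` times, the codon homozygosity is

.. math:: \\hat F = \\frac{n \\sum_i \\hat p_i^2 - 1}{n - 1},

with :math:`\\hat p_i` the within-family codon frequencies.  Averaging
:math:`\\hat F` within each degeneracy class gives :math:`\\bar F_k` and

.. math:: N_c = 2 + \\frac{9}{\\bar F_2} + \\frac{1}{\\bar F_3}
          + \\frac{5}{\\bar F_4} + \\frac{3}{\\bar F_6},

capped into [20, 61].  20 means one codon per amino acid; 61 means no bias.
When isoleucine (the only 3-fold family) is unobservable, its class mean is
imputed as the average of the 2-fold and 4-fold class means and the
imputation is recorded; a missing 2-, 4- or 6-fold class leaves ENC
undefined with a QC flag rather than silently imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .genetic_code import GeneticCode, standard_code
from .seqio import CodonCountTable, pool_counts


@dataclass(frozen=True)
class RscuVector:
    """Per-codon RSCU for one gene or one pooled group.

    ``values`` maps every sense codon to its RSCU; codons of an amino acid
    that never occurs are NaN (undefined, not zero).
    """

    scope: str
    values: dict[str, float]
    n_codons_used: int


@dataclass(frozen=True)
class EncResult:
    gene_id: str
    enc: float
    f_bar: dict[int, float]
    imputed_classes: frozenset[int] = field(default_factory=frozenset)
    capped: bool = False
    ok: bool = True


def rscu(counts: CodonCountTable, code: GeneticCode | None = None) -> RscuVector:
    """RSCU of every sense codon for one count table."""
    code = code or standard_code()
    values: dict[str, float] = {}
    for aa, fam in code.families.items():
        n_a = sum(counts.counts[c] for c in fam)
        k_a = code.degeneracy[aa]
        for c in fam:
            values[c] = counts.counts[c] * k_a / n_a if n_a > 0 else math.nan
    return RscuVector(scope=counts.gene_id, values=values, n_codons_used=counts.total_codons)


def pooled_rscu(
    tables: Iterable[CodonCountTable],
    code: GeneticCode | None = None,
    label: str = "pooled",
) -> RscuVector:
    """RSCU of element-wise summed counts (usage-weighted pooling).

    This is deliberately not the mean of per-gene RSCU: pooling counts keeps
    the family-sum identity exact and weights genes by their codon usage.
    """
    return rscu(pool_counts(tables, label=label), code)


def high_frequency_codons(
    r: RscuVector, code: GeneticCode | None = None
) -> set[str]:
    """Codons of the 56-codon analysis set with RSCU strictly above 1."""
    code = code or standard_code()
    return {
        c
        for c in code.analysis_set
        if not math.isnan(r.values[c]) and r.values[c] > 1.0
    }


def _family_homozygosity(counts: Mapping[str, int], fam: tuple[str, ...]) -> tuple[int, float]:
    """(n, F-hat) for one synonymous family; F-hat is NaN when n < 2."""
    n = sum(counts[c] for c in fam)
    if n < 2:
        return n, math.nan
    sum_p2 = sum((counts[c] / n) ** 2 for c in fam)
    return n, (n * sum_p2 - 1) / (n - 1)


def _enc_families(
    code: GeneticCode, sixfold: str
) -> list[tuple[int, tuple[str, ...]]]:
    """(class size, codon family) pairs entering the ENC class means.

    ``sixfold="joint"`` (Wright, CodonW default) keeps Leu/Ser/Arg as single
    6-codon families; ``"split"`` divides each into its 4-fold block (shared
    first two bases) and 2-fold remainder, as some tools do.
    """
    fams: list[tuple[int, tuple[str, ...]]] = []
    for aa, fam in code.families.items():
        k = code.degeneracy[aa]
        if k < 2:
            continue
        if k == 6 and sixfold == "split":
            prefixes = {c[:2] for c in fam}
            for pre in sorted(prefixes):
                sub = tuple(c for c in fam if c[:2] == pre)
                fams.append((len(sub), sub))
        else:
            fams.append((k, fam))
    return fams


def enc(
    counts: CodonCountTable,
    code: GeneticCode | None = None,
    impute_missing_ile: bool = True,
    sixfold: str = "joint",
) -> EncResult:
    """Wright's effective number of codons for one gene.

    Amino acids observed fewer than twice contribute nothing (the bias
    correction divides by n−1); class means additionally drop families whose
    F-hat is exactly 0, which cannot enter a harmonic contribution.
    """
    code = code or standard_code()
    class_f: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    n_families: dict[int, int] = {2: 0, 3: 0, 4: 0, 6: 0}
    for k, fam in _enc_families(code, sixfold):
        n_families[k] += 1
        n, f_hat = _family_homozygosity(counts.counts, fam)
        if n >= 2 and not math.isnan(f_hat) and f_hat > 0:
            class_f[k].append(f_hat)

    f_bar = {k: (sum(v) / len(v) if v else math.nan) for k, v in class_f.items()}
    imputed: set[int] = set()
    if math.isnan(f_bar[3]) and impute_missing_ile:
        if not (math.isnan(f_bar[2]) or math.isnan(f_bar[4])):
            f_bar[3] = (f_bar[2] + f_bar[4]) / 2
            imputed.add(3)

    weights = {k: float(n) for k, n in n_families.items()}
    required = [k for k in (2, 3, 4, 6) if n_families[k] > 0 or k == 3]
    if any(math.isnan(f_bar[k]) for k in required):
        return EncResult(
            gene_id=counts.gene_id,
            enc=math.nan,
            f_bar=f_bar,
            imputed_classes=frozenset(imputed),
            ok=False,
        )
    raw = 2.0 + sum(weights[k] / f_bar[k] for k in (2, 3, 4, 6) if weights[k] > 0)
    capped = raw > 61.0 or raw < 20.0
    return EncResult(
        gene_id=counts.gene_id,
        enc=min(61.0, max(20.0, raw)),
        f_bar=f_bar,
        imputed_classes=frozenset(imputed),
        capped=capped,
    )
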