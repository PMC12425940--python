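"""Optimal codon identification by the ΔRSCU extreme-group method.

Genes are ranked by ENC; the lowest-ENC tail (strong bias, conventionally
labelled the "high-expression" group) and the highest-ENC tail are pooled
separately and each group's RSCU is computed from summed counts.  A codon is

* **highly expressed** when its RSCU is higher in the low-ENC group by at
  least a threshold (ΔRSCU = RSCU_high − RSCU_low ≥ 0.08 by default),
* **high frequency** when its RSCU over the complete gene set exceeds 1, and
* **optimal** when both hold.

The classifier also accepts an externally supplied group-RSCU table plus a
high-frequency codon list, so published tables can be re-classified without
the underlying sequences; a reference table for the 151-gene banana WRKY
transcription-factor CDS set is bundled as the worked example.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .codon_stats import EncResult, RscuVector, pooled_rscu
from .genetic_code import GeneticCode, standard_code, to_dna, to_rna
from .seqio import CodonCountTable


@dataclass(frozen=True)
class ExtremeGroups:
    high_expression: tuple[str, ...]  # lowest ENC
    low_expression: tuple[str, ...]  # highest ENC
    fraction: float
    group_size: int


def extreme_groups(
    enc_results: Iterable[EncResult], fraction: float = 0.10
) -> ExtremeGroups:
    """Select the low-ENC and high-ENC tails of the gene set.

    Group size is floor(fraction * n), at least 1.  Sorting is by ENC
    ascending with gene_id as a deterministic tie-break.
    """
    usable = [e for e in enc_results if e.ok and not math.isnan(e.enc)]
    n = len(usable)
    size = max(1, int(fraction * n))
    if n < 2 * size:
        raise ValueError(
            f"{n} genes cannot supply two disjoint groups of {size} at fraction {fraction}"
        )
    ranked = sorted(usable, key=lambda e: (e.enc, e.gene_id))
    return ExtremeGroups(
        high_expression=tuple(e.gene_id for e in ranked[:size]),
        low_expression=tuple(e.gene_id for e in ranked[-size:]),
        fraction=fraction,
        group_size=size,
    )


def _classify(
    rscu_high: Mapping[str, float],
    rscu_low: Mapping[str, float],
    high_frequency: set[str],
    code: GeneticCode,
    delta_threshold: float,
) -> pd.DataFrame:
    rows = []
    for codon in code.analysis_set:
        aa = code.codon_to_aa[codon]
        hi = rscu_high.get(codon, math.nan)
        lo = rscu_low.get(codon, math.nan)
        delta = hi - lo
        defined = not (math.isnan(hi) or math.isnan(lo))
        highly_expressed = defined and delta >= delta_threshold
        hf = codon in high_frequency
        rows.append(
            {
                "amino_acid": aa,
                "codon": to_rna(codon),
                "rscu_high": hi,
                "rscu_low": lo,
                "delta": delta,
                "highly_expressed": highly_expressed,
                "high_frequency": hf,
                "optimal": highly_expressed and hf,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["amino_acid", "codon"], ignore_index=True)


def delta_rscu_table(
    groups: ExtremeGroups,
    tables: Mapping[str, CodonCountTable],
    pooled: RscuVector,
    code: GeneticCode | None = None,
    delta_threshold: float = 0.08,
    rscu_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-codon ΔRSCU classification over the 56-codon analysis set.

    Group RSCUs come from pooled (summed) counts within each group, which
    keeps the within-family RSCU sums exactly equal to the degeneracy and
    hence the within-family ΔRSCU sum exactly 0.  Codons of an amino acid
    absent from either group have NaN group values and are never classified.
    """
    code = code or standard_code()
    r_high = pooled_rscu([tables[g] for g in groups.high_expression], code, label="high")
    r_low = pooled_rscu([tables[g] for g in groups.low_expression], code, label="low")
    hf = {
        c
        for c in code.analysis_set
        if not math.isnan(pooled.values[c]) and pooled.values[c] > rscu_threshold
    }
    return _classify(r_high.values, r_low.values, hf, code, delta_threshold)


def classify_from_group_rscu(
    group_rscu: pd.DataFrame,
    high_frequency: Iterable[str],
    code: GeneticCode | None = None,
    delta_threshold: float = 0.08,
) -> pd.DataFrame:
    """Classify from an externally supplied group-RSCU table.

    ``group_rscu`` needs columns ``codon`` (RNA or DNA alphabet),
    ``rscu_high`` and ``rscu_low``; ``high_frequency`` is the codon list to
    intersect with.  Output matches :func:`delta_rscu_table`.
    """
    code = code or standard_code()
    hi = {to_dna(r.codon): float(r.rscu_high) for r in group_rscu.itertuples()}
    lo = {to_dna(r.codon): float(r.rscu_low) for r in group_rscu.itertuples()}
    hf = {to_dna(c) for c in high_frequency}
    return _classify(hi, lo, hf, code, delta_threshold)


def optimal_codon_set(rows: pd.DataFrame) -> list[str]:
    """Codons flagged optimal, ordered by amino acid then codon."""
    sel = rows[rows["optimal"]].sort_values(["amino_acid", "codon"])
    return list(sel["codon"])


def load_reference_group_rscu() -> pd.DataFrame:
    """Bundled extreme-group RSCU table for the banana WRKY CDS set."""
    with resources.files("cubkit.data").joinpath("mawrky_extreme_group_rscu.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_reference_high_frequency() -> list[str]:
    """Bundled genome-wide high-frequency (RSCU > 1) codon list for the
    banana WRKY CDS set (26 codons, RNA alphabet)."""
    with resources.files("cubkit.data").joinpath("mawrky_high_frequency_codons.txt").open() as fh:
        return [line.strip() for line in fh if line.strip()]
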