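"""Seeded generator of CDS sets with known mutation pressure and selection.

The analysis stages only ever see codon composition, so the generator
implements the minimal structure that produces the signals the diagnostics
are built to detect, with the ground truth recorded per gene:

* a per-gene **mutational GC pressure** ``g``: within each synonymous
  family, a codon's weight is ``g`` for a G/C third base and ``1 - g`` for
  an A/T third base (normalized within the family);
* a per-gene **selection weight** ``w``: with probability ``w`` a site's
  codon is instead drawn uniformly from the preferred (optimal) codons of
  its amino acid — concentrating usage and pulling ENC below the
  composition-only expectation;
* in mutation and mixed modes, an **amino-acid coupling** that tilts amino
  acid choice toward residues whose first two codon positions are G/C-rich
  when ``g`` is high, so GC12 co-varies with GC3 and the neutrality plot
  has a recoverable positive slope.

Genes draw from independent substreams keyed on (seed, gene index), so the
same seed is byte-identical and extending ``n_genes`` never changes earlier
genes.  Default parameters emulate a plant transcription-factor family CDS
set: 151 genes, lengths log-normal with a 100-codon floor, mean GC around
0.56 and mean GC3s around 0.62, per-gene ENC spread roughly 35-60.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .genetic_code import GeneticCode, standard_code
from .seqio import CdsRecord

Mode = Literal["mutation", "selection", "mixed"]

# Amino-acid frequencies typical of plant proteomes (normalized at use).
DEFAULT_AA_FREQUENCIES: dict[str, float] = {
    "A": 0.069, "R": 0.054, "N": 0.045, "D": 0.054, "C": 0.018,
    "Q": 0.035, "E": 0.065, "G": 0.066, "H": 0.023, "I": 0.050,
    "L": 0.093, "K": 0.062, "M": 0.024, "F": 0.044, "P": 0.049,
    "S": 0.082, "T": 0.050, "V": 0.067, "W": 0.012, "Y": 0.028,
}

# One G/C-ending preferred codon per amino acid (two for the 6-fold families
# Leu and Ser), mirroring the G/C-ending optimal sets typical of monocots.
DEFAULT_OPTIMAL_SET: dict[str, tuple[str, ...]] = {
    "L": ("CTC", "CTG"), "V": ("GTG",), "S": ("TCC", "AGC"), "P": ("CCG",),
    "T": ("ACC",), "A": ("GCC",), "Y": ("TAC",), "H": ("CAC",), "Q": ("CAG",),
    "N": ("AAC",), "K": ("AAG",), "D": ("GAC",), "E": ("GAG",), "C": ("TGC",),
    "F": ("TTC",), "R": ("CGC",), "G": ("GGC",), "I": ("ATC",),
    "M": ("ATG",), "W": ("TGG",),
}


@dataclass(frozen=True)
class SimulationParams:
    """Study-condition parameters for one synthetic CDS set.

    ``gc_pressure`` / ``selection_weight``: a float fixes the value for all
    genes; None draws per-gene values from the Beta distributions below.
    Mode only chooses sensible defaults for selection weight and coupling:
    mutation -> weight 0, coupling on; selection -> weight 0.8, coupling
    off; mixed -> Beta-distributed weights, coupling on.
    """

    n_genes: int = 151
    length_log_mean: float = float(np.log(350.0))  # codons
    length_log_sigma: float = 0.35
    min_codons: int = 100
    aa_frequencies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AA_FREQUENCIES)
    )
    mode: Mode = "mixed"
    gc_pressure: float | None = None
    gc_beta: tuple[float, float] = (9.9, 6.1)  # mean ~0.62, sd ~0.12
    selection_weight: float | None = None
    selection_beta: tuple[float, float] = (1.5, 6.0)  # mean 0.2 (mixed mode)
    coupling: float | None = None
    optimal_set: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_OPTIMAL_SET)
    )
    seed: int = 0

    def effective_coupling(self) -> float:
        if self.coupling is not None:
            return self.coupling
        return 0.0 if self.mode == "selection" else 1.5

    def draw_gene_params(self, rng: np.random.Generator) -> tuple[float, float]:
        """(gc_pressure, selection_weight) for one gene's substream."""
        g = self.gc_pressure if self.gc_pressure is not None else float(
            rng.beta(*self.gc_beta)
        )
        if self.selection_weight is not None:
            w = self.selection_weight
        elif self.mode == "mutation":
            w = 0.0
        elif self.mode == "selection":
            w = 0.8
        else:
            w = float(rng.beta(*self.selection_beta))
        return g, w


@dataclass(frozen=True)
class TruthTable:
    """Per-gene ground truth plus the parameters that produced the set."""

    genes: pd.DataFrame  # gene_id, length_codons, gc_pressure, selection_weight
    params: SimulationParams


def _aa_gc12(code: GeneticCode) -> dict[str, float]:
    """Mean G/C fraction of the first two codon positions, per amino acid."""
    out = {}
    for aa, fam in code.families.items():
        out[aa] = float(
            np.mean([(c[0] in "GC") + (c[1] in "GC") for c in fam]) / 2.0
        )
    return out


def _gene_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def _mutation_kernel(fam: tuple[str, ...], g: float) -> np.ndarray:
    w = np.array([g if c[2] in "GC" else 1.0 - g for c in fam])
    return w / w.sum()


def generate_gene_set(
    params: SimulationParams, code: GeneticCode | None = None
) -> tuple[list[CdsRecord], TruthTable]:
    """Generate a CDS set under the given study conditions.

    Every sequence is ATG-initiated and stop-terminated; the body amino
    acids are drawn from (possibly GC-coupled) frequencies and each site's
    codon from the selection/mutation mixture.
    """
    code = code or standard_code()
    if params.n_genes < 1:
        raise ValueError("n_genes must be at least 1")
    aas = sorted(set(params.aa_frequencies) & set(code.families))
    base_freq = np.array([params.aa_frequencies[a] for a in aas], dtype=float)
    if not np.all(base_freq >= 0) or base_freq.sum() <= 0:
        raise ValueError("amino-acid frequencies must be non-negative and not all zero")
    base_freq = base_freq / base_freq.sum()

    needs_selection = params.mode != "mutation" or params.selection_weight not in (None, 0.0)
    if needs_selection:
        missing = [a for a in aas if not params.optimal_set.get(a)]
        if missing:
            raise ValueError(
                f"optimal_set lacks preferred codons for: {', '.join(missing)}"
            )

    gc12 = _aa_gc12(code)
    tilt_base = np.array([2.0 * gc12[a] - 1.0 for a in aas])
    coupling = params.effective_coupling()

    records: list[CdsRecord] = []
    truth_rows = []
    for idx in range(params.n_genes):
        rng = _gene_rng(params.seed, idx)
        g, w = params.draw_gene_params(rng)
        length = int(
            max(
                params.min_codons,
                round(rng.lognormal(params.length_log_mean, params.length_log_sigma)),
            )
        )
        freq = base_freq * np.exp(coupling * tilt_base * (2.0 * g - 1.0))
        freq = freq / freq.sum()
        aa_seq = rng.choice(len(aas), size=length, p=freq)

        codons = np.empty(length, dtype=object)
        for ai in np.unique(aa_seq):
            aa = aas[ai]
            fam = code.families[aa]
            sites = np.flatnonzero(aa_seq == ai)
            p = _mutation_kernel(fam, g)
            if w > 0:
                opt = params.optimal_set[aa]
                u = np.array([1.0 / len(opt) if c in opt else 0.0 for c in fam])
                p = w * u + (1.0 - w) * p
            codons[sites] = rng.choice(np.array(fam, dtype=object), size=len(sites), p=p)

        stop = str(rng.choice(np.array(sorted(code.stop_codons), dtype=object)))
        seq = "ATG" + "".join(codons.tolist()) + stop
        # fixed-width ids so extending n_genes never renames earlier genes
        gene_id = f"synth{idx + 1:05d}"
        records.append(CdsRecord(gene_id=gene_id, sequence=seq))
        truth_rows.append(
            {
                "gene_id": gene_id,
                "length_codons": length + 1,  # body plus initiator Met
                "gc_pressure": g,
                "selection_weight": w,
            }
        )
    truth = TruthTable(genes=pd.DataFrame(truth_rows), params=params)
    return records, truth


def regenerate(truth: TruthTable, code: GeneticCode | None = None) -> list[CdsRecord]:
    """Rebuild the exact sequences a truth table came from.

    Reproducibility contract: byte-identical to the original generation.
    """
    if truth.params.seed is None:  # defensive; dataclass default prevents this
        raise ValueError("truth table lacks a seed")
    records, _ = generate_gene_set(truth.params, code)
    return records


def write_truth_tsv(truth: TruthTable, path) -> None:
    truth.genes.to_csv(path, sep="\t", index=False)


def extend(truth: TruthTable, n_genes: int, code: GeneticCode | None = None):
    """Regenerate with a different gene count; earlier genes are unchanged
    because every gene draws from its own (seed, index) substream."""
    return generate_gene_set(replace(truth.params, n_genes=n_genes), code)
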