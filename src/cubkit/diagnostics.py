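"""Mutation-versus-selection diagnostics across a gene set.

Four classic views of codon usage:

* **ENC-plot** — per-gene ENC against GC3s, compared with the composition-only
  expectation ``Nc* = 2 + s + 29/(s^2 + (1-s)^2)``.  Genes shaped only by
  mutational GC pressure straddle the curve; genes under translational
  selection fall noticeably below it (positive relative deviation).
* **PR2 bias plot** — A3/(A3+T3) against G3/(G3+C3) at the third positions of
  four-fold degenerate families.  (0.5, 0.5) means no asymmetry between the
  complementary bases; systematic displacement implicates strand-specific
  mutation or selection.
* **Neutrality plot** — OLS regression of GC12 on GC3 across genes.  A slope
  near 1 indicates mutation pressure acting on all positions alike; a slope
  near 0 indicates selection holding first/second positions in place while
  third positions drift.
* **Correlation matrix** — pairwise Pearson correlations (with two-sided
  t-test p-values) among the per-gene indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_stats import EncResult
from .composition import CompositionProfile
from .genetic_code import GeneticCode, standard_code
from .seqio import CodonCountTable


def enc_expected(gc3s: float) -> float:
    """Expected ENC when composition alone (GC3s = s) drives codon choice.

    ``Nc* = 2 + s + 29 / (s^2 + (1 - s)^2)``, the standard ENC-plot null
    curve.  Raises ValueError outside [0, 1].
    """
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"GC3s must lie in [0, 1], got {gc3s}")
    s = gc3s
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) * (1.0 - s))


def enc_plot_table(
    genes: Iterable[tuple[CompositionProfile, EncResult]],
    abscissa: str = "gc3s",
    deviation_threshold: float = 0.1,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene ENC-plot rows plus above/near/below summary counts.

    ``deviation = (Nc* - Nc) / Nc*``; genes with deviation above the
    threshold sit "noticeably below" the curve.  ``abscissa`` may be
    ``"gc3s"`` (default) or ``"gc3"``.
    """
    if abscissa not in ("gc3s", "gc3"):
        raise ValueError(f"abscissa must be 'gc3s' or 'gc3', got {abscissa!r}")
    rows = []
    for prof, er in genes:
        if prof.gene_id != er.gene_id:
            raise ValueError(f"mismatched gene ids: {prof.gene_id} vs {er.gene_id}")
        s = getattr(prof, abscissa)
        expected = enc_expected(s) if not math.isnan(s) else math.nan
        dev = (expected - er.enc) / expected if expected and not math.isnan(er.enc) else math.nan
        rows.append(
            {
                "gene_id": prof.gene_id,
                abscissa: s,
                "enc": er.enc,
                "enc_expected": expected,
                "deviation": dev,
            }
        )
    df = pd.DataFrame(rows)
    dev = df["deviation"].to_numpy() if len(df) else np.array([])
    summary = {
        "n_below": int(np.sum(dev > deviation_threshold)),
        "n_near": int(np.sum(np.abs(dev) <= deviation_threshold)),
        "n_above": int(np.sum(dev < -deviation_threshold)),
    }
    return df, summary


@dataclass(frozen=True)
class Pr2Point:
    gene_id: str
    x: float  # G3 / (G3 + C3)
    y: float  # A3 / (A3 + T3)
    n_sites: int
    ok: bool = True


@lru_cache(maxsize=4)
def _fourfold_blocks(code: GeneticCode) -> tuple[str, ...]:
    """Codons of all four-fold degenerate blocks (shared first two bases with
    all four third bases present), including the 4-fold blocks of Leu, Ser
    and Arg."""
    by_prefix: dict[str, list[str]] = {}
    for c in code.sense_codons:
        by_prefix.setdefault(c[:2], []).append(c)
    out: list[str] = []
    for prefix, fam in sorted(by_prefix.items()):
        aas = {code.codon_to_aa[c] for c in fam}
        if len(fam) == 4 and len(aas) == 1:
            out.extend(sorted(fam))
    return tuple(out)


def pr2_point(
    counts: CodonCountTable,
    code: GeneticCode | None = None,
    site_set: str = "fourfold",
) -> Pr2Point:
    """PR2 coordinates for one gene.

    ``site_set="fourfold"`` (Sueoka's construction, default) tallies third
    bases over the eight four-fold degenerate blocks only; ``"all"`` uses
    every synonymous third position.  A zero denominator leaves that
    coordinate NaN and flags the point.
    """
    code = code or standard_code()
    if site_set == "fourfold":
        codons: Sequence[str] = _fourfold_blocks(code)
    elif site_set == "all":
        codons = code.synonymous_codons()
    else:
        raise ValueError(f"site_set must be 'fourfold' or 'all', got {site_set!r}")
    third = {b: 0 for b in "ACGT"}
    for c in codons:
        third[c[2]] += counts.counts[c]
    n_sites = sum(third.values())
    gc = third["G"] + third["C"]
    at = third["A"] + third["T"]
    x = third["G"] / gc if gc else math.nan
    y = third["A"] / at if at else math.nan
    return Pr2Point(
        gene_id=counts.gene_id,
        x=x,
        y=y,
        n_sites=n_sites,
        ok=bool(gc and at),
    )


@dataclass(frozen=True)
class NeutralityFit:
    slope: float
    intercept: float
    r2: float
    pearson_r: float
    p_value: float
    n_genes: int


def neutrality_fit(profiles: Iterable[CompositionProfile]) -> NeutralityFit:
    """OLS of GC12 on GC3 across genes (the neutrality plot regression)."""
    pts = [(p.gc3, p.gc12) for p in profiles if not (math.isnan(p.gc3) or math.isnan(p.gc12))]
    if len(pts) < 3:
        raise ValueError(f"neutrality fit needs at least 3 genes, got {len(pts)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: GC3 has zero variance")
    if np.ptp(y) == 0:
        # flat response: nothing to explain; report a null association
        return NeutralityFit(
            slope=0.0, intercept=float(y[0]), r2=0.0, pearson_r=0.0,
            p_value=1.0, n_genes=len(pts),
        )
    res = stats.linregress(x, y)
    return NeutralityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n_genes=len(pts),
    )


CORRELATION_INDICES = ("A3s", "T3s", "G3s", "C3s", "GC", "GC1", "GC2", "GC3s", "ENC")


@dataclass(frozen=True)
class CorrelationMatrix:
    labels: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame

    def starred(self, digits: int = 3) -> pd.DataFrame:
        """r rounded, annotated with * (p<0.05) / ** (p<0.01)."""
        out = pd.DataFrame(index=self.r.index, columns=self.r.columns, dtype=object)
        for i in self.labels:
            for j in self.labels:
                r = self.r.loc[i, j]
                if math.isnan(r):
                    out.loc[i, j] = "NA"
                    continue
                star = ""
                if i != j:
                    p = self.p.loc[i, j]
                    star = "**" if p < 0.01 else "*" if p < 0.05 else ""
                out.loc[i, j] = f"{r:.{digits}f}{star}"
        return out


def index_table(
    profiles: Iterable[CompositionProfile], enc_results: Iterable[EncResult]
) -> pd.DataFrame:
    """Per-gene table of the nine standard indices, keyed by gene_id."""
    enc_by_id = {e.gene_id: e.enc for e in enc_results}
    rows = []
    for p in profiles:
        rows.append(
            {
                "gene_id": p.gene_id,
                "A3s": p.a3s,
                "T3s": p.t3s,
                "G3s": p.g3s,
                "C3s": p.c3s,
                "GC": p.gc,
                "GC1": p.gc1,
                "GC2": p.gc2,
                "GC3": p.gc3,
                "GC12": p.gc12,
                "GC3s": p.gc3s,
                "ENC": enc_by_id.get(p.gene_id, math.nan),
            }
        )
    return pd.DataFrame(rows)


def correlation_matrix(
    table: pd.DataFrame, labels: Sequence[str] = CORRELATION_INDICES
) -> CorrelationMatrix:
    """Pairwise Pearson correlations with two-sided t-test p-values.

    Constant columns yield NaN for their off-diagonal entries (flagged by
    NaN rather than an arbitrary r).
    """
    labels = tuple(labels)
    n = len(table)
    if n < 3:
        raise ValueError(f"correlation matrix needs at least 3 genes, got {n}")
    r = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    p = pd.DataFrame(np.zeros((len(labels), len(labels))), index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            x = table[a].to_numpy(dtype=float)
            y = table[b].to_numpy(dtype=float)
            mask = ~(np.isnan(x) | np.isnan(y))
            if mask.sum() < 3 or np.ptp(x[mask]) == 0 or np.ptp(y[mask]) == 0:
                rv, pv = math.nan, math.nan
            else:
                rv, pv = stats.pearsonr(x[mask], y[mask])
            r.loc[a, b] = r.loc[b, a] = float(rv)
            p.loc[a, b] = p.loc[b, a] = float(pv)
    return CorrelationMatrix(labels=labels, r=r, p=p)
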