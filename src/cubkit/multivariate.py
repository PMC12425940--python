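"""PCA on the RSCU matrix.

The matrix is oriented with the 56 analysis-set codons as observations
(rows) and genes as variables (columns): the analysis reduces the gene
dimension and places codons in component space, so codon score plots can be
colored by third base.  Covariance PCA (column-mean centering, no scaling)
via SVD, with a deterministic sign convention so results are stable across
linear-algebra backends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .codon_stats import RscuVector
from .genetic_code import GeneticCode, standard_code, to_rna


@dataclass(frozen=True)
class RscuMatrix:
    """56-codon x n-gene RSCU matrix; ``mask`` marks entries imputed as 0
    because the amino acid was absent from that gene."""

    values: pd.DataFrame
    mask: pd.DataFrame

    @property
    def codons(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame  # codon x component
    loadings: pd.DataFrame  # gene x component
    explained_pct: np.ndarray
    cumulative_pct: np.ndarray


def build_rscu_matrix(
    genes: list[RscuVector], code: GeneticCode | None = None
) -> RscuMatrix:
    """Stack per-gene RSCU vectors into the analysis-set matrix.

    Undefined RSCU (amino acid absent from a gene) becomes 0 and is flagged
    in the mask; codon row labels use the RNA alphabet.
    """
    code = code or standard_code()
    if len(genes) < 2:
        raise ValueError(f"need at least 2 genes to build an RSCU matrix, got {len(genes)}")
    rows = [to_rna(c) for c in code.analysis_set]
    values = np.zeros((len(rows), len(genes)))
    mask = np.zeros_like(values, dtype=bool)
    for j, g in enumerate(genes):
        for i, c in enumerate(code.analysis_set):
            v = g.values[c]
            if math.isnan(v):
                mask[i, j] = True
            else:
                values[i, j] = v
    cols = [g.scope for g in genes]
    return RscuMatrix(
        values=pd.DataFrame(values, index=rows, columns=cols),
        mask=pd.DataFrame(mask, index=rows, columns=cols),
    )


def pca(matrix: RscuMatrix, n_components: int | None = None) -> PcaResult:
    """Covariance PCA of the RSCU matrix (codons as observations).

    All components up to the matrix rank are computed by default, so the
    explained percentages sum to 100.  The sign of each component is fixed
    by making its largest-magnitude codon score positive.
    """
    X = matrix.values.to_numpy(dtype=float)
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    max_comp = min(X.shape)
    if n_components is None:
        n_components = max_comp
    elif n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # gene x component

    for j in range(scores.shape[1]):
        # round magnitudes so exact mirror-pairs tie and the first index wins
        # deterministically regardless of float noise or column order
        i = int(np.argmax(np.round(np.abs(scores[:, j]), 9)))
        if scores[i, j] < 0:
            scores[:, j] *= -1
            loadings[:, j] *= -1

    explained = model.explained_variance_ratio_ * 100.0
    comp_labels = [f"PC{k + 1}" for k in range(scores.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.codons, columns=comp_labels),
        loadings=pd.DataFrame(loadings, index=matrix.gene_ids, columns=comp_labels),
        explained_pct=explained,
        cumulative_pct=np.cumsum(explained),
    )


def codon_ending_groups(codons: list[str]) -> dict[str, str]:
    """Classify codons by third base (RNA letter), for score-plot annotation."""
    out = {}
    for c in codons:
        c_rna = to_rna(c.upper())
        if len(c_rna) != 3 or any(b not in "ACGU" for b in c_rna):
            raise ValueError(f"not a valid codon: {c!r}")
        out[c] = c_rna[2]
    return out
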