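"""Independent brute-force oracles used to cross-check the package.

Each function recomputes a statistic from first principles (string walks,
Σ-formulas, direct eigendecomposition) without touching the implementation
paths under test.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import t as t_dist


def composition_oracle(seq: str, code) -> dict[str, float]:
    """Per-nucleotide tally over a raw stop-free CDS string."""
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    codons = [c for c in codons if c not in code.stop_codons]
    n = len(codons)

    def frac_gc(pos):
        return sum(1 for c in codons if c[pos] in "GC") / n

    gc1, gc2, gc3 = frac_gc(0), frac_gc(1), frac_gc(2)
    nt = "".join(codons)
    gc = sum(1 for b in nt if b in "GC") / len(nt)

    syn = [c for c in codons if code.degeneracy[code.codon_to_aa[c]] >= 2]
    gc3s = sum(1 for c in syn if c[2] in "GC") / len(syn) if syn else math.nan

    x3s = {}
    for base in "ACGT":
        able = {
            aa
            for aa, fam in code.families.items()
            if code.degeneracy[aa] >= 2 and any(c[2] == base for c in fam)
        }
        denom = [c for c in syn if code.codon_to_aa[c] in able]
        num = sum(1 for c in syn if c[2] == base)
        x3s[base] = num / len(denom) if denom else math.nan
    return {
        "gc": gc, "gc1": gc1, "gc2": gc2, "gc3": gc3, "gc12": (gc1 + gc2) / 2,
        "gc3s": gc3s, "a3s": x3s["A"], "t3s": x3s["T"], "g3s": x3s["G"],
        "c3s": x3s["C"],
    }


def rscu_oracle(counts: dict[str, int], code) -> dict[str, float]:
    out = {}
    for aa, fam in code.families.items():
        n_a = sum(counts.get(c, 0) for c in fam)
        for c in fam:
            out[c] = len(fam) * counts.get(c, 0) / n_a if n_a else math.nan
    return out


def enc_oracle(counts: dict[str, int], code) -> float:
    """Spreadsheet-style evaluation of Wright's estimator (joint 6-fold,
    Ile imputation as the 2-/4-fold mean, [20, 61] cap)."""
    per_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, fam in code.families.items():
        k = code.degeneracy[aa]
        if k < 2:
            continue
        ns = [counts.get(c, 0) for c in fam]
        n = sum(ns)
        if n < 2:
            continue
        f = (n * sum((x / n) ** 2 for x in ns) - 1) / (n - 1)
        if f > 0:
            per_class[k].append(f)
    fbar = {k: (np.mean(v) if v else math.nan) for k, v in per_class.items()}
    if math.isnan(fbar[3]) and not (math.isnan(fbar[2]) or math.isnan(fbar[4])):
        fbar[3] = (fbar[2] + fbar[4]) / 2
    if any(math.isnan(fbar[k]) for k in (2, 3, 4, 6)):
        return math.nan
    nc = 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6]
    return min(61.0, max(20.0, nc))


def pr2_oracle(seq: str, code) -> tuple[float, float]:
    """String-walk A3/T3/G3/C3 over four-fold degenerate blocks."""
    fourfold_prefixes = set()
    by_prefix: dict[str, set[str]] = {}
    for c in code.sense_codons:
        by_prefix.setdefault(c[:2], set()).add(code.codon_to_aa[c])
    for prefix, aas in by_prefix.items():
        block = [prefix + b for b in "ACGT"]
        if len(aas) == 1 and all(c not in code.stop_codons for c in block):
            fourfold_prefixes.add(prefix)
    tallies = {b: 0 for b in "ACGT"}
    for i in range(0, len(seq), 3):
        c = seq[i : i + 3]
        if c[:2] in fourfold_prefixes and c not in code.stop_codons:
            tallies[c[2]] += 1
    gc = tallies["G"] + tallies["C"]
    at = tallies["A"] + tallies["T"]
    return (
        tallies["G"] / gc if gc else math.nan,
        tallies["A"] / at if at else math.nan,
    )


def ols_oracle(x, y) -> tuple[float, float, float]:
    """(slope, intercept, r2) by the Σ-formulas."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sxy = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    sxx = n * np.sum(x * x) - np.sum(x) ** 2
    syy = n * np.sum(y * y) - np.sum(y) ** 2
    slope = sxy / sxx
    intercept = (np.sum(y) - slope * np.sum(x)) / n
    r2 = sxy**2 / (sxx * syy)
    return float(slope), float(intercept), float(r2)


def pearson_oracle(x, y) -> tuple[float, float]:
    """(r, two-sided p) by the Σ-formula and the exact t transformation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    den = math.sqrt(
        (n * np.sum(x * x) - np.sum(x) ** 2) * (n * np.sum(y * y) - np.sum(y) ** 2)
    )
    r = num / den
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * t_dist.sf(abs(t), n - 2)
    return float(r), float(p)


def pca_eigen_oracle(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(eigenvalues desc, |scores|) from direct covariance eigendecomposition
    of the column-centered matrix (rows are observations)."""
    Xc = X - X.mean(axis=0, keepdims=True)
    C = Xc.T @ Xc / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    scores = Xc @ vecs[:, order]
    return vals, np.abs(scores)
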