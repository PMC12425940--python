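"""End-to-end pipeline: validate -> count -> indices -> diagnostics -> PCA
-> optimal codons, emitting a bundle of plot-ready TSV tables.

Output dialect: tab-separated, '.' decimal, codons in the RNA alphabet.
Report tables round floats to 3 decimals; each also gets a full-precision
``*_full.tsv`` twin.  Per-gene rejections never abort a run; a run manifest
records every threshold and dialect switch that affects any number.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .codon_stats import enc, high_frequency_codons, pooled_rscu, rscu
from .composition import composition_profile
from .diagnostics import (
    correlation_matrix,
    enc_plot_table,
    index_table,
    neutrality_fit,
    pr2_point,
)
from .genetic_code import standard_code, to_rna
from .multivariate import build_rscu_matrix, codon_ending_groups, pca
from .optimal_codons import delta_rscu_table, extreme_groups
from .seqio import (
    ValidationPolicy,
    count_codons,
    read_cds_fasta,
    validate_batch,
    write_rejections_tsv,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Fatal pipeline failure (e.g. no valid genes survive screening)."""


@dataclass(frozen=True)
class PipelineConfig:
    input: str
    outdir: str
    policy: ValidationPolicy = field(default_factory=ValidationPolicy)
    x3s_dialect: str = "codonw"
    pr2_site_set: str = "fourfold"
    enc_sixfold: str = "joint"
    enc_plot_abscissa: str = "gc3s"
    extreme_fraction: float = 0.10
    delta_threshold: float = 0.08
    rscu_threshold: float = 1.0
    deviation_threshold: float = 0.1
    plots: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("extreme_fraction", "delta_threshold", "rscu_threshold", "deviation_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _write(df: pd.DataFrame, path: Path, full: bool = True) -> None:
    """Write a 3-decimal report TSV and a full-precision twin."""
    rounded = df.copy()
    for col in rounded.columns:
        if pd.api.types.is_float_dtype(rounded[col]):
            rounded[col] = rounded[col].round(3)
    rounded.to_csv(path, sep="\t", index=False)
    if full:
        df.to_csv(path.with_name(path.stem + "_full.tsv"), sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full analysis; returns the map of artifact names to paths."""
    code = standard_code()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records = read_cds_fasta(config.input)
    accepted, rejected = validate_batch(records, config.policy, code)
    write_rejections_tsv(rejected, outdir / "rejects.tsv")
    if not accepted:
        raise PipelineError(f"no valid genes in {config.input} ({len(rejected)} rejected)")
    logger.info("accepted %d genes, rejected %d", len(accepted), len(rejected))

    tables = {v.gene_id: count_codons(v) for v in accepted}
    profiles = [
        composition_profile(t, code, x3s_dialect=config.x3s_dialect)
        for t in tables.values()
    ]
    enc_results = [
        enc(t, code, sixfold=config.enc_sixfold) for t in tables.values()
    ]
    gene_rscu = [rscu(t, code) for t in tables.values()]
    pooled = pooled_rscu(tables.values(), code, label="all_genes")

    # composition.tsv — one row per gene, the box-plot-ready index table
    comp = pd.DataFrame(
        [
            {
                "gene_id": p.gene_id,
                "A3s": p.a3s, "T3s": p.t3s, "G3s": p.g3s, "C3s": p.c3s,
                "GC": p.gc, "GC1": p.gc1, "GC2": p.gc2, "GC3": p.gc3,
                "GC12": p.gc12, "GC3s": p.gc3s,
            }
            for p in profiles
        ]
    )
    _write(comp, outdir / "composition.tsv")

    hf = high_frequency_codons(pooled, code)
    pooled_df = pd.DataFrame(
        [
            {
                "amino_acid": code.codon_to_aa[c],
                "codon": to_rna(c),
                "count": sum(t.counts[c] for t in tables.values()),
                "rscu": pooled.values[c],
                "high_frequency": c in hf,
            }
            for c in code.analysis_set
        ]
    ).sort_values(["amino_acid", "codon"], ignore_index=True)
    _write(pooled_df, outdir / "rscu_pooled.tsv")

    enc_df = pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "ENC": e.enc,
                "capped": e.capped,
                "imputed_classes": ",".join(map(str, sorted(e.imputed_classes))),
                "ok": e.ok,
            }
            for e in enc_results
        ]
    )
    _write(enc_df, outdir / "enc.tsv")

    plot_df, plot_summary = enc_plot_table(
        zip(profiles, enc_results),
        abscissa=config.enc_plot_abscissa,
        deviation_threshold=config.deviation_threshold,
    )
    _write(plot_df, outdir / "enc_plot.tsv")

    pr2 = pd.DataFrame(
        [
            {"gene_id": p.gene_id, "g3_over_gc3": p.x, "a3_over_at3": p.y,
             "n_sites": p.n_sites, "ok": p.ok}
            for p in (
                pr2_point(t, code, site_set=config.pr2_site_set)
                for t in tables.values()
            )
        ]
    )
    _write(pr2, outdir / "pr2.tsv")

    fit = neutrality_fit(profiles)
    neut = pd.DataFrame(
        [
            {
                "slope": fit.slope, "intercept": fit.intercept, "r2": fit.r2,
                "pearson_r": fit.pearson_r, "p_value": fit.p_value,
                "n_genes": fit.n_genes,
            }
        ]
    )
    _write(neut, outdir / "neutrality.tsv")

    idx = index_table(profiles, enc_results)
    corr = correlation_matrix(idx)
    starred = corr.starred().reset_index(names="index")
    starred.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
    long = corr.r.stack().rename("r").to_frame()
    long["p"] = corr.p.stack()
    long.index.names = ["index_a", "index_b"]
    _write(long.reset_index(), outdir / "correlations_long.tsv")

    matrix = build_rscu_matrix(gene_rscu, code)
    pca_res = pca(matrix)
    n_scree = min(20, len(pca_res.explained_pct))
    scree = pd.DataFrame(
        {
            "component": range(1, n_scree + 1),
            "explained_pct": pca_res.explained_pct[:n_scree],
            "cumulative_pct": pca_res.cumulative_pct[:n_scree],
        }
    )
    _write(scree, outdir / "scree.tsv")
    endings = codon_ending_groups(matrix.codons)
    scores = pca_res.scores[["PC1", "PC2"]].copy()
    scores.insert(0, "codon", scores.index)
    scores["third_base"] = [endings[c] for c in scores["codon"]]
    _write(scores.reset_index(drop=True), outdir / "scores.tsv")

    groups = extreme_groups(enc_results, fraction=config.extreme_fraction)
    delta = delta_rscu_table(
        groups,
        tables,
        pooled,
        code,
        delta_threshold=config.delta_threshold,
        rscu_threshold=config.rscu_threshold,
    )
    _write(delta, outdir / "optimal_codons.tsv")

    if config.plots:
        _quicklook_plots(outdir, plot_df, pr2, idx, fit, scree, scores, config)

    manifest = {
        "cubkit_version": __version__,
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "policy"},
            "policy": asdict(config.policy),
        },
        "n_genes_accepted": len(accepted),
        "n_genes_rejected": len(rejected),
        "enc_plot_summary": plot_summary,
        "extreme_group_size": groups.group_size,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    artifacts = [
        "composition.tsv", "rscu_pooled.tsv", "enc.tsv", "enc_plot.tsv",
        "pr2.tsv", "neutrality.tsv", "correlations.tsv", "correlations_long.tsv",
        "scree.tsv", "scores.tsv", "optimal_codons.tsv", "rejects.tsv",
        "manifest.yaml",
    ]
    return {name: outdir / name for name in artifacts}


def _quicklook_plots(outdir, plot_df, pr2, idx, fit, scree, scores, config):
    """Scatter + curve/regression quick-look figures (not publication grade)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    from .diagnostics import enc_expected

    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    ax = axes[0, 0]
    s = np.linspace(0, 1, 201)
    ax.plot(s, [enc_expected(v) for v in s], "k-", lw=1)
    ax.scatter(plot_df[config.enc_plot_abscissa], plot_df["enc"], s=8)
    ax.set(xlabel=config.enc_plot_abscissa.upper(), ylabel="ENC", title="ENC-plot")

    ax = axes[0, 1]
    ax.scatter(pr2["g3_over_gc3"], pr2["a3_over_at3"], s=8)
    ax.axhline(0.5, color="k", lw=0.5)
    ax.axvline(0.5, color="k", lw=0.5)
    ax.set(xlabel="G3/(G3+C3)", ylabel="A3/(A3+T3)", title="PR2 bias")

    ax = axes[1, 0]
    ax.scatter(idx["GC3"], idx["GC12"], s=8)
    xs = np.linspace(idx["GC3"].min(), idx["GC3"].max(), 2)
    ax.plot(xs, fit.intercept + fit.slope * xs, "r-")
    ax.set(xlabel="GC3", ylabel="GC12",
           title=f"Neutrality (slope={fit.slope:.3f}, R2={fit.r2:.3f})")

    ax = axes[1, 1]
    markers = {"A": "s", "U": "^", "G": "*", "C": "o"}
    for base, mk in markers.items():
        sub = scores[scores["third_base"] == base]
        ax.scatter(sub["PC1"], sub["PC2"], marker=mk, label=base, s=18)
    ax.legend(title="3rd base", fontsize=8)
    ax.set(xlabel="PC1", ylabel="PC2", title="Codon scores")

    fig.tight_layout()
    fig.savefig(outdir / "quicklook.png", dpi=120)
    plt.close(fig)
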