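# cubkit

Codon usage bias (CUB) analysis for coding-sequence sets — built for gene-family
studies such as plant transcription-factor families, where the question is
whether synonymous codon choice is shaped mainly by mutational GC pressure or
by translational selection.

Synonymous codons are not used interchangeably: genomes, and gene families
within them, prefer some codons over their synonyms. `cubkit` takes a
multi-FASTA of coding sequences (CDS) and computes the standard battery of
CUB statistics, the classic mutation-versus-selection diagnostics, and the
ΔRSCU optimal-codon classification, emitting plot-ready TSV tables.

## What it computes

* **Composition indices** per gene: GC, GC1/GC2/GC3 (by codon position),
  GC12 = (GC1+GC2)/2, GC3s (synonymous third positions only), and
  A3s/T3s/G3s/C3s in the CodonW convention.
* **RSCU** (relative synonymous codon usage), per gene and pooled over a
  group: for codon *c* of an amino acid with family count *n_a* and
  degeneracy *k_a*,
  `RSCU(c) = k_a · n_c / n_a`,
  so uniform usage gives 1 and family values sum to *k_a*. Codons with
  pooled RSCU > 1 are the *high-frequency* codons.
* **Wright's effective number of codons (ENC/Nc)** from per-family codon
  homozygosities `F̂ = (n Σ p̂ᵢ² − 1)/(n − 1)`, combined as
  `Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆` and capped into [20, 61]
  (20 = one codon per amino acid, 61 = no bias).
* **Diagnostics**: the ENC-plot against the composition-only expectation
  `Nc* = 2 + s + 29/(s² + (1−s)²)`; the PR2 bias plot
  (A3/(A3+T3) vs G3/(G3+C3) at four-fold degenerate sites); the neutrality
  regression of GC12 on GC3; and the Pearson correlation matrix of the
  per-gene indices with significance stars.
* **PCA on the RSCU matrix** (56 analysis-set codons × genes; covariance
  PCA, codons as observations) with scree and codon-score tables annotated
  by third base.
* **Optimal codons by ΔRSCU**: genes are ranked by ENC, the lowest- and
  highest-ENC 10% tails are pooled, and a codon is *optimal* when its
  ΔRSCU = RSCU(low-ENC group) − RSCU(high-ENC group) ≥ 0.08 **and** its
  pooled RSCU over all genes exceeds 1.
* **Synthetic CDS generator** with per-gene mutational GC pressure,
  selection strength toward a preferred-codon set, and a GC12–GC3 coupling,
  so every stage can be exercised against known ground truth.

## Worked example

Simulate a 151-gene CDS set under mixed mutation/selection conditions and
run the full pipeline:

```bash
cub simulate -o demo --seed 42
cub run -i demo/synthetic.fasta -o demo/out
```

The run accepts all 151 genes and writes 13 artifacts. For this seed the
set has mean GC 0.597 and mean GC3s 0.681, with per-gene ENC spanning
30.83–61.00 — a GC-rich, weakly-to-moderately biased family. The neutrality
regression (`demo/out/neutrality.tsv`):

```
slope   intercept  r2     pearson_r  p_value  n_genes
0.606   0.13       0.692  0.832      0.0      151
```

A slope of 0.606 means GC12 tracks GC3 strongly across genes — the
signature of gene-to-gene variation in mutational GC pressure — while the
gap from 1 leaves room for selection; genes with large positive `deviation`
in `demo/out/enc_plot.tsv` sit below the composition-only ENC curve, the
selection signature. The first PCA axis dominates the RSCU matrix
(`demo/out/scree.tsv` starts `60.986, 5.9, 2.647, ...` percent).

The ΔRSCU classifier can also run directly from a published group-RSCU
table. With the bundled reference table for a 151-member banana WRKY
transcription-factor CDS set:

```bash
$ cub optimal
15 optimal codons: GCC, GAG, UUC, GGC, CAC, CUC, CUG, AAC, CCG, CAG, AGC, UCC, ACC, GUG, UAC
```

All 15 end in G or C, as expected for a GC3-rich monocot gene family.

## Layout

| module | contents |
| --- | --- |
| `cubkit.seqio` | FASTA reading, CDS validation policies, codon counting |
| `cubkit.genetic_code` | standard code, degeneracy classes, 56-codon analysis set |
| `cubkit.composition` | GC/GC1/GC2/GC3/GC12/GC3s and X3s indices |
| `cubkit.codon_stats` | RSCU, pooled RSCU, high-frequency codons, ENC |
| `cubkit.diagnostics` | ENC-plot, PR2, neutrality fit, correlation matrix |
| `cubkit.multivariate` | RSCU matrix and PCA |
| `cubkit.optimal_codons` | extreme groups, ΔRSCU table, optimal set |
| `cubkit.synthetic_data` | seeded CDS generator with ground truth |
| `cubkit.pipeline` / `cubkit.cli` | orchestration and the `cub` command |

See `docs/methods.md` for the statistical details, parameter defaults and
known limitations.
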