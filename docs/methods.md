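# Methods

This note records the statistical definitions `cubkit` implements, the
defaults and dialect switches that affect its numbers, what the synthetic
generator does and does not emulate, and the design choices made where the
conventions in the field genuinely diverge.

## Sequence screening

A CDS enters the analysis only if it is at least 300 nt (configurable), a
multiple of 3 (or trimmed, under the `trim` policy), and free of internal
stop codons (or masked, under the `mask` policy). The 300 nt floor keeps
per-gene indices — ENC above all — away from their worst small-sample
behaviour. A terminal stop codon is recorded but never counted; ambiguity
codes (N, R, Y, …) invalidate only the containing codon, with the skip count
reported for QC. Sequences are stored as DNA; all report tables print codons
in the RNA alphabet, matching how codon-usage tables are conventionally
published. The genetic code is fixed to the standard nuclear table
(translation table 1): the target data are nuclear plant CDS, and no other
table is exposed in this version.

## Composition indices

GC1/GC2/GC3 are computed over all sense codons; the aggregate GC weights the
three positions equally (equivalently, per-nucleotide GC of the stop-stripped
CDS). GC12 = (GC1+GC2)/2 exactly. GC3s is restricted to codons of amino
acids with at least two synonymous codons (Met, Trp and stops excluded; Ile
included). GC3 and GC3s are deliberately kept as separate quantities and
never aliased: the neutrality plot uses GC3, the ENC-plot GC3s by default,
and both are available because usage in the literature is inconsistent.

X3s follows the CodonW convention: the numerator counts synonymous codons
ending in base *x*; the denominator counts synonymous codons of amino acids
that *can* end in *x*. The four denominators differ, so A3s+T3s+G3s+C3s ≠ 1
in general (it equals 1 exactly when every amino acid present is four-fold
degenerate). A `strict` dialect with a single shared denominator (all
synonymous codons) is provided as a config switch, because tools differ and
the convention is rarely stated in papers.

## ENC

Wright's original estimator. Per amino acid with usage n ≥ 2, the codon
homozygosity is F̂ = (n Σ p̂ᵢ² − 1)/(n − 1). Class means F̄ₖ average F̂
within each degeneracy class (k = 2, 3, 4, 6) over amino acids with n ≥ 2
and F̂ > 0; then Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆. Numerical rules:

* Amino acids seen once contribute nothing (the bias correction divides by
  n − 1); families with F̂ = 0 are dropped from their class mean because a
  zero homozygosity cannot enter a harmonic term.
* If the 3-fold class (isoleucine alone) is unobservable, F̄₃ is imputed as
  the mean of F̄₂ and F̄₄, and the imputation is recorded per gene. If the
  2-, 4- or 6-fold class is unobservable the result is undefined and QC
  flagged — never silently imputed.
* The raw value is capped into [20, 61] and the cap is flagged. Finite
  samples push the raw estimator above 61 for near-uniform usage (F̂ is
  unbiased but 1/F̄ is convex), so an uncapped maximum would exceed the
  no-bias ceiling.
* A `split` dialect divides the three 6-fold families (Leu, Ser, Arg) into
  their 4-fold block and 2-fold remainder, as some tools do; the default
  keeps them joint.

The ENC-plot null curve is Nc* = 2 + s + 29/(s² + (1−s)²) with s = GC3s,
the standard composition-only expectation. The relative deviation
(Nc* − Nc)/Nc* is reported per gene; "noticeably below the curve" is
quantified by a configurable threshold, default 0.1, because no numeric
convention exists in the literature.

## PR2 and the neutrality fit

The PR2 point is A3/(A3+T3) against G3/(G3+C3) tallied over the third
positions of the eight four-fold degenerate codon blocks (Val, Pro, Thr,
Ala, Gly plus the four-fold blocks of Leu, Ser, Arg) — Sueoka's
construction, under which a gene with no strand or selective asymmetry sits
at (0.5, 0.5). An `all` dialect tallies every synonymous third position
instead. Zero denominators leave the coordinate NaN with a QC flag.

The neutrality fit is ordinary least squares of GC12 on GC3 across genes
(scipy's linregress), reporting slope, intercept, R², Pearson r and the
two-sided p. Degenerate inputs are errors (fewer than 3 genes, or zero
variance in GC3); a zero-variance *response* returns a null fit (slope 0,
R² 0) rather than NaN, since there is nothing to explain. Correlation
p-values use the exact t transformation with n − 2 degrees of freedom, with
`*`/`**` stars at 0.05/0.01.

## PCA on RSCU

The RSCU matrix is 56 analysis-set codons × genes; the analysis set drops
the initiation codon AUG, tryptophan's UGG, the three isoleucine codons and
the three stops. Missing families (amino acid absent from a gene) are
imputed as 0 and masked. PCA is covariance-based (column-mean centered, no
scaling) via SVD, with codons as observations, so codon scores can be
plotted by third base; all components up to rank are computed and the scree
table prints the first 20. The sign of each component is fixed by making
the largest-magnitude codon score positive, with magnitudes rounded to 9
decimals first so exact mirror pairs tie deterministically — this keeps
snapshots stable across linear-algebra backends and column orders.
Correspondence analysis, the older tradition in codon-usage work, is out of
scope here; the orientation with genes as observations is available as the
transpose but is not the default.

## Optimal codons

Genes are sorted by ENC (ascending, gene id as tie-break); the first and
last floor(0.10 · n) genes (minimum 1, error if the groups would overlap)
form the low-ENC ("high expression") and high-ENC ("low expression")
groups. Group RSCUs are computed from summed counts, not means of per-gene
RSCU: pooling keeps each family's RSCU sum exactly equal to its degeneracy,
and hence each family's ΔRSCU sum exactly 0 — an identity the tests assert
at 1e-9. A codon is highly expressed when ΔRSCU = RSCU_high − RSCU_low ≥
0.08, high frequency when its pooled RSCU over all genes exceeds 1
(strict), and optimal when both hold. All three thresholds are config keys.

The classifier also ingests an externally supplied group-RSCU table plus a
high-frequency list (`cub optimal --from-table …`), so published tables can
be re-classified without sequences. The bundled reference table for the
151-gene banana WRKY family reproduces its published 15-codon optimal set
exactly. Note that printed tables rounded to 2 decimals do not satisfy the
family-balance identity (and the bundled table contains two family columns
whose printed values are internally inconsistent beyond rounding); the
identity is therefore asserted only on tables computed from counts.

## Synthetic data

The generator emulates the minimal statistical structure the diagnostics
respond to, with ground truth recorded per gene:

* **Mutation kernel.** Within each synonymous family a codon's weight is g
  for a G/C third base and 1 − g for A/T, normalized. In the infinite-gene
  limit this is exactly the model behind Wright's expected curve, so
  mutation-only genes straddle the ENC-plot curve, and the kernel weights G
  and C identically, so PR2 stays centered at (0.5, 0.5).
* **Selection.** With probability w a site's codon is drawn uniformly from
  the preferred set of its amino acid (default: one or two G/C-ending
  codons per amino acid, as typical for monocots). This concentrates usage,
  pulls ENC below the curve, and displaces PR2 where the preferred set is
  G/C-asymmetric.
* **Coupling.** In mutation and mixed modes, amino-acid choice is tilted by
  exp(c · (2·GC12(aa) − 1)(2g − 1)) with c = 1.5, so GC12 co-varies with
  GC3 across genes and the neutrality slope is recoverable (≈ 0.6 at the
  defaults); selection mode sets c = 0, giving a flat slope.

Defaults: 151 genes; codon counts log-normal (median 350, σ = 0.35, floor
100 codons, i.e. ≥ 300 nt); per-gene g ~ Beta(9.9, 6.1) (mean ≈ 0.62,
matching the GC3s level typical of the target family); mixed-mode
w ~ Beta(1.5, 6). With these settings a default set lands near mean GC 0.60,
mean GC3s 0.68 and ENC spanning roughly 31–61. The GC3s mean sits slightly
above the mutational mean because G/C-directed selection adds to it; with a
G/C-preferring optimal set it is not possible to hold both the mutational
pressure and the realized GC3s at 0.62, and the pressure distribution is the
quantity fixed by design. Every gene draws from an independent substream
keyed on (seed, gene index): the same seed is byte-identical, and extending
the gene count never changes earlier genes.

What the generator does *not* emulate: phylogenetic correlation between
genes, indels or misannotation, amino-acid composition differences between
real gene families, codon autocorrelation along a sequence, and expression
levels (selection strength is assigned, not derived from expression). Tests
passing on synthetic data therefore validate the statistics and their
interplay, not any claim about a particular real genome.

## Problem sizes in the test-suite and acceptance checks

Oracle-equivalence checks run on 20+ random codon tables (~1,500 codons
each) against independent string-walk and Σ-formula implementations.
Parameter-recovery checks use 20 replicates × 151 genes (~130 codons per
gene) per mode, comparing replicate neutrality slopes and mean ENC-plot
deviations by one-sided t-tests at α = 0.01; these sizes give clear
separation (selection-mode slopes ≈ 0.06 ± 0.08 vs mutation-mode ≈ 0.63 ±
0.03) while keeping the whole suite fast.

## Known limitations

* The ENC missing-class behaviour of legacy tools is not fully documented;
  genes missing an entire 2-/4-/6-fold class are flagged undefined here,
  which may differ from tools that silently extrapolate.
* The X3s convention, PR2 site set, ENC-plot abscissa (GC3 vs GC3s) and
  6-fold handling all vary across published tools; the defaults follow the
  dominant CodonW-style conventions and every switch is recorded in the run
  manifest, but numerical agreement with any specific legacy binary is not
  guaranteed.
* RSCU for absent amino-acid families is undefined (NaN), imputed as masked
  zeros only inside the PCA matrix; downstream consumers should respect the
  mask for genes with unusual amino-acid usage.
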