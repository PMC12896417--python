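# Methods

## Model of the data

Two sublines of *M. lignano* differ in subgenome copy number: the
reference karyotype carries (S, L1, L2) = (2, 1, 1) chromosome-copy
equivalents, the alternative (2, 2, 2). With equal subgenome sizes the
genome-size ratio is G = 6/4 = 1.5. Sequencing is modelled as
*fixed-total-reads* (compositional) sampling: a library of total depth N
allocates to gene g an expected count

* WGS: `N · ℓ_g c_g κ_g ε_g / Z`, with ℓ the counting-window length,
  c the copy number in that subline, κ ≥ 1 a reference-collapse
  multiplier (identical in both sublines), ε a WGS capture efficiency,
  and Z the sum of the numerator over genes;
* RNA: `N · q_g c_g m_g κ_g / Z′`, with q the per-copy transcription rate
  and m a regulatory multiplier (m = 1 ⇔ dosage-proportional).

Counts are negative binomial with variance μ + αμ². This compositional
construction is what makes dosage normalization non-trivial: no single
library carries absolute copy-number information, only relative shares.

Because the three subgenomes descend from one ancestral gene complement,
the generator draws one length and one rate per ancestral locus and
shares them across the three homeologs. This enforces equal subgenome
sizes — the geometry behind G = 1.5 and the theoretical coverage ratios —
rather than leaving them to sampling noise. Scaffolds belong entirely to
one subgenome, so nearest-neighbour imputation stays within a subgenome,
as it does on real subgenome-resolved scaffolds.

### Generator defaults and what they emulate

| parameter | default | rationale |
|---|---|---|
| genes | 666/667/667 per subgenome | ~2000 genes; equal subgenome shares |
| WGS libraries | 6 per subline | three pools × two replicate libraries |
| RNA libraries | 3 per subline | three biological replicates |
| depth scalars | evenly spaced 0.9–1.1 | exercises depth normalization; identical between sublines so neither subline is systematically deeper |
| reads/library | 2 × 10⁶ | hundreds of counts per gene — bulk-like depth |
| α (RNA) | 0.05 | biological replication of pooled worms |
| α (WGS) | 0.002 | replicate libraries from the *same* DNA pools: technical, near-Poisson. A biological-scale α here would be physically wrong (DNA copy number does not fluctuate between aliquots) and would make per-gene coverage ratios uninformative at 6 libraries |
| trans-DE fraction | 5%, |log2 m-ratio| = 2 | minority of genuine 4-fold regulatory responses, sign random |
| compensated fraction | 5% of L genes, m_alt = 1/2 | total output invariant to the copy doubling |
| collapse fraction | 5%, κ = 2 | collapsed haplovariants double apparent coverage in both assays and sublines |
| low-coverage fraction | 2%, ε = 0.005 | triggers nearest-gene imputation |
| gene length | log-uniform 500–30000 bp | brackets the 10 kb expansion rule from both sides |

Special-gene fractions are capped at 20% in total so that median-based
estimators anchor on the dosage-proportional majority — the same
robustness assumption ordinary median-of-ratios normalization makes.

What the generator does **not** emulate: read-level artifacts (mapping
ambiguity, GC bias), isoforms and splice variation, correlated
library-preparation effects, and any structure in which genes within a
scaffold share fates. Passing tests therefore demonstrate the *logic* of
the pipeline under its stated model, not robustness to every failure mode
of real sequencing.

## WGS normalization and coverage ratios

Counts are taken over the gene body, expanded symmetrically to ≥ 10 kb
(clipped at scaffold edges, shifting to preserve the window where the
scaffold allows); the expansion is essential for low-pass WGS — without
it sub-kilobase genes have too few reads for a usable per-gene ratio.

Size factors are median-of-ratios (per-library median of count /
geometric-mean-reference, zero-containing genes excluded from the
reference). Factors are *share-anchored*: multiplied by the geometric
mean over libraries of (total counts / factor), so normalized values are
per-read shares. This makes normalized coverage exactly invariant to
rescaling any single library's counts; without the anchoring, a
per-subline median-of-ratios pins each subline to its own geometric-mean
depth and the cross-subline ratio inherits any depth imbalance.

Two modes are kept deliberately distinct, because the two theoretical
expectations quoted for this design (S at 1.5, L at 1.0) are attainable
only under different anchorings:

* `per_subline_independent` — factors within each subline. Theoretical
  cr (reference/alternative): S = 1.5, L = 0.75. Used for subgenome
  assignment; the default thresholds 1.375/1.125 are midpoints-with-buffer
  on this scale.
* `L_anchored` — factors recomputed across **all** libraries using only
  the L1/L2 anchor set (found by a deterministic 1-D two-means split of
  log cr, initialized at the 25th/75th percentiles; the two modes must
  differ by ≥ 1.5-fold or the input is rejected as unimodal). Theoretical
  cr: L = 1.0, S = 2.0. This is the scale of the dosage-factor matrix and
  of the threshold sensitivity scan, whose scanned range [1.30, 1.50]
  then sits strictly between the two clusters — which is why the
  classification is stable across the whole grid. On the independent
  scale the stringent endpoint 1.50 would sit *on* the S mode and any
  scan through it would be unstable by construction.

Genes whose total WGS count falls below 10 × (number of libraries) — or
with zero denominator coverage — are flagged low-coverage; their cr and
dosage row are copied from the nearest covered gene on the same scaffold
(midpoint distance, ties to the upstream neighbour). A gene with no
eligible neighbour keeps cr undefined (assigned NA) and a neutral
all-ones dosage row.

## The dosage-factor matrix and combined offsets

Each gene's mean L-anchored coverage per subline is broadcast to that
subline's RNA libraries and the row is centred to geometric mean 1:
`w_gj` encodes *relative* dosage only (S rows contrast √2 : 1/√2, L rows
1 : 1), leaving library depth to the size factors. Centring also removes
any gene-constant scale — collapse artifacts drop out here.

RNA size factors are median-of-ratios on `counts / w` and the model
offsets are `f_gj = s_j · w_gj` (the DESeq2 `normMatrix` convention).
Dividing out w first matters: the raw-count ratio distribution is a
mixture (S and L genes sit √2 apart within each library), so its pooled
median falls at an off-centre quantile of the majority cluster and would
bias every fold change by ~0.2–0.4 log2 units at α = 0.05; after dividing
by w the distribution is unimodal and the median unbiased. The ablation
(`use_dosage=False`) keeps this size-factor vector and removes only the
gene-level term, isolating exactly what the dosage matrix contributes.

## Dispersion and testing

Genes with mean raw count < 10 in **both** sublines are excluded
(strictly-less; one passing group keeps the gene).

Per-gene dispersion: Cox–Reid-adjusted NB profile likelihood, maximized
on an 81-point log grid over [10⁻⁶, 10] with one parabolic refinement
(group means profiled out as Σcounts/Σfactors; adjustment
−½ log det X'WX). A mean–dispersion trend α(μ) = a0 + a1/μ is fit
gamma-GLM-style on the natural scale — the adjusted MLE is nearly
unbiased in arithmetic mean but not in log-median, so a log-scale fit
would underestimate the trend by ~20% at n = 6 and inflate every Wald
statistic by ~10%. Gene-wise estimates are then squeezed toward the trend
on the log scale with an empirical-Bayes weight τ²/(τ² + V_g): V_g is
the delta-method sampling variance of the log estimate,
(2/d)(1 + ξ/(αμ))², and τ² the excess of the observed residual spread
(robust MAD²) over its median — zero when dispersions are homogeneous, so
the estimate collapses to the trend exactly when gene-wise values carry
no signal. Boundary/uninformative genes take the trend; everything is
floored at 10⁻⁸.

The GLM `log μ = log f + β0 + β1·x` is fit by IRLS, vectorized across
genes with closed-form 2×2 weighted-least-squares updates (tolerance
10⁻¹⁰, 100 iterations, steps clamped to keep the linear predictor in
range; expected information at the final coefficients gives the SE). A
gene with zero total count in either group has its MLE at infinity and is
reported NaN, excluded from multiple testing. p-values are two-sided
normal on β1/SE; BH adjustment over the tested genes; DEGs are
padj < 0.05 and |log2FC| > log2 1.5 on the unshrunken estimate (no LFC
shrinkage anywhere, so the FC screen is applied to the raw Wald
estimate), classified by the subgenome assignment.

## Auxiliary statistics

* **ddPCR correction** for comparing absolute transcript concentrations
  against per-transcriptome fold changes: multiply the aneuploid
  measurement by `G / (c_alt/c_ref)` — ×1.5 for an S target (copy ratio
  1), ×0.75 for an L target (copy ratio 2).
* **Stage survival**: Kaplan–Meier product of per-stage conditional
  survival over egg → hatchling → juvenile → adult; with every individual
  followed to the end (no censoring) the product telescopes to final
  survivors / initial count, independent of the stage decomposition.
  Two cohorts are compared by a log-rank test on stage-indexed event
  times (survivors censored at the last stage), via lifelines.
* **Mann–Whitney U**: U by midrank summation (scipy); z, p and r use the
  plain normal approximation without tie or continuity correction —
  `z = (U − n₁n₂/2)/√(n₁n₂(N+1)/12)`, `r = |z|/√N` — the convention the
  reproduced summary tables follow.

## Numerical and design choices

* Coordinates are 0-based half-open internally; GFF3 I/O converts to and
  from 1-based inclusive.
* cr direction is reference/alternative (euploid over aneuploid), the
  direction in which the S expectation is 1.5.
* One RNG stream per matrix, spawned from the single configuration seed;
  identical (config, seed) reproduce byte-identical outputs.
* `noise=False` simulation returns rounded expected counts for
  closed-form checks.
* Problem sizes in the test-suite studies (2000 genes, 6 + 6 WGS and
  3 + 3 RNA libraries, 300-gene closed-form designs) match the emulated
  study's scale while keeping the whole suite fast.

## Known limitations

* Size-factor anchoring assumes dosage-proportional genes are the
  majority within every subgenome class; designs where most genes respond
  to aneuploidy violate the medians' anchor.
* The Wald test with plug-in dispersions is approximate at n = 3 + 3; the
  empirical-Bayes squeeze keeps it calibrated when dispersions are
  homogeneous, but strongly gene-specific dispersions at this replication
  level are only partially recoverable.
* Subgenome assignment is hard-thresholded, not probabilistic; genes with
  genuine intermediate dosage (segmental CNVs) land in NA rather than
  being modelled.
* The log-rank test treats stages as discrete event times; continuous
  follow-up, covariates and censoring are out of scope.
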