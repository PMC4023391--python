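# Methods

## Decay model and estimator

Transcription is arrested at t = 0 and each 3′ isoform's molecule count
decays as a single exponential, mu(t) = A0 · exp(−k t). The package
estimates k per isoform from raw 3′-end counts K over (timepoint ×
replicate) libraries in three steps.

**Normalization.** Spike-in RNA represents the same number of molecules
in every library, so per-library spike totals T_l measure capture
efficiency directly. Normalized counts are K / s_l with s_l = T_l /
10 000 by default ("counts per 10 000 spike reads"). The anchor is a
data-independent constant on purpose: it makes normalization exactly
equivariant, so rescaling one library's raw counts (a pure
sequencing-depth change) leaves its normalized counts unchanged to
machine precision. Geometric-mean anchoring per condition (factors with
geometric mean one) is available via `anchor="condition"`; it produces
the same decay estimates — only intercepts shift — but is not exactly
equivariant because the anchor itself moves with the data.

**Dispersion.** Counts are negative binomial, Var = mu + alpha·mu².
For every (condition, timepoint) the replicate mean m and variance v of
normalized counts give a per-site moment estimate (v − m)/m², and the
trend alpha(mu) = a0 + a1/mu is fit across sites by ordinary least
squares over sites with m above `min_mean` (default 8). Two estimation
details matter with few replicates:

- the per-site estimates are used *unclipped* for the trend fit. They
  are extremely right-skewed with 2–3 replicates; clipping negatives
  before fitting biases the trend up, and robust (Huber) location of the
  clipped values targets their center, which lies well below their mean.
  Plain least squares on the raw values is noisy but nearly unbiased, and
  the trend is averaged over hundreds of sites.
- only the trend, never a per-site estimate, enters the regression
  weights; with two replicates per-site dispersions are far too noisy.

Coefficients are clipped at zero and predictions floored at `floor`
(default 0) so the variance model stays valid.

**Weighted regression.** The response is y = ln(K/s); zero counts are
dropped (the log is undefined and a pseudocount would bias slopes; the
weighting already down-weights near-zero expectations). The design has a
shared slope −k across replicates and replicate-specific intercepts. By
the delta method, Var(ln K) ≈ Var(K)/mu² = 1/mu_raw + alpha(mu_norm);
weights are the inverse of this quantity. Fitting is two-stage feasible
generalized least squares: an ordinary least-squares pilot fit supplies
fitted means, and two reweighted passes refine them. Weights are always
computed from fitted means, never from the observed counts — plugging
single noisy observations into the variance formula couples weights to
noise and makes the standard errors anticonservative, which we verified
empirically inflates the pair-test tail.

The same Taylor expansion that yields the variance gives a mean
correction, E[ln K] ≈ ln mu − (1/mu + alpha)/2. Because alpha rises with
timepoint, the uncorrected log response sags at late timepoints by
roughly alpha/2, which systematically steepens slopes; the correction
(on by default) removes this drift and is essential for slow decayers,
whose true slope over a 40-min window is comparable to the drift.

Coefficient covariance is (XᵀWX)⁻¹ with no residual-variance scale: the
weights are taken as known variances, which is what makes the downstream
z-tests approximately calibrated. `se_k` is the square root of the slope
entry. Fits with fewer than 3 usable points (or points at fewer than 2
distinct timepoints) are refused with qc `insufficient_points`; slopes
numerically at or below zero give qc `nondecaying` with half-life ∞ and
are excluded from ratio and correlation summaries.

**Differential stability.** For every unordered pair of qc-pass coding
isoforms within a gene, z = (k_A − k_B)/√(se_A² + se_B²), p = 2·Φ(−|z|),
with Benjamini–Hochberg adjustment across all pairs genome-wide
(per-gene adjustment behind a flag). Gene summaries flag any significant
pair and the maximal half-life fold ratio. Gene-level decay is the
abundance-weighted mean of isoform rates, weighted by fitted t = 0
abundance, reflecting that a gene's overall turnover is a composite of
its isoforms'. Mutant/wild-type regulation is measured per isoform as
the rate ratio k_mut/k_wt, which cancels global shifts between strains.

## Mispriming filter

Oligo-dT primers can anneal to genomic A-rich tracts and create false
poly(A) sites. A site is removed when its downstream window (18 nt,
strand-aware, starting at the nucleotide after the site, evaluated on
the transcript sense strand) has A-fraction above 0.67 or contains a run
of ≥ 6 consecutive A. All three parameters are exposed; windows running
off a chromosome end are truncated and evaluated on the available bases.
The filter is idempotent by construction (it depends only on genome
sequence, not counts).

## Isoform classification

A poly(A) site is joined to full-length isoforms (TIFs) whose 3′ ends
match within `tif_match_tolerance` (default 0 — nucleotide resolution).
Each (site, TIF) pair receives exactly one of eight categories from the
TIF's coverage of same-strand gene models: covering one full CDS
(`coding_1orf`), two or more (`coding_2plus_orf`), overlapping the
translated regions of two genes without covering either
(`partial_2orf`), matching a stable unannotated transcript at ≥ 50%
reciprocal overlap (`sut`), overlapping only the 3′ or 5′ portion of a
CDS (`overlap_3prime`/`overlap_5prime`), lying entirely within a CDS
(`intragenic`), or overlapping nothing (`intergenic`). Precedence when
several could apply: coding > partial_2orf > sut > overlap > intragenic
> intergenic; a TIF spanning a CDS interval exactly minus its last base
counts as intragenic (containment is checked before boundary overlap).
"Covers the CDS" means the transcript interval contains [cds_start,
cds_end) entirely. 3′UTR length is measured in transcript orientation
from the base after the stop codon to the site, inclusive, against the
covered gene whose stop is closest upstream. Sites without a matched TIF
get a site-only heuristic label and a `site_only` flag; a site matched
by several TIFs contributes each assignment separately, so one
polyadenylation position can legitimately be both a coding and a
non-coding isoform end.

## Motif and category statistics

Category comparisons use one-way ANOVA on decay rates over categories
with at least 20 members (the display rule for category-level
reporting), followed by Welch pairwise t-tests with BH adjustment.
Motif scanning is exact IUPAC matching (overlapping matches included) on
the sense strand of each gene's 3′UTR stretch, from the stop codon to
its most distal site; per isoform, a hit is `contained` when it ends at
or upstream of that isoform's site, and its distance to the 3′ end is
recorded. The with/without-motif comparison is restricted to genes with
at least one motif-containing isoform, so the contrast is between
isoforms of the same genes. Divergent-pair analysis correlates
gene-level decay of opposite-strand gene pairs transcribed head-to-head
whose 5′ starts lie within 200 bp.

## isRIP enrichment

The IP-vs-input test is a self-contained negative-binomial testing
scheme: median-of-ratios size factors over sites with all-nonzero
counts, anchored to geometric mean one; per-site moment dispersions
pooled across conditions and shrunk toward an OLS-fitted mean trend with
`trend_weight` pseudo-replicates (default 6, so with triplicates the
trend carries two thirds of the weight); a per-site NB log-linear model
with a condition coefficient fit by iteratively reweighted least squares
(statsmodels GLM provides the solver; a moment fallback with a
half-count continuity correction handles degenerate separation); and a
Wald test on the condition coefficient with BH adjustment. An isoform is
bound when q ≤ 0.1 and the raw (unshrunken) fold change exceeds 4. The
mutant/WT ratio group test is Welch's t on *log* ratios — a ratio of two
noisy rates is heavy-tailed on the raw scale, and slow decayers would
otherwise dominate the variance — with medians of raw ratios reported
alongside, separately for coding and non-coding isoforms.

## Synthetic data

The generator is the package's ground-truth instrument, emulating the
assay's statistical structure: genes on both strands with 1–4 isoforms
whose sites differ by as little as 1 nt; dedicated cassettes realizing
all eight coverage categories; divergent gene pairs within 200 bp;
standalone artifact sites with a 20-nt A tract directly downstream; a
spike-in chromosome whose sites carry one ninth of the sample's expected
t = 0 molecules; and NB counts with library size factors drawn
log-normal (σ = 0.25) so normalization does real work. Defaults:
half-lives log-uniform on [4, 180] min drawn per gene (isoforms share
the gene baseline unless an effect is planted, so within-gene tests are
null by default); abundances log-normal around 200 expected t = 0
counts; dispersion rising over timepoints, (0.02, 0.04, 0.08, 0.14,
0.20); non-coding category rate multipliers (partial two-ORF overlaps
1.7×, SUTs 1.35×, boundary overlaps 1.3×, intragenic and intergenic
1.0×) mirroring the relative instability of non-coding classes.

The PUF3-like motif (TGTAAATA) is planted in 30% of genes between the
two most distal sites, so only the distal isoform carries it; this makes
binding isoform-specific and keeps the bound and unbound groups of the
binding-conditional analysis drawn from the same genes, which is what
makes the planted twofold group-mean rate ratio identifiable (bound-only
genes would enter the bound average with no unbound counterpart, and
with half-lives spanning 45-fold the mismatched gene weights dominate
the contrast; `motif_all_fraction` restores such genes if wanted).
Motif-carrying coding isoforms are destabilized 2× in the WT condition
and revert to baseline in the mutant; motif-carrying non-coding isoforms
(planted in half the SUTs) are bound but not destabilized, providing a
built-in negative control. RIP simulation multiplies IP expectations by
the enrichment factor (default 8) for bound isoforms.

What the generator does not emulate: raw reads and alignment error,
sequencing-cycle or positional biases, correlated biological replicate
effects, non-exponential decay, transcriptional readthrough, or any
dependence between isoform abundance and stability. Passing tests
therefore demonstrate the statistical machinery under the assumed noise
model, not robustness to artifacts outside it.

Problem sizes in the test-suite and acceptance runs (500–4000 isoforms,
genomes of 150–400 genes) were chosen so that Monte-Carlo error on the
checked quantities is small relative to their tolerances while runs
complete in seconds.

## Numerical choices and known limitations

- t = 0 libraries are included in fits by default (`include_t0`).
- Slopes with |k| < 1e-12 are treated as exactly zero (flat data can
  produce ±1e-17 slopes in floating point).
- The z-test's normal reference is mildly anticonservative in the
  p ≈ 0.01–0.05 range for fast decayers, where zero-truncation at late
  timepoints is not captured by the delta-method variance; the far tail
  (p ≤ 0.001) is accurately calibrated. Empirical FDR of BH at 0.1 runs
  slightly above nominal as a result (measured by the calibration test).
- Relative half-life error for slow decayers (t½ ≳ 50 min) is bounded
  below by information, not implementation: over a 40-min window with
  two replicates and late-timepoint dispersion near 0.2, the weighted
  normal-equations variance — the Cramér–Rao bound for this design —
  already implies median relative errors of tens of percent for the
  slowest transcripts. Extending the time course, not refining the
  estimator, is the remedy.
- Half-lives are reported as ∞ for non-decaying fits rather than
  negative values, and such fits are excluded from ratios, correlations,
  and medians.
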