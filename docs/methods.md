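# Methods

`senhic` analyzes binned intra-chromosomal Hi-C contact maps layer by
layer — distance decay, A/B compartments, TADs, loops, differential
interactions, 3D geometry — and ships a synthetic generator that plants
every one of those features with known parameters. The package's claims
about correctness rest on parameter recovery from those planted maps,
not on agreement with any particular dataset.

## The synthetic contact model

A chromosome of `L` bp at bin size `b` has `n = L/b` bins. The expected
count of pixel `(i, j)` at bin distance `s = |i - j|` is

```
lambda_ij = B_i B_j (max(s,1) b)^(-alpha)
            exp(c_eff(s) p_i p_j)
            (1 + e_T [same TAD])
            (1 + f_L K(i,j))
```

* **Decay** `alpha` (default 1.0) is the contact-probability exponent
  typical of mammalian interphase chromatin. The diagonal is capped at
  the one-bin value so the power law stays finite.
* **Compartments**: `p_i` in [-1, 1] is a block-alternating profile;
  `c` scales the checkerboard contrast. `c_eff(s) = c (1 + s b / 10 Mb)^(-gamma)`
  lets compartment contrast weaken with genomic separation
  (`gamma` = 0.3 for the compartment genome), reproducing the
  empirical observation that compartment strength declines with
  distance; setting `gamma = 0` gives a separation-independent
  checkerboard.
* **TADs** multiply intra-domain pixels by `1 + e_T` (default 1.0).
* **Loops** add a truncated Gaussian kernel at each anchor pair
  (default sigma 1.5–2 bins, support 5 bins), mirrored so the planted
  peak strength is `f_L` on both triangles.
* **Biases** `B_i` are log-normal (sigma 0.15–0.25), mean-normalized.

The intensity is rescaled so its upper triangle sums to the configured
depth, and counts are drawn pixel-wise Poisson. Replicates share the
intensity and differ only in the random stream; a perturbed condition
reuses the same geometry with modified parameters (decay shift,
amplitude scale, per-TAD enrichment scale, loop deletion/addition,
regional fold changes). Because both conditions are rescaled to the
same depth — emulating the standard practice of down-sampling condition
pairs to matched totals — a planted regional fold `f` is observed as a
slightly diluted effective fold `f / (1 + (f-1) m)` where `m` is the
region's share of total intensity; the differential-interaction test
genome therefore uses small (160 kb) regions so the dilution is
negligible.

What the generator does **not** emulate: trans contacts,
restriction-fragment geometry, copy-number variation, distance-
dependent noise beyond Poisson counting, TAD nesting, and cell-to-cell
heterogeneity. Passing recovery tests on these maps therefore shows the
estimators are correct and calibrated under Poisson sampling with
planted architecture — not that they are robust to every artifact of
real libraries.

### Study-condition genomes

| factory | geometry | depth | purpose |
|---|---|---|---|
| `compartment_config` | 60 Mb @ 100 kb, 2 Mb checkerboard, c = 0.6 | 2M | PC1 / saddle / interval-pair strength (60 Mb keeps the >30 Mb stratum populated) |
| `domain_config` | 20 Mb @ 10 kb, 8 TADs (~2.5 Mb) + 3 loops per TAD | 5M | insulation, TAD calling, ATA, stability metrics |
| `loop_config` | as domain | 30M | loop calling/APA — focal-dot detection at 10 kb is the most count-hungry layer |
| `difftad_config` | 20 Mb @ 10 kb, 40 × 500 kb TADs, 10% with e_T halved | 5M | differential-TAD power with a mostly-null score cloud |
| `dci_config` | domain genome + three 160 kb regions at fold 2.5 | 10M/rep | differential-interaction recall |

Depths are per replicate and chosen to match the per-chromosome share
of deeply sequenced Hi-C libraries (a 20 Mb chromosome's share of a
multi-hundred-million-pair genome-wide map is a few million contacts;
loop-resolution studies run several-fold deeper).

## Matrix operations

**ICE balancing** iteratively divides by row-sum ratios until the
coefficient of variation of unmasked marginals falls below `tol`
(default 1e-5, max 200 iterations); biases are normalized to unit mean.
The default mask removes zero-coverage bins plus the lowest 2% of
nonzero-coverage bins, which is standard protection against mappability
artifacts in real data. Synthetic maps have no unmappable bins, so the
validation pipeline balances them with `mask_fraction = 0`; masking 2%
of legitimately low bins would otherwise blur insulation dips at
domain boundaries, where coverage is genuinely lowest.

**Expected profile / O/E** are computed per chromosome (never pooled),
as the mean balanced value over unmasked pairs at each separation.

**P(s)** is computed on raw counts with log-spaced distance bins
(ratio 1.12; linear bins available). The stored `prob` column sums to
one (counts over total); the decay exponent is fit by least squares on
log10 *mean count per pair* versus log10 distance, which is free of the
pair-multiplicity artifact that binned totals carry. The default fit
range is 1–10 Mb at 100 kb bins.

**Down-sampling** draws a multivariate hypergeometric sample over
pixels, i.e. removes reads without replacement — the new total is exact
and pixel expectations scale linearly.

## Compartments

PC1 is the leading eigenvector of the Pearson correlation matrix of the
per-chromosome O/E map, scaled by the square root of its eigenvalue and
sign-oriented against an activity track (GC content or accessibility;
the synthetic pipeline uses the planted accessibility track). Saddle
plots rank unmasked bins into 50 equal-occupancy PC1 groups; strength
is the mean of the two intra corners over the two inter corners, with
corner width 20% of groups (a common convention; configurable).

Interval-pair (distance-stratified) strength: contiguous A/B intervals
of at least 3 bins define the units; every ordered interval pair
contributes its O/E submatrix, rescaled to 33×33 by bilinear
interpolation. Self-pairs are "short range" (they touch the diagonal),
distinct pairs "long range"; pairs are stratified by interval-midpoint
separation into <10 Mb, 10–30 Mb, >30 Mb. An intra-type pair's strength
is its submatrix mean divided by the pooled mean of inter-type (A–B)
submatrices in the same range and stratum; the self-pair stratum has no
on-diagonal inter reference, so it falls back to the nearest long-range
inter mean. Empty cells are reported missing rather than erroring.

## TADs

**Insulation** is the log2 ratio of the mean of a `w × w` square
sliding along the diagonal (upstream × downstream of each bin) to the
chromosome-wide mean of such squares (window 500 kb by default on the
synthetic genome). Boundary calling Gaussian-smooths the track
(sigma = w/10) before finding local minima — single-bin Poisson dips
otherwise flood the minima list — then snaps each minimum back to the
raw-score minimum within the smoothing radius, and keeps minima whose
prominence (mean of flanking maxima minus the minimum) exceeds 0.1
log2 units. TADs are the segments between boundaries; segments shorter
than `min_tad_bins` are merged by removing their weaker boundary.

**ATA** rescales each TAD window (TAD ± half its length) to a common
size with the first two diagonals removed and averages; the score is
the mean of the central TAD area.

**Stability metrics**, per TAD:

* *Consolidation score (CS)*: mean intra-TAD signal over spans
  ≥ 400 kb divided by the mean over distance-matched pairs in the
  ±1-TAD-length flanking window that are not fully inside any TAD,
  with per-distance averaging so a purely distance-dependent matrix
  gives exactly 1. Undefined for TADs at or below the span floor.
* *Intra-TAD connectivity (iTC)*: intra-TAD contact mass over intra
  plus one-end-in-TAD mass, with inter-TAD pairs capped at 2 Mb span to
  bound the denominator; always in (0, 1]. The alternative reading
  (intra over contacts to adjacent TADs only) is not implemented as
  the default; the cap already restricts the denominator to the local
  neighborhood.
* *Degree of disorder (DoD)*: among the TAD's top-decile O/E pixels,
  the mean pairwise Euclidean distance in bin units divided by TAD
  length. Focal, clustered strong interactions give low DoD; when
  domain enrichment dissolves, the strongest pixels scatter and DoD
  rises. This operationalizes "dispersion of important interactions"
  with a fixed quantile because the cited construction is not fully
  specified.

**Differential TADs**: paired per-TAD scores (x, y) are fit with a
bivariate mean/covariance; points with squared Mahalanobis distance
above the chi-square(2) 95% quantile are dropped and the fit repeated,
multiplying the refit covariance by the standard truncation consistency
factor `h / F_chi2(4)(q_h)` so that null data remain chi-square(2)
distributed (without it the trimmed fit inflates the type-I rate to
~8%). p-values are the upper chi-square(2) tail; direction follows
sign(y − x) at p < 0.05. Perfectly colinear score pairs (a degenerate
null) are handled by measuring deviation only off the fitted axis.
The detector is an outlier test: it assumes most TADs are null, so the
validation genome perturbs 10% of domains.

**Rearrangement classification** uses deterministic boundary-matching
rules with ±1 bin tolerance and precedence
unchanged > split > merge > shift > complex (shift requires ≥50%
reciprocal overlap with exactly one reference TAD).

## Loops

The caller tests raw counts against four local expectations (donut,
lower-left quadrant, horizontal and vertical stripes; inner radius 2,
outer radius 5) transferred through the global expectation
`E_ij = b_i b_j E(s)`, with Poisson upper-tail p-values BH-corrected
per neighborhood across the tested band (spans 3 bins–2 Mb). A pixel is
significant when all four q ≤ fdr (default 0.1) and its enrichment over
both the donut and lower-left expectations is ≥ 1.5. Significant pixels
are clustered by 8-connectivity; each cluster reports its highest-count
pixel. Because a true loop concentrates several significant pixels into
one call while stray BH-tail pixels each become their own call,
single-pixel clusters must additionally clear q ≤ fdr/20. An optional
`peak_window` sums observed and expected counts over a small square
before testing (useful for wide dots); the default tests single pixels.
Multi-resolution calls are merged keeping the finest call within 20 kb.

APA averages O/E windows (±100 kb at 10 kb) over loops, excluding the
first two diagonals and windows that touch the matrix edge; enrichment
is the center pixel of the mean.

Differential loops quantify the union loop list (anchors merged within
2 bins) as the mean raw count over the loop pixel ±1 bin per condition,
CPM-scaling condition 2 when totals differ. Loops below the count floor
`cacut = 5` are dropped; |log2 FC| ≥ `cmcut = 0.5` with a BH-adjusted
two-sided conditional binomial p ≤ 0.05 classifies lost/gained; the
rest are common. `cacut`/`cmcut` are interpreted as a minimum mean
anchor count and a minimum absolute log2 fold change.

## Differential chromatin interactions

Replicated pixel tables are jointly normalized by cyclic pairwise loess
of M (log2 ratio) on A (mean log2) within log-spaced distance strata
(ratio 1.3, minimum 30 pixels, 3 cycles). The loess trend is fit only
on pixels within 3 robust standard deviations of the stratum median M
and evaluated everywhere by interpolation: focal differential signal is
exactly what the test must preserve, and letting it bend the trend
line absorbs 10–20% of a planted fold change.

The per-pixel test is an exact conditional binomial: given the pixel's
grand total, the condition-2 share is tested against the library-size
ratio, two-sided, BH-corrected genome-wide across tested pixels (span
≤ 2 Mb). A pixel is directional only when log2 CPM > 2,
|log2 FC| > 1.2 and adjusted p < 0.05 — the conditional test is a
calibrated (slightly conservative) substitute for a negative-binomial
exact test; under Poisson simulation its null discovery fraction is
effectively zero.

Per-TAD summaries count directional pixels with both ends inside the
TAD ± 80 kb flank (clipped at chromosome ends) and keep TADs with
n_up + n_down ≥ 10 (the either-class-≥10 reading is available via
`min_dci_rule="either"`). Covariate means use the TAD body only; the
flank covers pixel assignment, not covariates. Spearman correlations of
the down fraction with each covariate are reported overall and per
rearrangement class. Enrichment: Fisher's exact test on compartment ×
(high/low downFrac) — with a Haldane-corrected odds ratio reported
alongside for degenerate tables — and a logistic regression of the
high-group indicator on rearrangement type with "unchanged" as
reference (Wald p, 95% CI; separation flagged).

## 3D embedding

Contacts become wish distances `d_ij = (O/E + 0.01)^(-0.5)` and a 3D
configuration minimizes weighted stress (weights `1/d^2`) by L-BFGS
from 5 random restarts (seeded); the best restart is returned, centered
at the origin. This is a deliberately simple stress-majorization
stand-in for population-based conformation optimizers and recovers
relative geometry (distance ranking, domain compaction), not literal
structures; the contact-to-distance exponent is a convention, not an
inferred quantity. Focus-bin distance profiles are compared across
conditions with a paired Wilcoxon test, pairing bins by genomic
position.

## Pipeline and reporting

`run_pipeline` executes matrix → compartments → domains → loops → DCI →
3D on simulated condition pairs, writes every table with a provenance
header (module, parameter hash, seed) and a JSON manifest; a failed
stage aborts its dependents while independent stages proceed. The
statistical reporting helper maps p-values to the star convention
ns / * < 0.05 / ** < 0.01 / *** < 0.001 / **** < 0.0001. Significance
tests offered: paired/unpaired Wilcoxon, paired/Welch t, Spearman,
Fisher. The library functions and the `senhic` CLI subcommands
(simulate, balance, decay, compartments, tads, loops, dci, embed,
run-all) are thin wrappers over the same code paths.

## Problem sizes and determinism

The default validation runs use the genome sizes and depths in the
table above; a full `run-all` completes in well under 15 minutes on one
CPU. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the same seed reproduces byte-identical
outputs. Derived seeds are kept below 2^31.

## Known limitations

* Cross-resolution loop merging is implemented but the validation
  genomes use a single resolution per layer.
* The conditional-binomial DCI test ignores biological overdispersion
  beyond what joint normalization removes; on real replicates an
  overdispersion-aware exact test would be less anticonservative.
* CS is undefined for domains shorter than the 400 kb span floor.
* The 3D embedder returns one consensus structure; ensemble variability
  is out of scope.
* Trans (inter-chromosomal) contacts are not modeled or analyzed;
  cis-fraction accounting operates on pair labels only.
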