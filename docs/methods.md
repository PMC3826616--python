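# Methods

This note documents the models, conventions and numerical choices behind
`unipeak`, in the order the pipeline applies them.

## Hits and coordinates

Every retained alignment contributes exactly one hit at its 5′-most
reference coordinate: `reference_start` for forward-strand alignments, the
rightmost aligned base (`reference_end − 1`) for reverse-strand alignments.
All coordinates are 0-based half-open internally; BED passes through
unchanged and 1-based annotation tables must be converted on load. Alignment
confidence is a posterior probability, enforced on BAM input through the
MAPQ bridge MAPQ = −10·log₁₀(P_err): a posterior cutoff of 0.9 is MAPQ ≥ 10.
Duplicate reads are *not* collapsed by default (an optional flag collapses
each position/strand to one hit); secondary and supplementary records are
skipped. Read truncation to a uniform length is an aligner-side concern:
the package consumes alignments as given.

## Density model

The strand-specific density is a discrete Epanechnikov kernel average with
integer bandwidth *h* and a **fixed denominator** Σ_{k=−h..h} K(k/h). There
is no boundary renormalization, so hits within *h* of a chromosome end lose
the kernel mass that falls off-chromosome; everywhere else each hit
contributes exactly unit mass (Σᵢ H(i) = N). Profiles are stored sparsely —
only positions within *h* of some hit are materialized; H is implicitly
zero elsewhere. Smoothing is direct sparse scatter-add, which at bandwidths
of 50–100 nt is faster and simpler than FFT convolution.

Bandwidths: 50 nt for the preliminary (shift-estimation) pass, 100 nt for
the final pass, the latter chosen to merge binding sites in close
proximity into single regions.

## Strand-shift estimation

Per sample: preliminary regions are called from the *unshifted* sum of the
two strand profiles at 25× fold enrichment, leptokurtic regions (excess
kurtosis > 50) removed, and the 1,000 regions with the most contained hits
retained. For each region and each integer shift s ∈ [25, 150], the Pearson
correlation between the forward profile translated +s and the reverse
profile translated −s is computed over the region span; profile values are
read from a window extended by the maximum shift on both sides so shifted
slices never truncate (an otherwise-open convention chosen to avoid edge
bias). Regions whose best correlation is below 0.3 do not vote. The
per-region argmax shifts are kernel-smoothed (Epanechnikov, bandwidth 5 nt)
on the shift grid and the grid argmax is the sample-wide shift; ties break
toward the smaller shift at both levels. Negative controls never yield
enough preliminary regions, so they inherit the **median** of the ChIP
samples' shifts (midpoint for an even count, rounded to the nearest integer
when applied).

On simulated data the estimate recovers half the fragment length within a
few bases across fragment lengths 100–200 bp.

## Region calling and QC

Background rate b = (total hits of non-control samples) / (effective genome
size, the summed length of non-excluded chromosomes). Enriched regions are
maximal runs of consecutive bases with pooled H(i) > fold·b; the final pass
uses the same default fold (25) as the preliminary pass, exposed as a flag.
Region peaks are the leftmost argmax. Three filters follow:

- **Kurtosis**: excess (Fisher) kurtosis of the multiset of shifted 5′
  starts within the region; > 50 fails. All hits on one base (zero
  positional variance) is defined as +∞ and always fails. Raw (Pearson)
  kurtosis, which differs by +3, is available by flag since the variant is
  a convention.
- **Strand correlation**: Pearson r between the pooled shifted strand
  profiles over the region span; r < 0.3 (or undefined, when a strand has
  zero variance) fails. Pooled rather than per-sample strands are used in
  the final pass — the per-sample choice is equally defensible but pooling
  matches the pooled calling step.
- **Structural**: regions on excluded chromosomes (default patterns chrX,
  chrY, chrM), regions overlapping a blacklist interval by ≥ 1 bp, and
  regions longer than 500 bp are dropped. The size filter applies only to
  the final pass, not to preliminary shift-estimation regions.

Counting is half-open: a sample's hit shifted to exactly `end` is outside
the region. Controls and histone-mark samples are excluded from pooling and
the background total but are counted in the final matrix.

## Normalization

The count matrix is mapped to continuous occupancy scores in three steps,
re-implementing the variance-stabilization contract of count-based
differential analysis rather than any specific package's internals
(numeric parity with such packages is a non-goal):

1. **Size factors** — median over all-positive regions of count/geometric
   mean. The invariant is on factor *ratios*: scaling one sample by c
   scales its factor by c relative to every other sample (the geometric-
   mean reference renormalizes all factors jointly).
2. **Dispersion-mean fit** — per-region means and variances of normalized
   counts within each replicate class (replicates from different labs are
   separate classes), pooled across classes into one analysis-wide cloud,
   then a lowess fit of log variance vs log mean (span 0.3). Only fitted
   values are used downstream. Outside the fitted mean range the
   *dispersion* α(q) = (w(q) − ζq)/q², ζ = mean reciprocal size factor, is
   clamped at its boundary value — clamping the variance instead would
   inflate the shot-noise term near zero. The analysis shares one pooled
   dispersion-mean *relationship* across all classes; a scalar-dispersion
   mode (median of raw dispersions) is available by flag.
   When no region shows within-class variance the dispersion is exactly 0.
3. **VST** — τ(q) = ∫₀^q dv/√(ζv + α(v)v²), evaluated by trapezoid
   integration after the substitution v = u², which removes the integrable
   1/√v singularity (4096-point u grid). τ(0) = 0, τ is strictly
   increasing, and in the α→0 limit τ(q) → 2√q to ~1e−7 relative error.

## Annotation

Region peaks are matched to the nearest point feature of each kind within
500 bp; exact distance ties go to the smaller coordinate. The signed
distance is (feature − peak), negated for minus-strand features, so
negative always means the feature lies upstream of the peak on the
feature's strand. A region matching an initiating Pol II peak, a CAGE peak
and an annotated TSS simultaneously is a consensus promoter. GC fraction
uses called A/C/G/T bases only; the CpG rate counts `CG` dinucleotides over
fully-called adjacent pairs (soft-masked bases count, Ns are excluded from
both denominators). Evolutionary-constraint fraction is the share of
*scored* positions with score strictly > 2; unscored positions are missing,
not zero. Gene-body counts use unshifted 5′ starts in the closed interval
from 100 bp upstream of the TSS to 100 bp downstream of the TES of the
longest isoform, with upstream/downstream flipped for minus-strand genes.

### Motif scanning

The built-in scanner scores both strands of a 201-bp window centered on
each region peak with log₂-odds against a uniform 0.25 background. Scores
are integerized (scale 1000) and the null distribution of the window score
is the exact column-wise convolution on the integer grid, so the best-hit
p-value equals the exhaustively enumerated background fraction by
construction. A motif's E-value is that p-value times the number of window
start positions scanned for the motif across the whole run (both strands,
all regions); E < 10 is a hit, and a motif *set* hits a region if any
member motif does. This is a deliberate, documented approximation of MAST,
which combines per-sequence p-values differently; ingesting a pre-computed
MAST tabular hit file is the fidelity route and is collapsed to sets by the
same any-member rule.

## Clustering and statistics

Sample distances are the Pearson metric 1 − r over occupancy vectors.
UPGMA (hand-rolled agglomeration: merge height = half the average
inter-cluster distance, ties toward the lexicographically smallest label
pair) yields rooted ultrametric trees; neighbor joining (Saitou–Nei, via
scikit-bio) yields unrooted trees, exact on additive distance matrices.
Trees serialize as newick.

Motif-conditioned occupancy tests pool replicates by the mean of
variance-stabilized columns per TF, then apply a two-sided **Welch**
(unequal-variance) t-test of occupancy at promoters with vs. without the
motif set; "t-test" alone underdetermines the variant and Welch is the
robust default, with Student available by choice of caller. Reported
significance is sign(Δmean)·(−log₁₀ p), base 10 being the conventional
reading of an unqualified logarithm of a p-value. Groups smaller than 2 are
skipped. The interaction-pair comparison splits all between-sample
correlations (same-target pairs excluded) by whether the two targets are a
listed interacting pair, over all HOT regions.

## Latent-variable regression

The regulation model regresses the response block (PIC, histone marks,
Pol II, CAGE, RNA readouts) on the predictor block (all TF replicate
columns plus negative-control columns; the null variant keeps controls
only) by two-block NIPALS partial least squares with Y-deflation.  Both
blocks are column-centered and unit-variance scaled by default (autoscale
exposed as a flag). NIPALS stops early when either block is numerically
exhausted, so noiseless low-rank systems are handled exactly; with the
maximum number of components on full-rank data, predictions coincide with
ordinary least squares.

The component count follows an RMSEP-decrement rule: the first latent
variable plus every subsequent one that lowers the average RMSEP by at
least 0.01, applied greedily in component order, where RMSEP is the
leave-one-out root-mean-squared prediction error averaged over response
columns on the autoscaled response scale (so columns are comparable).
Leave-one-out is literal: each held-out region is predicted after
re-centering, re-scaling and re-fitting on the remaining regions. CV R² is
reported per response column as 1 − PRESS/TSS with TSS taken about the
full-data column mean (a documented convention; a constant response is
defined to have R² = 0). One multivariate-Y model is fit per variant, not
one model per response.

## Synthetic data

The simulators define the package's test conditions; all are pure functions
of (parameters, seed).

- **ChIP-seq**: point sites evenly slotted (with random offsets) along a
  1 Mb chromosome; per site and sample, Poisson(reads_per_site) reads, each
  assigned a strand uniformly, with forward 5′ starts at site − F/2 and
  reverse at site + F/2 plus rounded-Normal(0, F/10) jitter; uniform
  Poisson background; controls are background-only. Defaults — 30 sites, 3
  ChIP samples + 1 control, fragment 150 bp, 200 reads/site, background
  0.005 reads/bp — give planted sites roughly 25-fold local enrichment
  over the pooled background at the default calling threshold. The jitter
  law and uniform strand split are fixture conventions, parameterized.
  What the simulator does *not* emulate: mappability gaps, duplicated
  reads, copy-number variation, GC bias, and fragment-length variance
  between samples — so passing recovery tests demonstrate correctness of
  the algorithm under its own model, not robustness to every artifact of
  real libraries (the kurtosis/blacklist filters that target such artifacts
  are exercised by constructed fixtures instead).
- **NB counts**: log-uniform region means, lognormal size factors
  (geometric mean 1), negative-binomial counts with common dispersion α
  (Var = μ + αμ², Poisson at α = 0).
- **Regulation**: `rank` latent factors with geometrically decaying
  standard deviations drive both the TF block (random loadings + noise)
  and the responses; control columns are independent noise, so any
  explanatory power of the null model on this fixture is spurious.

## Problem sizes and determinism

The test suite and the acceptance script run the study at desk scale: 1 Mb
chromosomes, 30–50 sites, tens of thousands of reads per sample, 2,000
regions for normalization checks, 120–200 regions for regression fixtures,
and 200 random trees — sizes chosen so the full verification completes in
minutes while every estimator operates well inside its asymptotic regime.
All randomness flows from explicit integer seeds; rerunning any stage with
the same configuration and seed reproduces outputs byte-identically.

## Known limitations

- No statistical significance model for regions: calling thresholds on
  fold enrichment only, with negative controls used for counting, not
  filtering.
- No paired-end fragment logic; each read contributes its own 5′ end.
- The VST does not promise numeric parity with any external normalization
  package, only the same contract (monotone, variance-flattening, Poisson
  limit).
- The built-in motif scanner approximates MAST's E-values (search-space
  convention: window count per run); use ingested MAST tables when exact
  parity matters.
- UPGMA/NJ trees carry no support values.
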