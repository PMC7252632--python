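# Methods

## Data model and preprocessing

The unit of analysis is a 400-bin concatenated promoter profile: for
each TSS, 100 bins of 100 bp (50 upstream of and including the TSS, 50
downstream) are extracted per mark and joined in the fixed order
H3K4me2, H3K4me3, H3K9ac, H4K20me1. Coordinates are 1-based inclusive
internally; BED and bedGraph I/O convert from/to 0-based half-open. A
TSS window spans `[tss − 4999, tss + 5000]`, so 10 kb windows align
with the bin grid and a TSS at position 5000 on a track starting at 1
is still usable; windows truncated by chromosome ends are skipped
rather than padded, since zero-padding would bias the max-count QC
filter. Minus-strand windows are reversed bin-wise so "upstream" is
always on the left.

Quality control mirrors the two stated rules literally, including
their off-by-one difference: *training promoters* are kept when the
profile maximum count is **≥ 7** ("less than seven" excluded), while
*scanned windows* are tested only when the maximum is **> 7**. A
window with maximum exactly 7 is therefore trainable but not
scannable; resolving the inconsistency either way would silently
change both sets, so the asymmetry is preserved as written.
Overlapping promoter windows (sharing ≥ 1 bp, i.e. TSSs closer than
10 kb on one chromosome) are removed pairwise — both members — because
the mark counts cannot be attributed unambiguously.

The log transform is `ln(1 + y)` (bins contain zeros). FPCA and all
scan correlations operate on this log scale, the same scale on which
the mixture step's Gaussian assumption is stated; Pearson correlation
is not invariant to the log map, so train-time thresholds and
scan-time correlations must share a scale.

## Step 1 — functional PCA

Profiles are dense, regularly sampled functional data, so the
covariance is estimated cross-sectionally with no smoothing: the mean
is the columnwise mean, and the eigenfunctions/eigenvalues come from
`eigh` of the 400×400 sample covariance (denominator n − 1) of the
centred profiles. Grid spacing is treated as 1: inner products are
plain dot products and eigenvectors are unit Euclidean norm.
Eigenvalue signs from rounding are clipped at zero; each
eigenfunction's sign is fixed so its largest-magnitude element is
positive, making fits deterministic. Scores are projections
`C_j = ⟨y − μ, ψ_j⟩`; their sample covariance equals `diag(λ)` and
`Σ_j λ_j` equals the covariance trace by construction (both asserted
in tests at 1e−8 relative tolerance).

`q` is the smallest component count whose cumulative fraction of
variance explained (FVE) reaches the threshold, default 0.90;
`q_override` fixes it directly. On real chromatin data the smooth,
spatially correlated signal concentrates variance in few components
(single digits); on the synthetic generator below, whose noise is
white rather than smooth, 90 % FVE needs on the order of 100
components — that is a property of the fixture, not a defect, and the
mixture step is unaffected because the scores stay uncorrelated.

## Step 2 — mixture clustering

Scores are clustered under a K-component mixture whose components are
products of univariate Gaussians — equivalently a diagonal-covariance
Gaussian mixture, exactly matching the model's factored density; full
covariance is deliberately not offered. EM details:

* initialization by k-means on the scores, one distinct sub-seed per
  restart (default 10 restarts; best final log-likelihood wins);
* responsibilities via log-sum-exp; variances floored at 1e−8 to
  prevent degenerate spikes;
* the log-likelihood is asserted non-decreasing at every iteration;
  convergence when the relative change drops below 1e−6 (cap 500
  iterations);
* a run whose component weights underflow (empty component) is
  discarded; if all restarts degenerate the fit errors out.

K is chosen by the user: `select_K` fits a range of K, reports BIC
(flagging its minimum as a suggestion) and cluster sizes, and writes a
cluster-sorted heatmap of per-bin z-scores of the log counts per K for
the homogeneity judgement; the package never auto-commits a K.
Cluster numbering is made canonical by sorting clusters by descending
mean total raw signal, so the last cluster is always the least active
("inactive promoters") regardless of EM's arbitrary label order. The
characteristic pattern of a cluster is the elementwise mean of its
member profiles, kept on both scales (raw counts for display, log for
scanning); the log pattern is the mean of member log profiles, not the
log of the raw mean.

## Promoter prediction

Per-cluster thresholds are the lower empirical 100α percentile
(inverse ECDF, numpy's `inverted_cdf`) of the training members'
correlations with their own pattern — a data-valued cutoff, so the
strict "exceeds" comparison is unambiguous. α defaults to 0.4, a
compromise between sensitivity and confidence; raising α can only
raise thresholds and hence never increases calls on well-separated
signals. The least-active (canonical last) cluster is excluded from
scanning by default, since a flat pattern carries no shape to
correlate with.

The scan is vectorized: sliding 100-bin views per mark are
concatenated into an (n_windows × 400) matrix, filtered by the
known-promoter overlap mask and the max-count rule, log-transformed
and correlated against all patterns at once. Windows with zero
variance yield undefined correlation and are treated as
non-significant. Chromosome-end windows are skipped.

Merging is a single sorted sweep: same-cluster windows sharing ≥ 1 bp
chain into a region `[min start, max end]` that records its maximum
correlation, its extreme windows and its window count; cross-cluster
transitively overlapping regions form one putative promoter spanning
their union, assigned to the evidence cluster with the largest maximum
correlation, ties to the lowest cluster index. Two guards are
optional and off by default: a minimum-windows-per-region filter
(against single-window "spikes") and the shortening rule, which trims
half of the first and/or last contributing window (5 kb each side at
defaults) and leaves the interval unchanged (with a warning) if
trimming would invert it.

Annotation overlap uses a 1 bp minimum (no fraction is imposed); SNPs
become 1 bp points after BED conversion. The seven Venn cells plus the
no-overlap count partition the promoter set per cluster by
construction.

## Synthetic data generator

The generator produces the statistical structure the method assumes,
not realistic ChIP-seq. Four mean shapes on the log scale, shared by
the first three mark segments with the H4K20me1 segment flat in all
four: a descending ramp ending at the TSS (pre-TSS enrichment), its
ascending mirror (post-TSS), a symmetric Gaussian-shaped peak at the
TSS, and a flat baseline. Noise is iid Gaussian on the log scale —
matching the Gaussian-after-log assumption — then exponentiated and
rounded to non-negative integer counts. Defaults, chosen once:
baseline 1.0 log units (≈ 1.7 counts), amplitude 2.5 above baseline
(profile maxima ≈ 30 counts, well clear of the QC threshold 7, while
roughly a tenth of flat-cluster profiles fall below it and exercise
the filter), noise SD 0.4 ("moderate") for profile simulation and 0.1
for genome embedding. Because counts are rounded, a zero-noise
profile's log transform matches its generating shape only up to
rounding (< 0.35 log units), not exactly.

The genome simulator overlays full four-mark signatures of random
active clusters on Poisson(1) background counts at sites spaced
≥ 20 kb (so neighbouring calls cannot merge), reporting ground truth
as BED. The test/acceptance problem sizes — 400 training profiles, a
2 Mb chromosome with 20 sites scanned at 100 bp stride — keep every
check comfortably under a few seconds while leaving each estimate far
from its decision boundary.

What passing these fixtures shows: the decomposition, clustering,
thresholding and interval mechanics are correct, and the pipeline
recovers planted signals at realistic separation. What it does not
show: robustness to spatially correlated noise, mappability artefacts,
replicate variation or diffuse marks — real data concerns outside the
generator's scope.

## Known limitations

* Sparse/irregular functional data (PACE-style conditional scoring)
  and covariance smoothing are not implemented; the dense-grid
  cross-sectional estimator assumes every bin observed.
* No FDR control for scan calls; the percentile rule is the only
  significance notion.
* The canonical cluster ordering is an artifact convention for
  reproducibility; cluster identity across datasets still requires
  inspection of the patterns.
* Promoter-count monotonicity in α holds for well-separated calls; in
  dense signal a higher threshold can in principle split one merged
  region into several.
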