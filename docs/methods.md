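# Methods

This note describes the models and procedures `cenchrom` implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot show.

## Coordinate and data conventions

All coordinates are 0-based, half-open (BED convention); all interval I/O is
BED-family, so no conversion ever happens internally. Haplotype is carried in
the contig name suffix (`chr5_MATERNAL` / `chr5_PATERNAL`) and parsed into a
tag. Modified-base calls follow the MM/ML convention: every candidate
position on a read carries an integer probability 0–255, and "detected"
means the probability clears a per-mark quality cutoff (6mA ≥ 230/255,
5mC ≥ 210/255 by default; one protocol variant filters 5mC at 230, exposed
as `FiberConfig.min_quality_5mC`).

## Sub-CDR calling

The caller smooths a per-CpG percent-methylation track with a 10 kb window
stepped at 1 kb, requiring ≥ 3 CpGs per window (sparser windows are flagged
invalid and excluded; by default invalid windows also break candidate runs,
switchable via `bridge_invalid`). The detection threshold sits 10 percentage
points below the array-wide mean; the mean is computed over CpGs by default
(`mean_over="windows"` switches to window means — the two differ when CpG
density varies along the array). A window exactly at the threshold counts as
below (fixed, documented tie convention).

Maximal runs of below-threshold windows become candidate domains. Each is
scored 0–100 as

    score = 100 · (0.5·s_depth + 0.3·s_cpg + 0.2·s_span)

with `s_depth = clamp(depth / array_mean)`, `s_cpg = clamp(n_cpgs /
expected CpGs in one window at array density)`, and `s_span = clamp(span /
50 kb)`. The three sub-score maps are the simplest monotone saturating forms
consistent with the 50/30/20 weighting and the 0–100 range; the reference
span of 50 kb saturates at roughly the largest single sub-CDR seen under
baseline conditions. Domains scoring ≥ 40 are retained and ≥ 50 are
HIGH_CONFIDENCE; CDR total span runs from the first to the last
high-confidence domain.

**Run → interval rule.** A run of windows is converted to a bp interval by
taking the union of each member window's central step cell
(`[start + (w−s)/2, start + (w+s)/2)` per window), not the union of the full
windows. The full-window union systematically over-extends each boundary by
≈ (1 − f\*)·window, where f\* is the overlap fraction at which a window's
mean first crosses the threshold (f\* ≈ 0.27–0.35 at typical dip depths),
i.e. ~7 kb per side at the default geometry; the center-cell rule bounds the
systematic error by about half a window. The full union remains available
as `boundary="union"`. Resolution is in either case limited by the window
and step sizes; boundary error on planted synthetic dips stays within
window/2 + step (6 kb), and in practice within ~3 kb.

The deeply-dipped LCL case, which the source protocol annotated manually,
is served by an `lcl` preset (detection offset 20 pp, matching ~60–40%
baselines dropping to 25–10%); this is a documented automated approximation
of a manual procedure, not a reproduction of it.

## Single-molecule density and the decision stump

A read's density in a region is (calls ≥ quality cutoff) / (candidate
positions), computed only over the read's candidate positions inside the
region. A read with zero candidate positions there is *excluded*, not given
density 0 — an absent denominator carries no evidence. Background (non-CDR)
territory is the active array minus sub-CDRs padded by a 10 kb buffer,
tiled into 5 kb non-overlapping windows, at most 15 per homolog (seeded
uniform subsample when more are available; one published comparison uses a
50 kb buffer, which is the same `background_buffer_bp` parameter).

The CDR vs background threshold is a decision stump: pooled densities are
sorted, candidate thresholds are midpoints between consecutive distinct
values, and the threshold minimizing the weighted Gini impurity
Σ_side (n_side/n)(1 − p₁² − p₀²) is chosen, smallest first on ties. A read
is enriched iff its density is *strictly* above the threshold; depletion
(for mCpG) is *strictly* below. Ties are therefore conservative in both
directions.

For co-occupancy, a read "fully spans" a sub-CDR when its alignment covers
≥ 95% of it (`span_fraction`), mirroring the `windowFrac = 0.95` retention
rule used for read-level matrices — the only span criterion stated anywhere
in the source protocol, adopted here for both uses. A spanning read is
mCpG-depleted when its 5mC density is below the learned 5mC threshold at
*every* spanned sub-CDR (the depletion criterion is otherwise unspecified;
the learned threshold is the package's choice), and CENP-A-multi when its
6mA density clears the 6mA threshold at ≥ 2 spanned sub-CDRs.

Per-read methylation matrices (reads × reference CpGs, probabilities /255,
missing where a read has no call at a site) are clustered with HDBSCAN at
min_cluster_size 5, min_samples 3, cluster_selection_epsilon 0.005, with a
Ward-linkage leaf ordering for display. Missing entries are mean-imputed
per column for distance computation only. Noise rows (label −1) are
excluded from summaries. All-identical input rows are returned as a single
cluster directly, since density-based clustering degenerates on duplicate
points.

## Remodeling comparison

Domains are matched across conditions by any-overlap (≥ 1 bp); the floor is
exposed as `min_overlap_bp` because the published bookkeeping does not
state its rule, and any-overlap is the weakest assumption. Many-to-one
merges count once on each side; a maintained domain is expanded/contracted
by comparing the summed matched-B length against its own length. Summary
percentages (count reduction, maintained fraction, expanded-of-maintained,
total-length change) are kept unrounded internally and rounded to one
decimal only for display. Differential regions are the per-base set
difference A \ B.

Baseline normalization divides each region's density by its chromosome's
mean non-CDR baseline and takes log2; fold-changes ≤ 0 are excluded before
the transform, with the exclusion count reported. Group comparisons use
Welch's t (Welch–Satterthwaite df, two-tailed) with Cohen's d on the pooled
n−1 SD, or a paired t over chromosomes. Degenerate cases (zero variance)
return t = 0, p = 1, d = 0 for identical constants and flag d undefined for
distinct constants.

Boundary metaplots center a ±flank window on each oriented boundary,
flipping windows so the hypomethylated (domain) side always lies to the
right; bins with no CpGs, including truncated flanks, are missing (NaN),
never zero-filled.

## Dosage and homolog balance

Per chromosome/haplotype, mean density pools all reads (total passing calls
/ total candidate positions within sub-CDRs) so that read depth cancels;
the dosage proxy is density × aggregate sub-CDR length. A companion
coverage metric (summed read-base coverage of sub-CDRs) is reported as
`read_coverage_bp`; the source protocol mentions a per-chromosome read
length metric without defining it, and this coverage-length analog is an
explicit interpretation. Homolog concordance reports Pearson r and the MSE
from y = x; maternal − paternal residuals are standardized against their
own mean and population (n-denominator) SD, and |z| > 3 flags outliers.
Zero residual variance leaves z undefined and flags nothing.

## HOR haplotype structure

Pairwise Hamming distances over aligned, equal-length units count a gap as
a fifth symbol (switchable to dropping gap-containing columns); the source
does not specify gap handling. Ward-linkage clustering of the distance
matrix is cut to exactly k clades; k is a required user parameter because
the published choice ("optimal regionalization") was made by inspection.
Labels are renumbered by first occurrence along the array for determinism.
Per-clade divergence is the mean pairwise Hamming *fraction* (scale-free;
the source does not say fraction vs count), with the lowest-divergence
clade called youngest; singleton clades are excluded from the ranking.

The superHOR scan finds, for each n = 2–9, maximal periodic regions (runs
of positions whose label equals the label n steps ahead) and reports one
hit per region with the largest whole-repeat count ≥ 3. Patterns whose
minimal internal period is shorter than n are suppressed by default (a
(1,2,1,2) 4-mer is really a 2-mer; it is reported at period 2), with a raw
unsuppressed mode available since the original script's behavior on this
point is unknown.

The CDR–age question uses the one-sided exact binomial test: P(X ≥ k) for
X ~ Binomial(n, expected younger fraction).

Local identity smoothing averages, for each window, up to two neighbors on
each side (self excluded, following "closest neighbors"; switchable),
truncated at array ends, and attaches the color floor (fixed 90% or the
10th percentile) as metadata. The CDR-homogeneity permutation test
statistic is the length-weighted mean smoothed identity over CDR bases; the
null re-places the CDR-length blocks uniformly at random without overlap
(order preserved, continuous placement via sorted uniforms in the free
space). The original test's null is not described, so this reconstruction
is labeled as such in the output metadata. p = (1 + #{null ≥ obs})/(N + 1),
with ties counted against the alternative.

## Synthetic data: what it emulates, and what it does not

The generator plants known structure at the study's stated conditions:
LCL-like arrays at ~60% baseline mCpG with dips to 10–25% (per-CpG noise SD
10 pp, reflecting the scatter of per-CpG percent calls at modest read
depth), iPSC-like arrays at ~90% with shallow dips to ~60%, 2–9 sub-CDRs of
16–40 kb per array, read lengths on the tens-of-kb scale (mean 50 kb;
200 kb for co-occupancy scenarios, matching the 100 kb+ ultra-long tail),
and 6mA detection probabilities of 0.2 inside planted CENP-A domains vs
0.005 outside. CpG positions are a jittered 25 bp lattice rather than
sequence-derived, and 6mA candidate positions sit on a fixed 4 bp lattice,
because no downstream computation needs nucleotide context. Default array
length is 1 Mb — within the real active-array size range, small enough for
desk-scale suites.

Deliberately *not* simulated: nanopore signal and basecalling error,
alignment and mappability artifacts, satellite sequence structure at the
nucleotide level, antibody efficiency variation between molecules, and
correlated (bursty) modification noise. Passing recovery tests therefore
demonstrates that the algorithms are correct and calibrated under clean,
known-truth conditions with realistic geometry and noise magnitudes — not
that the pipeline is robust to mapping bias or chemistry artifacts in real
centromeric data.

## Evaluation problem sizes

The packaged experiments (`cenchrom.evaluation`, also run by
`scripts/acceptance.py`) use 50 synthetic 1 Mb arrays for sub-CDR recovery,
500 train + 500 test reads for classifier accuracy, 100 trials for clade
recovery (divergence separation ≥ 5× within-clade), 100 seeds × 24
chromosomes for outlier calibration, and 500 permutation tests of 199
permutations each for null uniformity — sizes chosen so the full suite
completes in seconds while keeping Monte-Carlo error well below the margins
being tested.

## Known limitations

* The caller's boundary resolution is bounded by the window/step geometry
  (~half a window); sub-kb boundary shifts are invisible.
* The LCL preset automates what was originally a manual annotation; on real
  LCL tracks its calls approximate, not reproduce, hand curation.
* The stump threshold is a single global cut; it ignores read length and
  per-molecule efficiency covariates.
* `mean_over`, `bridge_invalid`, gap handling in Hamming distance, the
  overlap floor in matching, and the background buffer are intent-ambiguous
  points in the source procedure; each is a documented parameter rather
  than a guess baked in.
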