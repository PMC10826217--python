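# Methods

This note records the model behind each pipeline stage, the parameters that
matter, the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not establish.

## Signal model

The caller operates on a binned read-depth (RD) profile: the per-base
coverage of a chromosome averaged over non-overlapping windows of
`bin_size` bases (default 1,000 bp). Under the standard RD assumption the
expected depth of a bin is proportional to its copy number, so a diploid
genome produces a piecewise-constant signal at the fold-coverage with
plateaus displaced by c/2 inside CNVs of copy number c, plus counting
noise. A 1 kb bin makes typical CNVs of 3–50 kb span 3–50 bins — large
enough to segment, small enough to localize boundaries usefully.

Bins overlapping unassembled reference sequence are removed before analysis
(default: any N base masks its bin; the threshold is configurable). The
boolean mask over the original bin grid is retained so all emitted
coordinates refer to the reference, and masked gaps inside a called
variant are spanned. GC bias is corrected by stratum rescaling: bins are
grouped by GC percentage (1% resolution) and each bin is multiplied by
(global mean RD)/(stratum mean RD). Strata with fewer than
`min_gc_stratum = 10` bins are left uncorrected, as their stratum mean is
too noisy to be a correction factor. This correction is exactly
mean-preserving when every stratum is corrected.

Read counting: a read contributes 1 to every reference position covered by
its aligned span; secondary, supplementary and duplicate-flagged alignments
are excluded by default. A trailing partial bin is dropped rather than
padded, avoiding one systematically biased value per contig. Chromosomes
are processed independently throughout, which avoids cross-chromosome
normalization artifacts at the cost of re-estimating the neutral depth per
chromosome.

## Segmentation

At every interior boundary the segmenter compares a right-sided robust mean
anchored just after the boundary with a left-sided one anchored just
before:

    Diff_i = u_i^right − u_{i−1}^left,
    u^right_i = Σ_m ω_{m,i} r_m / Σ_m ω_{m,i},
    ω_{m,i} = exp(−Σ (r_j − r_{j−1})²)  (sum along the path from anchor i to m)

The anchor's own weight is exactly 1 (the accumulated sum starts strictly
after the anchor), and the accumulated exponent is monotone along the path,
so the weight sequence is nonincreasing. Window accumulation stops at
`k = 50` points or when the weight falls below `w_min = e^{-10}`; the
monotonicity makes "stop early" equivalent to "drop all points below
`w_min`", which is what allows the whole Diff profile to be computed with
O(N·k) vectorized work and is why runtime is linear in N for fixed k.

**Kernel bandwidth.** The weight exponent is scale-dependent: on raw depth
(≈30 at 30x) every weight would vanish, and the right operating scale
varies with coverage. The profile is therefore first divided by its global
mean, then rescaled so that a robust estimate of its per-bin noise — the
median absolute successive difference divided by 0.6745·√2 — lands at
`noise_target = 0.15`. Noisy low-coverage data thus get wider,
more-averaging windows and clean high-coverage data get sharper ones, with
the rescaling capped at `scale_max = 4`; (near-)noiseless profiles receive
the cap, which makes any jump ≥ 1 (after mean-normalization) cost exponent
≥ 16 and truncates windows exactly at breakpoints. The target 0.15 was
chosen by scanning the bandwidth on simulated data across 2x–10x coverage:
detection quality is flat across targets 0.12–0.18, while a fixed scale
trades low-coverage sensitivity against high-coverage sharpness (mean F1
0.86 vs 0.96 at scale 1.0, 0.90 vs 0.81 at scale 0.35, against 0.91/0.98
for the adaptive default). Everything downstream of breakpoint detection
uses the original, unnormalized values.

Candidate boundaries are positions where Diff leaves the wide boxplot fence
(Q3 + 3.5·IQR above, Q1 − 3.5·IQR below; quartiles by linear
interpolation). Maximal runs of consecutive candidates are reduced to the
position of the run extremum (leftmost on ties), one breakpoint per run.
The fence comparison uses an absolute tolerance of 1e−9 relative to the
Diff scale so floating-point dust cannot fire when the IQR collapses to
zero on noiseless data. The bin at a breakpoint starts the right-hand
segment.

## Classification

Segments are clustered into RD categories by greedy agglomeration: all
current categories are compared with a two-sided Welch t-test on their
pooled per-bin values (computed from exact pooled summary statistics), and
the pair with the largest p-value is merged while that p-value exceeds
`alpha = 0.05`. Non-significance is not transitive, so some aggregation
rule is unavoidable; merging the most-similar pair first and re-testing
against the pooled class is deterministic and conservative. Segments with a
single bin cannot be tested and are attached to the category with the
nearest mean; two zero-variance classes merge only if their means agree to
1e−9.

Each category C_i carries the mean u_i of its pooled values and the
probability p_i = n_i/n counted over *segments* (not bins) — the natural
weighting when the downstream threshold operates on the category
histogram. The copy-neutral depth u_normal is the u of the category with
the largest number of bins (ties: closest to the global mean) — the
diploid state dominates genomic mass, making the mass-weighted mode a
robust estimator.

Distances x_i = |u_i − u_normal| are sorted ascending with probabilities
co-permuted. Before thresholding, every distance above the mean distance is
clamped to the mean (**extreme-value suppression**). Gains can reach much
larger amplitudes than losses (copy 4+ versus at most a 2-copy deficit),
skewing the distance distribution the way uneven lighting skews an image
histogram; the clamp only affects values near the extreme and keeps the
array sorted. It is a single-pass operation — applying it twice clamps
further, because the clamp lowers the mean itself.

The Otsu criterion then scans k = 1..m−1 over the sorted categories and
maximizes the between-class variance, computed in the closed form
σ²(k) = (μ_T·ω(k) − μ(k))²/(ω(k)(1−ω(k))) with ω, μ the cumulative
probability and probability-weighted distance. Splits where one class has
zero probability are skipped (the denominator vanishes); ties take the
smallest k; if the maximal σ² is 0 (all distances equal — e.g. a single
category, or every category at the neutral depth) nothing is declared
abnormal. Categories beyond the split are abnormal; each of their segments
becomes a call, typed `gain` if the category mean exceeds u_normal and
`loss` otherwise, with adjacent same-type calls separated only by masked
bins merged. Note that with two or more categories at genuinely different
distances the Otsu split *always* declares the far side abnormal — on a
profile with no true CNVs this is usually prevented by the t-test stage
collapsing everything into one category, but a contaminated or wavy profile
can still yield spurious calls; there is no per-call significance score
(a known limitation, as is the single shared threshold for gains and
losses).

## Simulator

The simulator emulates the experiment at the binned-depth level rather than
generating reads: per-bin counts are Poisson with mean
`bin_size · coverage · (c/2) / read_length` (c = length-weighted mean copy
number of the bin, 2 outside events), and RD = count · read_length /
bin_size, so neutral bins average the fold-coverage and a homozygous
deletion is exactly zero. Defaults mirror the benchmark design the package
targets: events drawn uniformly in 3,000–50,000 bp with copy numbers
{0, 1, 3, 4}, placed uniformly with at least one bin between events (so
each bin is attributable to one event) and a 10-bin margin from the
chromosome ends; coverages of interest 2x/6x/10x; 100 bp reads; seeded
`numpy` Generator throughout, so every profile, benchmark row and output
file is reproducible from the seed. A negative-binomial option
(`dispersion`) provides over-dispersed counts.

What the simulator does *not* model: GC bias (available to inject only when
testing the corrector), mappability and alignment artifacts, read-level
errors, breakpoint micro-homology, or replication-timing waves. Passing
benchmarks here therefore demonstrates the statistical machinery —
segmentation accuracy against counting noise, threshold placement,
coverage robustness — not robustness to real-library artifacts; results on
real BAMs will depend on the quality of the GC correction and the absence
of unmodelled waviness.

Scoring is position-wise, each genomic position counted once:
precision = TP/PP, sensitivity = TP/P, F1 their harmonic mean, where TP is
the number of positions shared by declared and true CNVs, PP the positions
declared, and P the positions true. Type-agnostic by default;
`--match-type` restricts TP to type-concordant positions. An empty call set
has precision 0 by convention.

## Benchmark scale and expected numbers

The stock benchmark (`scripts/acceptance.py`, and the 2x acceptance test)
uses ten replicates of a 30 Mb chromosome with twenty events — small enough
to run in seconds on one core, large enough that the neutral background
dominates (~98% of bins) and per-replicate F1 varies by only a few points.
At these settings the pipeline averages F1 ≈ 0.93 at 2x and ≈ 0.97–0.98 at
6x/10x; boundary localization at bin resolution (events are not
bin-aligned) accounts for most of the remaining gap to 1.0 at high
coverage. Sub-10 kb heterozygous events at 2x are the dominant source of
missed calls — their boundary Diff signal sits near the boxplot fence.

## Degenerate inputs and numerical conventions

- Profiles shorter than 2 bins: one segment, no breakpoints; empty
  profiles are rejected by the estimators and skipped with a warning by
  the CLI.
- A constant profile yields a zero IQR fence; the absolute fence tolerance
  prevents spurious candidates.
- Zero-mean (all-zero) profiles skip mean-normalization.
- Quartiles use linear interpolation; all tie-breaks (run extrema, Otsu k,
  t-test pair selection) resolve to the smallest index, making the whole
  pipeline byte-deterministic for a given input and parameter set.
- Coordinates are 0-based half-open internally, 1-based inclusive in TSV
  output, 0-based half-open in BED output.
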