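# Methods

This note documents the models, estimators and numerical choices behind
`cghcompare`, and what the synthetic cohorts do and do not establish.

## Kernel-smoothed estimates (KSE)

Each aCGH profile is a vector of log2 ratios a_i at probe genomic
midpositions x_i (~1 Mb spacing on a BAC/PAC-style platform). The smoothed
profile is a Nadaraya–Watson estimator with a truncated Gaussian kernel:

    KSE(x) = Σ_i a_i K(x − x_i) / Σ_i K(x − x_i),
    K(d)   = exp(−d² / 2σ²) for |d| ≤ 2σ, else 0.

The nominal kernel width W (default 20 Mb, the scale at which smoothed
curves track ~1 Mb BAC data well) is interpreted as total effective support:
σ = W/4, truncation at 2σ. The original kernel-convolution tooling for this
analysis does not publish whether its convolution is locally normalized; we
chose the normalized form deliberately, because it keeps KSE in log2-ratio
units, which is what makes a fixed cutoff grid (0.02–1.00) on SD-1
normalized data interpretable. Kernels never cross chromosome boundaries;
grid positions with zero kernel mass (no probes within 2σ on that
chromosome) are reported absent (NaN). The evaluation grid is regular within
each chromosome (default step 100 kb, required ≤ W/4 so the kernel is
resolved) and the probe→grid weight matrix is precomputed sparsely, making a
permutation re-smoothing a single sparse mat-vec.

Group-level gains and losses curves smooth the probe-wise group means of
max(a, 0) and min(a, 0) respectively; with the shared probe layout this is
identical to pooling every tumor's kernels and normalizing locally.

## Single-group significance

The null permutes each tumor's log2 ratios across probe positions
independently, preserving per-tumor value distributions while destroying
genomic structure. The gain threshold is the (1 − α) quantile of the
genome-wide maximum of the null gains curve (losses analogously on minima),
i.e. a family-wise control over the genome at level α per tail (default
α = 0.05, 1000 permutations). Under pure noise, the chance that any gain
interval is called is ≈ α; the test suite verifies this calibration by
simulation.

## Between-group comparison

Each tumor is smoothed individually (signed, gains and losses together); at
each grid position x the two groups' KSE values give

    SNR(x) = (μ_A(x) − μ_B(x)) / (σ_A(x) + σ_B(x) + ε),

with population standard deviations and ε = 1e-8 guarding degenerate
positions. The denominator is the sum-of-SDs form standard for
signal-to-noise statistics in class-comparison genomics; the source analysis
names the statistic without printing a formula.

Significance: class-label permutations (default 6000; reproducible seed;
when fewer distinct assignments exist the sampler draws with replacement and
warns) generate null SNR curves. For a candidate threshold t (scanned over
the observed values of each tail separately),

    FDR(t) = E_perm[#null grid points ≥ t] / max(1, #observed ≥ t),

and the threshold is the smallest t with FDR(t) ≤ 0.05 (+∞ when none
qualifies — no calls). Positive and negative tails are thresholded
separately because gains and losses are displayed and interpreted
separately; whether the original tool used one two-sided or two one-sided
thresholds is not recoverable, so this is a documented choice.

Supra-threshold runs (runs separated by ≤ 1 grid step merged) become
differential regions. A region's carrier group is the group whose mean KSE
inside has the larger magnitude — not simply the side of the SNR sign,
because a loss specific to group B raises group A's *relative* signal; the
region's direction is the sign of the carrier's mean. Peaks are
plateau-aware local maxima of |μ_A − μ_B| inside the region, reported in Mb
(signal units rather than SNR units, so peak positions are comparable
across comparisons).

Interval intersections of same-direction regions from two comparisons carry
both comparisons' peaks; peaks falling outside the overlap are retained but
flagged, mirroring the typographic convention of the published region table.

## CNA burden

Each tumor's signed KSE curve is swept over symmetric cutoffs t
(default 0.02–1.00, step 0.02, matching the cutoffs quoted in the source
results). The counting unit is the aberration peak: a plateau-aware local
maximum above +t, plus local minima below −t, never spanning chromosomes.
An earlier draft counted supra-threshold *runs*, but run counts are not
monotone in the cutoff (one run splits in two as t rises past a saddle),
which breaks the exact per-sample monotonicity the sweep is meant to have;
peak counts are exactly non-increasing in t. On z-scaled data the low end
of the cutoff grid counts many small smoothed-noise peaks; these inflate
all groups equally, so group contrasts emerge at the cutoffs where genuine
segment peaks dominate. Group medians are reported (the source figure plots
medians) while group means are compared with Welch's two-sided t-test per
cutoff (the source legend describes a two-sided t-test on averages);
reporting both satisfies both descriptions. Groups with fewer than two
samples yield no p-values.

## Clustering

Tumors are summarized by the mean KSE over each region of a fixed region
set (e.g. the published differential regions, or the simulator's truth
segments). Distance is 1 − Pearson r between feature vectors; linkage is
complete; leaves are ordered by SciPy's optimal leaf ordering; the tree is
cut into two branches and per-group branch composition tabulated. Regions
are clustered identically on the transpose. The branch partition — not the
leaf order, whose historical algorithm in the original GUI tool is unknown —
is the tested contract. Zero-variance feature vectors are an error naming
the offending sample.

## Cross-platform normalization and merging

DNA from FFPE tissue yields systematically wider log2-ratio distributions
than fresh-frozen DNA. Each platform's pooled values (all probes × all
samples of that platform) are z-scaled to mean 0, SD 1 — a single affine map
per platform, so within-platform structure, including between-tumor burden
differences, is untouched. Per-sample scaling would destroy exactly those
differences and is deliberately not offered. Scaling precedes
duplicate-tumor removal when merging cohorts (the order is unstated in the
source; scaling first uses all available data to estimate the platform
moments). Loading drops probes with > 20% missing values and imputes the
rest with the sample's per-chromosome median (the source is silent on
missing data; this policy is ours). Coordinates are 0-based half-open bp
internally; reports use Mb with two decimals.

## TP53 mutation classes

The token grammar, in match order: "wild type" / "NA"; splice (any token
containing "splice" or "IVS"); amino-acid substitution R⟨codon⟩A (alt "X" =
nonsense, else missense; spaces tolerated, "V216 M"); nucleotide indel with
codon anchor (⟨codon⟩[ _⟨codon⟩ ] ins/del ⟨payload⟩ — frameshift iff payload
length mod 3 ≠ 0); codon-range deletion ("del 155-156", "155_156del") =
in-frame deletion. Comma-separated cells yield one record per token;
unparseable tokens raise with the token text, never skip silently.

Complex (typically protein-truncating) = nonsense, frameshift, splice, or
in-frame indel. Hotspot = missense at one of the 29 recurrently mutated
codons (K132 … E285). The packaged table's printed per-sample hotspot flag
disagrees with that codon list for a few rows (e.g. I195T, Q286K, V216M,
P177L flagged); the flag is stored but the codon list is authoritative here.
Deleterious-missense status is an externally supplied prediction flag
(SIFT-style), consumed as data — the predictors are out of scope. Group
summaries count tumors, never mutations; tumors without sequence data are
excluded from denominators; a mutation counts only if its estimated
abundance exceeds 25% or is unknown (the packaged table predates the filter,
so its abundances are unknown-and-passing).

Fisher exact tests are two-tailed in the min-likelihood convention (sum of
hypergeometric probabilities ≤ the observed table's, tolerance 1e-12);
a zero margin gives p = 1. One published p-value (7×10⁻³) is reproducible
only under the doubled-one-sided convention on the table as printed (whose
denominator conflicts with the stated number of sequenced tumors); the test
suite documents this reconstruction explicitly.

## Synthetic cohorts: scope and limits

The generator emulates the study's platform and design: ~1 Mb probe spacing
over Hg18-like chromosome lengths (22 autosomes + X, ~3.0 Gb, ~3,000
probes — comparable to the 3,500-clone array; probe positions jittered
uniformly), segmental CNAs with group-specific penetrance, a single
tumor-cell fraction per tumor scaling all its aberration amplitudes
(U(0.5, 1) by default), i.i.d. Gaussian probe noise (sd 0.15 by default —
the study reports no probe-level noise magnitudes, so this is a free
parameter chosen once as typical BAC-array scatter), and a multiplicative
platform scale (FFPE 1.5 × frozen) reproducing the wider FFPE distributions.

Not modeled: GC/wave artifacts, segmentation breakpoint uncertainty below
probe resolution, correlated noise, sex-chromosome dosage, and real CNA
length/amplitude distributions. Passing calibration and recovery tests on
these cohorts therefore establishes that the estimators behave correctly
under the stated noise model — not that the published regions would be
reproduced from the original arrays, which were never deposited.

## Problem sizes used in tests

The statistical test battery runs on scaled-down genomes chosen so each
property is measured with adequate replication: 2–4 chromosomes of 150 Mb
at 1 Mb probe spacing and a 1 Mb grid, 20-vs-20 tumors, 500 class-label
permutations with 50 replicates for FDR calibration and spike-in recovery,
120 replicates (100 permutations) for single-group calibration, and 25
replicates for clustering separation. The full-genome defaults
(100 kb grid, 6000 permutations) are exercised end-to-end by the analysis
drivers and the pipeline smoke test.
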