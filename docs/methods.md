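# Methods

## Scope and data model

All analyses operate on a `FeatureTable` (samples × features, absolute
counts or relative abundances; rows of a relative table sum to 1 within
1e-9) joined to a `SampleMetadata` frame (subject, age group, integer time
point 1..T, optional age and per-event before/after status). Tables are
plain TSV with a header row; both samples-in-rows and features-in-rows
layouts are read, the internal canonical form being samples × features. A
5-column read-mapping table (read, sample, ORF, function, taxon) supports
per-ORF taxon-contribution percentages, with unannotated reads pooled under
the reserved label `UNASSIGNED` rather than dropped.

## Taylor's power law

For one subject, relative-abundance temporal moments per feature are the
mean μᵢ and SD σᵢ (denominator n−1) over that subject's time points (≥ 3
required). The power law σ = V·μ^β is fitted by unweighted OLS of log₁₀σ on
log₁₀μ; β is the slope (invariant to the log base) and V the
back-transformed intercept, with delta-method standard errors and R²
reported. Features with μ = 0 or σ = 0 are excluded — their logarithm is
undefined — and a fit requires at least 20 usable features (configurable).
The law is stated on the SD scale, so β = 1/2 corresponds to Poisson-like
and β = 1 to exponential-like fluctuation.

Cohorts are compared after z-scoring V and β against a reference group
(mean/SD with n−1): the reference group then sits at the origin with unit
spread. Coverage regions at 68% and 98% are bivariate-normal ellipses at the
χ²(2) quantile of the requested coverage, using the reference points' sample
mean and covariance. They are ellipses, not circles: covering a 2-D point
cloud requires its covariance, and the two axes are already on comparable
(standardized) scales.

## Rank stability index

At each time point the unit's features are ranked by abundance, rank 1 most
abundant, ties broken deterministically by ascending feature identifier (so
zeros tie at the bottom in a reproducible order). A feature's displacement
is D = Σₖ|rank(k+1) − rank(k)|, maximal at (N−1)(t−1) for a rank
oscillating between the extremes, and

    RSI = (1 − D / ((N−1)(t−1)))^p .

The exponent defaults to p = 1 and is exposed as a parameter. RSI is
computed per subject (each subject's own series) or per group (relative
abundances averaged across the group's subjects at each time point);
features never observed within a unit are excluded from that unit's ranking
— they carry no dynamics — and marked missing in the aligned output.
Profiles are compared by PERMANOVA on pairwise Euclidean distances with
missing features excluded pairwise.

## Beta diversity, ordination and PERMANOVA

Jaccard similarity is computed on presence sets (presence = abundance above
a configurable threshold, default 0) and converted to distance 1 − J in
matrices; Bray–Curtis on abundances. PCoA Gower-centers −d²/2 and
eigendecomposes; coordinates come from positive eigenvalues only, while
negative eigenvalues of semimetric inputs are reported so the user can judge
the embedding distortion.

PERMANOVA uses the distance-based decomposition SS_total = Σ_{i<j}d²ᵢⱼ/n,
SS_within = Σ_g Σ_{i<j∈g}d²ᵢⱼ/n_g, pseudo-F = (SS_between/(a−1)) /
(SS_within/(n−a)), with the p-value from seeded random label permutations
(600 by default) under the +1 convention — the observed statistic counts
among the permutations, so p ≥ 1/(n_perm+1) and p can never be 0. An
exhaustive mode enumerates all distinct label arrangements for small n.
Labels are permuted freely: the intended inputs are one row per subject
(median-aggregated profiles or RSI profiles), where no repeated-measures
structure remains.

Consecutive-pair stability takes, per subject, the Jaccard similarity of
every adjacent time-point pair. A missing time point breaks adjacency (no
pair is formed across a gap) — "consecutive" is read literally rather than
bridging to the next available sample. Interval comparisons use
Mann–Whitney in two separately FDR-corrected families: within one group
between intervals, and between groups at the same interval.

## Alpha diversity and event splits

Shannon entropy is in nats (the base is a convention; nats are the default
of the underlying log). Chao1 uses the bias-corrected form
S_obs + F1(F1−1)/(2(F2+1)), defined also when no doubletons exist, and is
restricted to integer counts. Diversity is computed on raw counts by
default; a rarefy-to-minimum-depth option (seeded) exists but is off, since
depth normalization choices are study-specific. First-vs-last time point
changes are tested per group by Wilcoxon signed-rank on per-subject
differences (zeros dropped; an all-zero group is reported as NA) and
between groups by Mann–Whitney on the same differences, with
Benjamini–Hochberg correction across the whole family. Small-sample exact
p-values are used when the underlying implementation can (no ties, small
n); otherwise normal approximations with tie and continuity corrections.

Event splits aggregate each subject's samples to median relative-abundance
profiles before and after the event (subjects represented on both sides
only, at least 3 required). Median rows are re-normalized to sum to 1 —
per-feature medians of compositions generally do not, and downstream
distances assume compositional rows. PERMANOVA on the aggregated rows with
before/after labels tests the compositional shift; Mann–Whitney on
per-sample Shannon and Chao1 tests the diversity change.

## Synthetic cohort generator

The generator produces the data structure the analyses assume: three groups
(12 toddlers, 13 adolescents, 35 adults by default) × 10 time points,
300 taxa, 100,000 reads per sample, a taxa→function incidence map
(100 functions, mean redundancy 3) projecting taxonomic counts onto a
functional table exactly.

**Abundance structure.** A cohort-level template profile is drawn
log-uniform over [3e-6, 3e-2] (≈ 4 decades, spanning expected counts ~0.3
to ~3000 at default depth so that presence/absence genuinely fluctuates at
the rare end); each subject deviates from the template log-normally
(log-SD 0.6), giving subjects individual but correlated compositions, as in
real cohorts sharing a core microbiota.

**Fluctuation: balanced profiles.** Each feature's temporal trajectory is
its mean trajectory times a *balanced* fluctuation profile: a non-negative
length-t pattern with exact sample mean 1 and exact sample SD equal to the
target CV, randomly arranged in time. For moderate CV the pattern is a
standardized Gaussian shape; where that would go negative, a spike pattern
(k elevated values, t−k depressed, exactly zero at the feasibility edge) is
used. Target SDs follow σ = V·μ^β at the subject's (V, β) — group values
with 8% between-subject log-jitter — after subtracting the expected
multinomial counting variance at the sequencing depth, so the *observed*
relative abundances realize the prescribed law. Counts are multinomial
draws per time point.

This construction is deliberate: the generator's contract is that each
subject's realized mean–SD relation matches (V, β), which makes parameter
recovery a test of the estimator rather than of sampling noise. Its cost is
realism — real trajectories have serial autocorrelation, heavy-tailed
bursts and sampling-induced moment noise that balanced profiles do not
emulate, so passing recovery tests here does not bound estimator error on
real data with few time points.

A hard constraint applies regardless of mechanism: the sample CV of n
non-negative values is at most √n, so target CVs above √t (e.g. β = 0.5
with sizeable V at rare features) are capped at the spike-profile bound.
Combinations demanding CV > √t over much of the abundance range cannot be
realized by *any* non-negative generator at t time points; the recovery
grid's (V ≥ 0.2, β = 0.5) corner is in that regime, which is why recovery
quality is summarized by grid-wide medians.

`simulate_taylor_subject` (the single-subject entry point used for
parameter-recovery studies) defaults to means log-uniform on [1e-3, 3e-2]:
the regime where biological variance dominates sequencing noise at the
default depth, i.e. where the law is measurable at all.

**Study-condition features.** Toddlers carry an instability window at
T1→T2: the T1 mean composition is replaced by an independent draw
(an immature, pre-succession community), fluctuating and tilted like its
neighbours so evenness statistics are unaffected while presence overlap
with T2 collapses. Three quarters of toddlers undergo a weaning-like event
at a uniformly drawn interior time point (the rest enter already weaned):
before the event their mean profile is tilted by exponent 2.2 (rich get
relatively richer — lower Shannon and detected richness), after it the
cohort-shared log-normal shift (log-SD 0.6) is applied, the same taxa
rising or falling in every subject so the compositional change is
detectable across subjects. These defaults yield a toddler Shannon T1→T10
increase of about +1 nat and group-level patterns qualitatively matching
the emulated cohort; the remaining magnitudes (group V of 0.35/0.18/0.15,
β of 0.75/0.85/0.85) are round values chosen once for plausibility and
testability, as no empirical effect sizes are available for them.

## Numerical choices and degenerate inputs

- Medians use the midpoint convention for even sample counts.
- Rank ties: descending abundance, then ascending feature identifier.
- Permutation p-values: +1 convention; ties with the observed statistic
  count as ≥ (with a 1e-12 float guard).
- Degenerate inputs raise rather than warn: all-zero samples in
  normalization, both-empty pairs in Jaccard/Bray–Curtis, all-zero
  difference vectors in Wilcoxon, zero reference spread in
  standardization, rank-deficient covariance in coverage regions.
- Units with a single time point, subjects missing an endpoint, and test
  cells with < 2 observations are skipped with warnings, not errors.

## Problem sizes used by the test suite

The suite exercises scaled-down cohorts (6/6/10 subjects, 150 features,
depth 30,000) for structural and qualitative checks; power-sensitive
between-group claims use the full group sizes (12/13/35). Simulation-based
calibration checks use 50 seeds at 200 features × 10 time points (scale
index recovery), 50 × 100 subjects (coverage), 2,000 replicates
(rank-test null uniformity at sample sizes where the discrete null p-value
support is effectively continuous; exact small-sample p-values are
super-uniform by construction, and there the empirical size is verified
against the nominal level instead), and 500 × 99 permutations (PERMANOVA
null uniformity).

## Known limitations

- No phylogeny-aware metrics (UniFrac needs a tree the data model does not
  carry), no ordination biplots, no mixed-effects trend models.
- PERMANOVA offers no blocking/strata; applying it to repeated-measures
  rows without prior per-subject aggregation inflates significance.
- The generator does not model taxonomic identity, phylogeny, primer bias,
  compositional correlations beyond the shared template, or serial
  autocorrelation.
- Chao1 on unrarefied counts depends on depth; comparisons across samples
  of very different depth should use the rarefaction option.
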