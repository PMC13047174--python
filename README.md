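# microdyn

Longitudinal stability analysis of gut-microbiome time series.

Cohort studies that sample the same subjects repeatedly — for example
toddlers, adolescents and adults followed over several years at ten time
points — ask not only *what* a microbiota looks like but *how much it moves*.
`microdyn` implements the statistical toolkit for that question on ordinary
feature tables (ASV-level taxonomic tables or TIGRFAM-style functional
tables, samples × features, as plain TSV):

- **Taylor's power-law variability.** For one subject, each feature's
  temporal mean μ and temporal SD σ of relative abundance obey σ = V·μ^β.
  The amplitude *V* is the dispersion a hypothetically dominant feature
  (relative abundance ≈ 1) would attain — small *V* means a quiet community —
  and the scale index *β* characterizes the fluctuation regime (β = 1/2
  Poisson-like, β = 1 exponential-like). Per-subject (V, β) are estimated by
  OLS of log₁₀σ on log₁₀μ, standardized against a reference group, and
  compared in a z-scored parameter space with 68%/98% bivariate-normal
  coverage regions.
- **Rank stability index.** Features are ranked by abundance at every time
  point; with total rank displacement D across consecutive time points,
  RSI = (1 − D/((N−1)(t−1)))^p ∈ [0, 1] — 1 for a feature whose rank never
  changes, 0 for one oscillating between the extremes. Per-subject RSI
  profiles feed a PERMANOVA asking whether age groups differ in *how*
  stability is distributed across features.
- **Consecutive-pair Jaccard stability.** The fraction of features shared
  between a subject's adjacent time points, at taxonomic and functional
  level, with Mann–Whitney comparisons within groups (between intervals) and
  between groups (same interval), FDR-corrected.
- **Diversity trajectories and event splits.** Shannon (nats) and
  bias-corrected Chao1 per sample; paired first-vs-last time point tests
  (Wilcoxon within group, Mann–Whitney between groups); before/after
  aggregation around a per-subject event such as weaning, tested by
  PERMANOVA on median profiles plus diversity tests.
- **Permutation machinery.** PERMANOVA (pseudo-F from distance sums of
  squares, seeded label permutations, 600 by default, exhaustive enumeration
  for small n), PCoA with Gower double-centering that reports negative
  eigenvalues, Benjamini–Hochberg FDR.
- **A synthetic cohort generator** that emulates the cohort structure the
  analyses assume — group-specific (V, β), ten time points, sequencing depth,
  taxa→function redundancy, an early toddler instability window, a
  weaning-like event — so every stage is testable without external data.
  See `docs/methods.md` for the generative model.

## Worked example

```python
from microdyn import (SyntheticConfig, simulate_cohort, fit_cohort,
                      standardize_params, reference_region, rsi_profile,
                      rsi_distance_matrix, permanova, consecutive_stability,
                      alpha_series, paired_endpoint_difference)

cfg = SyntheticConfig(n_subjects={"toddler": 6, "adolescent": 6, "adult": 10},
                      n_features=150, n_functions=50,
                      sequencing_depth=30_000, seed=11)
cohort = simulate_cohort(cfg)

fits = standardize_params(fit_cohort(cohort.taxa, cohort.metadata), "adult")
print(fits.groupby("group")[["V", "beta"]].mean().round(3))
```

```
                V   beta
group
adolescent  0.169  0.785
adult       0.074  0.740
toddler     0.874  0.887
```

Toddlers, simulated as the volatile group with an extra compositional
turnover between T1 and T2, fit with an order-of-magnitude larger *V* than
adults. In the standardized parameter space they fall entirely outside the
adult reference region:

```python
region = reference_region(fits, 0.98, reference_group="adult")
toddlers = fits.loc[fits.group == "toddler", ["z_V", "z_beta"]].to_numpy()
print((~region.contains(toddlers)).mean())   # -> 1.0 (100% outside)
```

The same pattern shows up in every other stability lens. Mean consecutive
Jaccard similarity per interval (first rows shown): the toddler T1→T2 value
collapses to 0.36 against 0.85 in adults, then recovers —

```
group   adolescent  adult  toddler
t_from
1            0.754  0.848    0.356
2            0.731  0.827    0.716
3            0.739  0.836    0.746
```

— RSI profiles separate the groups (`PERMANOVA: pseudo-F = 8.17,
p = 0.0017` at 600 permutations), and toddler Shannon diversity rises by
`+1.13` nats from T1 to T10 (Wilcoxon p = 0.0312) while the other groups
stay flat.

A command-line interface mirrors the library
(`microdyn simulate | diversity | taylor | rsi | stability | permanova |
event | run`); `microdyn run --out dir/` executes the whole pipeline on a
simulated cohort and writes a manifest of every artifact.

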