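# Methods

## The model

A fork triplet (A, B, C) is modelled on the log scale. With
`r = log B − log C` the two-group interaction model is

    y = β₀ + β₁ r + β₂ g + β₃ (r·g) + ε,    g = 0 (control), 1 (treatment)

fit by ordinary least squares, and reversed with the roles of A and r
exchanged. β₁ is the control-condition slope, β₂ the condition offset and
β₃ the slope difference (treatment − control); its two-sided t-test on
`n − 4` residual degrees of freedom is the inferential core. A triplet is a
validated fork only when β₃ is significant strictly below α in **both**
directions. The dual rule exists because the direction of dependence
between A and the ratio is not identifiable from correlation structure;
requiring both regressions to agree is a stringency heuristic, not a causal
claim. The single-model OLS t-test matches what a default `lm` summary
reports; for a single coefficient it is numerically identical to the
partial F-test.

The screen that proposes candidates is deliberately ad hoc: per condition,
the Pearson correlation of A with r, and a pass when the absolute
between-condition difference (delta) is at least 1.2. Delta lives in
[0, 2]; 1.2 demands a substantial sign-flip-like rewiring and, under a
Gaussian null at n = 12/11, is passed by well under 1% of triplets (the
acceptance script measures it — typically 0 in 2,000). Ratios are screened
on the log scale, `log B − log C`, so swapping B and C is a pure sign flip;
enumeration therefore emits one orientation per unordered pair, giving
`m(m−1)(m−2)/2` triplets for m features.

Because the screen selects extreme correlation differences, candidates that
reach the model stage are a biased sample and most of them validate; and
any triplet sharing a member with a genuine fork partially inherits its
condition dependence. Validated forks are consequently read as a *set*
merged by shared membership — connected components over the union of each
fork's 3-clique — rather than as independent discoveries. No multiple-
testing correction is applied on the headline path (Benjamini–Hochberg
columns are available as optional reporting); the dual rule and the screen
are the stringency mechanism.

## Preprocessing

Metabolite non-detects (blank or "NA" cells; zeros count as measured) are
imputed with the compound's minimum observed value, pooled over both
conditions, on the raw scale, before the log transform — the vendor
convention for untargeted metabolomics exports. Transcript tables are FPKM;
since FPKM can be exactly 0, `log(FPKM + pseudocount)` is used with a
default pseudocount of 1 (configurable). The log base (default e) is
irrelevant to every reported statistic — correlations and the t-statistics
of both the interaction and Welch tests are invariant to affine rescaling —
which the acceptance script verifies to ~1e-14.

Differential abundance/expression uses Welch's unequal-variance t-test on
log values for both omics (R's default `t.test` is the same statistic).
The transcript scale (log vs raw FPKM) only affects the DE annotation, not
fork detection.

## Cross-omic triplets

Transcriptome samples are a subset of the metabolome samples; any statistic
involving features from both omics uses the per-triplet (or per-edge)
intersection of samples with observed values for all members, kept in
design order. A minimum of 3 samples per condition is enforced everywhere a
correlation or group fit is computed; triplets failing it are skipped with
a logged reason rather than an error.

## The synthetic generator

`synthetic_data.generate` draws, per planted fork, a per-sample log-ratio
`R ~ N(0, log_sd)`, sets `log A = base + slope_cond · R + N(0, noise_sd)`,
and decomposes R into members via `log C ~ N(base, log_sd)`,
`log B = R + log C`; everything is exponentiated to abundances so the
pipeline's own imputation/log path is exercised. Null features are
independent log-normals; transcripts are FPKM-like exponentiated normals
with a small zero-inflation rate (exercising the pseudocount path).

Defaults mirror the assumed study design and were fixed once: 12/11
metabolome samples, nested 8/8 transcriptome subset, one planted fork with
slopes +1/−1 and noise sd 0.1, `log_sd` 0.5 (so the planted per-condition
correlation is ≈ 0.98 and the expected delta ≈ 1.9), base log-abundance 10
(arbitrary units), 20 null metabolites and 10 null transcripts (keeps full
enumeration at ~16k triplets, seconds on one CPU), metabolite missing rate
0.02, transcript zero rate 0.05.

Two deliberate departures from a fully uniform corruption model: non-detect
masking applies to null metabolites only, and zero-inflation skips planted
transcript members. Min-value imputation of a planted member would inject a
high-leverage outlier and silently corrupt the planted slope, breaking the
generator's core contract that the recorded ground truth is recoverable
(per-condition OLS slopes on near-noiseless data reproduce the configured
slopes to numerical precision — tested). Recovery rates measured with this
generator therefore quantify the detection method, not imputation damage;
robustness of the screen to imputation artifacts on *null* features is
still exercised, but the generator does not emulate non-detects correlated
with abundance, batch effects, or heteroskedastic vendor noise, so passing
tests bound method behaviour only under the idealized log-linear model.

## Numerical choices

- Screening threshold comparison is inclusive (`delta ≥ 1.2`); the model
  rule is strict (`p < α`). Thresholds above 2 are accepted and simply
  screen out everything.
- Zero-variance inputs make a correlation undefined: the triplet is
  skipped and logged, never silently assigned 0.
- Rank-deficient interaction designs (a predictor constant within a group)
  return a flagged degenerate fit; numerically perfect fits
  (`SSR ≤ 1e-12 · TSS`) are flagged `zero_residual`, reported with p = 0,
  and excluded from fork status by default — real data never produces
  them, synthetic edge cases must not crash or auto-validate.
- Both-groups-constant Welch inputs: equal means → p = 1 by convention;
  unequal means → degenerate flag.
- Stage result tables (TSV) print floats at 6 significant digits; circuit
  exports (GraphML/JSON/sectioned TSV) and the processed-matrix checkpoint
  keep full precision and round-trip exactly (the checkpoint reader uses
  round-trip float parsing). The standalone `circuit` command re-derives
  screen statistics from the matrix so exported circuits are identical to
  the orchestrated run's.
- All enumeration, merging and serialization orders are canonical
  (lexicographic), so identical inputs and config give byte-identical
  outputs.

## Study problem sizes

Replicate studies use 2,000 null replicates for type-I calibration, 200
replicates for recovery, and 200 per point of the power grid
{0.5, 1.0, 2.0} at noise sd 0.5 — at the recovery setting's noise sd 0.1
all grid points saturate at power 1, so the flatter noise level is the one
at which monotonicity is informative. These sizes put Monte-Carlo error
comfortably inside the bands being checked (99% binomial interval around
α = 0.05 at n = 2,000 is ±0.013).

## Known limitations

- The screen's 1.2 threshold and the α = .05 dual rule are heuristics; no
  FDR guarantee is made over the enumerated triplet space.
- Correlation and OLS are linear tools; forks whose rewiring is monotone
  but non-linear will be under-detected.
- Edge direction in circuits is never inferred; causal arrows exist only
  as user-supplied regulator relations.
- Pathway-class subsetting reproduces a funnel (e.g. 600 → ~60 compounds)
  only relative to the annotations provided; no pathway database lookup is
  performed.
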