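# metafork

Discovery of condition-dependent **metabolic forks** from two-condition
metabolome and transcriptome data, and assembly of the validated forks into
regulatory circuit graphs.

A metabolic fork is a branch point at which a precursor pool is split
between two metabolic fates. Operationally it is a triplet (A, B, C) of
metabolites and/or gene transcripts whose coupling between the focal
feature A and the ratio B/C changes between a control and a stress
condition — for example a liver metabolome measured in thermoneutral versus
heat-stressed animals. `metafork` implements the full screen–validate–merge
workflow:

1. **Preprocess** — subset compounds by pathway class (e.g. sulfur, lipid
   and sugar metabolism), impute non-detects with each compound's minimum
   observed value, and log-transform. Transcript FPKM values get a
   pseudocount before the log.
2. **Screen** — for every triplet with distinct members, compute the
   Pearson correlation of A with the log-ratio log(B/C) separately per
   condition and keep candidates with

   `|cor_treatment(A, log B/C) − cor_control(A, log B/C)| ≥ 1.2`.

3. **Validate** — fit the two-group interaction model by OLS in both
   directions,

   `y = β₀ + β₁x + β₂g + β₃(x·g) + ε`  with `g ∈ {0, 1}` the condition,

   once with `y = A, x = log(B/C)` and once reversed. A candidate is a
   validated fork only if the interaction term β₃ (the treatment−control
   slope difference) is significant at `p < .05` (two-sided t-test,
   `n − 4` df) in **both** directions.
4. **Differential abundance** — Welch's two-sample t-test per feature on
   the log scale, used to annotate circuit nodes with direction of change.
5. **Assemble** — validated forks sharing at least one member are merged
   into connected circuit components; edges carry per-condition pairwise
   correlations and the owning forks' interaction p-values, and curated
   regulator genes can be attached with their expression changes.

Mixed triplets are supported: any member may be a transcript (e.g. the
ratio of an enzyme's expression to its substrate metabolite), in which case
statistics use the intersection of samples measured in both omics.

The package also ships a synthetic-data generator that emulates the
two-condition design (12 control / 11 treatment metabolome samples with a
nested 8 + 8 transcriptome subset), plants forks with known per-condition
slopes, and records the ground truth — so the whole pipeline is testable
without any external download.

## Worked example

Simulate a default dataset (one planted fork with slopes +1 / −1 and noise
sd 0.1, 20 null metabolites, 10 null transcripts) and run the pipeline:

```bash
metafork simulate --out demo --seed 7
metafork run-all \
    --metabolites demo/metabolites.csv --expression demo/expression.tsv \
    --design demo/design.tsv --pathway-column pathway_class \
    --out demo/out
```

which prints the filtering funnel:

```
n_features      33
n_triplets      16368
n_screened      16368
n_skipped       0
n_candidates    188
n_forks 180
n_de_significant        1
n_components    1
```

33 features yield 16,368 candidate triplets; 188 pass the 1.2 screening
threshold and 180 of those satisfy the dual interaction rule. The planted
triplet is the top row of `demo/out/forks.tsv` with a forward interaction
coefficient of −2.00 (the planted slope difference −1 − (+1)) and
interaction p-values of 1.7e-13 / 1.4e-13 — compare `demo/truth.json`.
Note that most other validated "forks" involve the planted members: a
triplet sharing B or C with a real fork inherits a condition-dependent
ratio, which is exactly why overlapping forks are merged into one circuit
component rather than read as independent discoveries.

The merged, annotated circuit is written to `demo/out/circuit.graphml` and
`demo/out/circuit.json`; per-stage tables (`screened.tsv`, `forks.tsv`,
`de.tsv`) let any stage be rerun standalone (`metafork screen`,
`metafork model`, `metafork de`, `metafork circuit`).

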