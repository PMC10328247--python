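# Methods

This note records the model implemented by `micfuzzy`, the numerical and
design choices made where the construction was genuinely open, and what
the synthetic validation does and does not establish.

## Model overview

The pipeline treats GRN inference as n independent sub-problems, one per
target gene. All expression values are first min-max normalized to
[0, 1] per gene, pooling all time series (normalization is idempotent;
constant genes map to zero with a warning rather than failing, so
degenerate simulated inputs keep pipelines running). Lagged samples pair
a regulator at time t with a target at t+1 and never cross the boundary
between independent series, so one series of T points contributes T−1
pairs.

### Stage 1: lagged MIC screening

For each ordered pair the maximal information coefficient is computed on
the lagged sample: the maximum over grid shapes X·Y ≤ B(n), X, Y ≥ 2, of
the grid's mutual information normalized by log₂ min(X, Y). Defaults:
α = 0.6 in B(n) = ⌊n^α⌋ (floored at 4 so the 2×2 grid is always
admissible), clump factor c = 15. The budget comparison is inclusive
(X·Y ≤ B(n)); `--grid-strict` switches to a strict bound.

The estimator follows the ApproxMaxMI strategy: per shape, one axis is
equipartitioned (ties never split) and the other is optimized exactly by
dynamic programming over value clumps, in both orientations. Two
implementation details matter:

- The DP exploits the column-additivity of
  H(P) − H(P,Q): each column's contribution depends only on its own cell
  counts, so a quadratic DP over clump boundaries is exact for the
  optimized axis. High-cardinality axes are pre-reduced to at most
  c × max-columns superclumps for speed.
- When the *equipartitioned* axis takes at most 12 distinct values (and
  at most 200 partitions exist), all of its contiguous partitions are
  enumerated instead, making the search exhaustive on low-cardinality
  axes at negligible cost. On continuous data this never triggers and
  the estimator is plain ApproxMaxMI. Consequence: on samples whose x
  takes at most B(n) distinct values the heuristic equals the
  brute-force oracle, and it can never exceed it (every evaluated grid
  is admissible).

An exhaustive oracle (`mic_bruteforce_oracle`, n ≤ 25) enumerates every
admissible grid and anchors the estimator in tests.

Screening keeps, per target, the genes whose MIC into the target is at
least the threshold: the mean of the n−1 incoming scores by default, or
a user-fixed value. The comparison is inclusive, with a 1e−12 slack
absorbing float error in the mean, so the mean mode is never empty on
non-constant data.

### Stage 2: activator–repressor fuzzy model

**Regulatory effect.** A regulator's effect is RRS × expression, where
RRS is its MIC score into the target. The product lives on [0, RRS] for
normalized expression; min-max scaling over that *attainable* range maps
it back to [0, 1]. Two scaling modes exist:

- `independent` (default): each regulator is scaled by its own RRS. The
  RRS then cancels exactly, which keeps the generator/scorer identity
  exact (see validation below) and makes the default pipeline's
  predictions depend only on expression shape.
- `paired`: both regulators of a triplet are scaled by the *larger* of
  the two RRS values, so the weaker regulatory relationship damps its
  regulator's effect proportionally. This is the mode in which RRS is
  consequential and the `--no-rrs` ablation (RRS ≡ 1) differs from the
  full model whenever candidates' MIC scores differ.

We deliberately did not use the empirical min/max of the realized effect
trajectory: that choice distorts trajectories that do not span [0, 1]
and breaks the exact self-consistency between the simulator and the
scorer.

**Fuzzification.** Inputs use three triangular memberships on [0, 1] —
Low (0, 0, 0.5), Medium (0, 0.5, 1), High (0.5, 1, 1) — the unique
uniform triangular partition of unity consistent with the worked anchor
value 0.4 ↦ (0.2, 0.8, 0). Outputs use five uniform triangles VL
(0, 0, 0.25), L (0, 0.25, 0.5), Med (0.25, 0.5, 0.75), H (0.5, 0.75, 1),
VH (0.75, 1, 1). Both layouts are configurable through a flat key-value
file (`micfuzzy/data/default_fuzzy.cfg` reproduces the defaults; run
logs record a SHA-256 digest of the active configuration).

**Rulebase.** The 3×3 matrix (rows activator, columns repressor)
defaults to

|        | rep Low | rep Med | rep High |
|--------|---------|---------|----------|
| act Low | Med | L | VL |
| act Med | H | Med | L |
| act High | **VH** | H | Med |

anchored by the (High, Low) → VH rule and completed as the unique
monotone, antisymmetric completion over five levels (output index
= 2 + activator level − repressor level). Monotonicity — non-decreasing
in the activator, non-increasing in the repressor — is validated at
construction, so alternative matrices can be dropped in safely. Firing
strength of rule (i, j) is min of the two input memberships; each rule
clips its output triangle at its firing strength (Mamdani
min-implication); the aggregate is the bounded sum min(1, Σ clipped).

**Defuzzification.** Centroid over a midpoint discretization of [0, 1]
with step 0.001 (the default resolution keeps discretization error far
below expression noise and makes symmetric aggregates defuzzify to
exactly 0.5). If no rule fires the output falls back to 0.5 with a
warning — impossible under the default partition-of-unity inputs, and
asserted so in tests.

**Pair scoring.** Effects at t−1 predict the target at t (mirroring the
MIC lag), so the first timepoint of each series is never predicted.
MSE divides by the number of predicted points P = Σ(Tₛ − 1) rather than
the raw series length: with stacked series a single "T" is ill-defined,
and any fixed positive denominator leaves the per-target RS ranking
unchanged. A rule counts as fired at a timepoint when its strength
exceeds 1e−9 (binary counts, not strength-weighted); Variance is the
population variance (divide by 9) of the nine counts; RS = MSE ×
Variance, min-max normalized per target into NRS (all-equal RS ⇒ all
NRS 0). Selection keeps pairs with NRS ≤ threshold or the k
lowest-RS pairs (ties broken by activator then repressor gene order,
gene order meaning input-file order throughout). Pairs are selected
first and genes extracted second; a gene appearing in both roles among
kept pairs is assigned the role of its lowest-RS pair, reflecting the
assumption that a gene acts as either activator or repressor for a
given target, not both.

### Evaluation

Confusion counts run over all n(n−1) ordered non-self pairs with signs
ignored (public gold standards are unsigned); sign accuracy against a
signed truth is reported separately. Zero-denominator ratios are
reported as 0 and flagged. SS_mean is not given a standard formula in
the GRN-evaluation literature; it is implemented as the harmonic mean
of sensitivity and specificity with geometric and arithmetic variants
selectable. The combinatorial-reduction percentage compares
Σ m_g(m_g − 1) scored pairs against the unfiltered n(n−1)(n−2).

## Synthetic data

The simulator plants one activator and one repressor per target
(configurable down to one or zero regulators), draws initial values
Uniform(0, 1) per series, and advances regulated genes by the same
defuzzified rulebase used for inference (a missing role enters as 0),
plus Gaussian noise (default sd 0.02) clipped to [0, 1]. Unregulated
genes follow a mean-reverting walk (rate 0.15 toward 0.5) with the same
noise. Datasets are produced directly on the [0, 1] scale and flagged
normalized. Reference conditions for validation: 10 genes, 5 series of
21 timepoints, noise sd 0.02 — the shape of a small in-silico challenge
instance.

Reusing the inference rulebase as ground-truth dynamics makes edge
recovery well-posed and isolates pipeline correctness from model
misspecification; a `linear` dynamics mode
(clip(0.25 + 0.75·a − 0.75·r) + noise) probes behaviour when generator
and scorer disagree. What passing recovery tests therefore shows is
that the machinery — screening, scoring, selection, sign assignment —
is internally correct and noise-tolerant at realistic sizes; it does
not show that real transcriptional kinetics follow a Mamdani rulebase,
and performance on laboratory data will be lower than on these
fixtures.

With zero noise the generator/scorer identity is exact: every planted
pair reproduces its own target trajectory to machine precision, which
the acceptance suite asserts at MSE < 1e−6.

## Degenerate inputs and tie-breaks

Constant genes normalize to zero (warning); constant MIC inputs score 0
(warning); candidate sets smaller than two yield no pairs for that
target (logged, not fatal); conflicting signs for the same edge from
different targets' selections resolve to the lower-RS occurrence
(warning). All iteration orders derive from input gene order, making
every run deterministic — there is no unseeded randomness anywhere in
the pipeline.

## Problem sizes

The bundled validation runs at desk scale by design: oracle comparisons
at n ≤ 20 (where exhaustive grid enumeration is exact and fast), and
recovery at 10 genes × 5 series × 21 timepoints over 10 seeds. The
estimator and pipeline themselves handle the 50–100-gene range; only
the exhaustive oracle is size-limited.

## Known limitations

- The rulebase is fixed, not learned; multi-activator rules and
  self-regulation are out of scope.
- The five-level output layout and the off-anchor rulebase cells are a
  principled reconstruction (uniform spacing, monotone antisymmetric
  completion); other completions are expressible via the config file.
- MIC significance testing (permutation p-values) and ranked evaluation
  (AUROC/AUPR) are not provided; evaluation is of thresholded networks.
- The `independent` effect scaling makes the default predictions
  RRS-invariant; use `paired` mode to make regulatory relationship
  strength bear on the scores.
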