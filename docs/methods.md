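# Methods

This note documents the models, conventions and numerical choices behind
`cpforest`, and what the synthetic-data results do and do not establish.

## Synthetic cohort model

The generator emulates a two-wave community cohort of elementary-school
children whose caregivers completed psychometric scales. Each variable is
produced by a one-factor latent model with block structure:

    z_v = λ_v·F + β_b(v)·B_b(v) + √(1 − λ_v² − β²)·ε_v

where `F` is a shared child-risk factor, `B_b` a per-block factor
(temperament, emotion, psychopathic traits, conduct problems, parenting,
parent characteristics), and `ε_v` idiosyncratic noise, all standard
normal. Risk-loaded variables (psychopathic traits, lability/negativity,
conflict, parental distress, prior CP) load positively (λ 0.25–0.60);
protective ones (effortful control, regulation, empathy, warmth, support)
negatively (λ −0.20…−0.45). Block loadings default to 0.30. The latent
draw is affinely mapped, clipped to the 1–5 response scale, and iteratively
moment-matched (about 40 fixed-point passes of re-centering/re-scaling the
pre-clip affine map) so the *clipped* sample mean and SD hit the published
per-variable targets; with means near the scale floor (e.g. CU at
1.30 ± 0.51) the truncation is substantial and a single affine pass would
miss by far more than the 5 % tolerance the generator guarantees at
n ≥ 2000.

The wave-2 outcome combines a stability-weighted component of the realised
(clipped) `CP.1` column, the shared factor (λ = 0.45), noise, and — before
the final moment match — an additive interaction shift: rows with
`GD.1 > 2.5` **and** `CONFLICT.1 > 2.5` receive +0.6 scale units. Folding
the shift in before moment matching keeps the marginal moments on target;
the matching is affine and monotone, so the planted group's elevation
survives (≈ +1 scale unit in the default cohort). Clipping attenuates
correlations, so when `stability_r ≠ 0` the latent stability coefficient is
calibrated by a deterministic Brent root solve on the *observed*
corr(CP.1, CP.2); targets beyond the attainable range saturate at the
maximum. With `stability_r = 0` no direct CP.1 component is added (shared
loadings may still correlate the two waves).

Defaults are the study conditions: n = 1095 complete cases,
`stability_r = 0.8` (prior CP is by far the strongest predictor),
interaction cutoffs at 2.5 (≈ +1.3 SD for GD, +1.8 for conflict — a small,
genuinely high-risk subgroup), effect 0.6 (a visible but not dominating
non-linearity). Missingness is missing-completely-at-random per cell;
complete-case filtering is the only treatment.

**What the generator does not emulate:** the real inter-predictor
covariance (unpublished — the one shared factor plus block bumps is the
simplest structure consistent with the qualitative finding that
individual-block variables dominate), item-level responses, informative
(SES-related) dropout, rater effects, and any distributional shape beyond
a clipped normal. Passing tests therefore demonstrate that the *pipeline*
recovers structure it is known to contain, not that the published
data-dependent metric values would be reproduced on the real cohort.

## Grouping, balancing, scoring

* Group cuts use the sample mean and ddof = 1 SD of the observed outcome
  **after** complete-case filtering, and are then frozen; the same cuts
  band model predictions. Boundaries are inclusive on both sides
  (≤ low cut → low, ≥ high cut → high), with a 1e-9 relative epsilon so
  scores stated at printed precision fall on the inclusive side of a
  float-accumulated cut.
* Balancing is random undersampling without replacement to the minority
  group, applied inside each training fold only (the leakage-safe reading);
  oversampling was deliberately not used to avoid synthetic-row artifacts.
* Cross-validation shuffles once per run and cuts contiguous near-equal
  blocks; metrics are computed on the pooled out-of-fold predictions (each
  row predicted exactly once), with per-fold values logged alongside.
* "Global" precision/recall are macro averages over the three groups
  (one-vs-rest); the high-group recall is reported separately. Classes with
  an empty denominator are flagged as undefined, never zeroed.
* Grid search maximizes cross-validated Pearson ρ; ties break toward fewer
  trees, then shallower depth, then grid order. Default forest settings:
  250 trees, depth 6, split/leaf thresholds at 0.1 % of the training
  sample, bootstrapped; Poisson split criterion for Case A and absolute
  error for Case B.

## Path and root mining

* Leaf sample counts are the bootstrap-draw multiplicities
  (`weighted_n_node_samples`), so per tree they sum to the draw size.
* A leaf is *high* iff its regressed value ≥ the frozen high cut — the only
  high/low rule already defined by the grouping; it is configurable.
* Path precision is evaluated on the full unbalanced analysis sample with
  true outcome labels (not on per-tree bootstrap draws), so precisions are
  comparable across trees; a path satisfied by no row is flagged undefined.
* Path identity is the ordered (variable, direction) signature; a variable
  may legitimately repeat at different depths and is kept positionally.
  Thresholds are averaged unweighted across occurrences at the path level;
  root-level averages (thresholds, precision, length, leaf samples) are
  occurrence-weighted by default with plain means behind a flag.
* Root length N is the largest value in 1–6 for which at least `min_roots`
  (default 5, the size of the reported tables) prefixes reach
  `min_count = 10` occurrences; if none qualifies, N falls back to 1 with a
  warning. Qualification for ranking is conjunctive: count ≥ 10 and
  precision ≥ the case's global model precision, both inclusive; near-miss
  roots are surfaced rather than silently dropped.
* The normalization maxima for M are taken over the qualifying set of the
  same case; cases are normalized independently. When re-deriving maxima
  from printed report rows, the brute-force solve scans integer count
  maxima upward from the largest printed count and precision maxima in
  0.01 % steps up to 100 %, accepting pairs that reproduce every printed M
  after 2-d.p. rounding; among admissible pairs the canonical choice is the
  smallest count maximum, then the largest precision maximum (a
  100 %-precision root is the natural ceiling).
* Report rounding is half-up to 2 decimals (thresholds, averages, M) and
  percent with 2 decimals for precision, matching the tabular conventions.

## Problem sizes

Tests and the demo run deliberately scaled-down configurations chosen to
exercise every code path with comfortable statistical margins: the
planted-signal checks use an n = 2000 cohort with 100-tree, depth-6
forests under 10-fold CV; oracle-equivalence checks use 50 random forests
of ≤ 20 trees and depth ≤ 4; the demo uses n = 500 with 60-tree forests.
The default study configuration (n = 1095, 250 trees) runs in well under a
minute per case on a laptop-class core.

## Known limitations

* The generator's loadings are calibration choices, not published facts;
  only the marginal moments, the stability correlation and the interaction
  are pinned to stated conditions.
* MCAR missingness cannot probe bias from informative dropout.
* Whether published path precisions were computed on training or held-out
  data, and whether "count" sums occurrences or distinct canonical paths,
  is not documented for the original analysis; this package evaluates
  precision on the full analysis sample and sums occurrences (distinct
  counting available behind a flag).
* The comparator models reproduce the leaderboard's *shape*; their
  data-dependent metric values on the real cohort are not reproducible from
  synthetic data and are not claimed.
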