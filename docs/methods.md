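# Methods

## The audit protocol

`embaudit` implements a two-step, post-hoc protocol for probing demographic
bias in classifiers built on shared document embeddings:

1. **Dual-model probing.** Two gradient-boosted decision tree (GBDT)
   classifiers are trained on the same n×D embedding matrix with the same
   stratified 70/30 split: an outcome model (cancer primary site, up to 70
   classes) and a demographic model (race, 7 categories). Optional binary
   one-vs-rest models for individual cancer sites are trained on the same
   embeddings. For each model the per-feature importance is the across-tree
   gain, normalized to sum 1. For a model pair (M1 = outcome, M2 = race) the
   audit intersects the top-k importance rankings (k = 50 by default),

       Overlap(M1, M2) = |F1 ∩ F2|,

   and sums each model's importance over the intersection (cumulative
   feature importance, CFI):

       CFI(M) = Σ_{f ∈ F_overlap} Importance(f, M).

   A pair is flagged when the race model's CFI strictly exceeds a threshold
   (10% of total race-model importance by default).

2. **Pruning sensitivity analysis.** Overlap dimensions are removed
   (columns deleted, never zeroed) and all models are retrained on the same
   split. Performance (accuracy, macro-F1), race-stratified macro
   precision/recall/F1/accuracy, and group-fairness gaps are compared
   before and after. A threshold sweep prunes progressively: overlap dims
   are ranked by descending race importance, and for each level L in the
   sweep grid (5%–15% in 1% steps by default) the shortest prefix whose
   cumulative race importance reaches min(L, total overlap mass) is pruned
   and the outcome model retrained. Levels exceeding the available overlap
   mass are capped at the full overlap set and annotated (`capped`), not
   treated as errors: an overlap CFI below the flag threshold is the
   expected, benign outcome. Distinct pruned sets are retrained exactly
   once (memoized), so duplicate rows are byte-identical.

Because the raw gain definition divides by the number of trees and the
audit uses only *normalized* importances, that constant cancels; all CFI
values live on [0, 1] and percentage thresholds are well defined.

## Fairness metrics

All metrics use a macro one-vs-rest formulation over predicted classes:

- **Demographic parity gap**: for each class c, the spread across protected
  groups g of the positive-prediction rate P(ŷ = c | g), averaged over
  classes.
- **Equalized odds** is reported as the pair of spreads of the
  class-conditional true-positive rate and false-positive rate. No scalar
  combination of the two is invented.
- **Spread** defaults to max − min across groups; mean absolute pairwise
  difference is available via `aggregation="mean_pairwise"`. The choice
  matters with more than two groups and is reported in every output.
- **Support handling**: a (class, group) rate is computed only where its
  denominator holds at least `min_support` records (default 1). Classes
  with fewer than two defined groups contribute a gap of 0 and are recorded
  in `excluded` — never silently dropped. With a protected-group marginal
  as skewed as the default one (84.2% / 10.3% / 3.5% / three groups under
  1%), per-group rates for small groups are intrinsically noisy; the
  exclusion log is how that shows up in reports.

Stratified performance computes macro precision/recall/F1 and accuracy
within each group over the classes present in that group, with
zero-division cells contributing 0 (scikit-learn's `zero_division=0`).

## Synthetic cohorts

Real registry pathology reports and their embeddings cannot be
redistributed, so the package ships a generator whose cohorts make every
audit stage testable against known ground truth:

- race ~ Categorical(p) with the default marginal taken from the printed
  registry distribution (White .842, Black .103, Asian .035, Island .003,
  Native .005, Other .002, Unknown .009, renormalized to sum 1);
- site ~ Categorical over `n_sites` classes with power-law weights
  (exponent `site_skew`, default 1), interpolated by a `confounding` knob
  (default 0) toward race-specific site distributions — race–site
  correlation is the mechanism the audit probes, so it is tunable even
  though the baseline study design does not model it;
- embeddings: X[i, d] = β_site·μ[site_i, d]·1[d ∈ site_dims]
  + β_race·ν[race_i, d]·1[d ∈ race_dims] + ε, with ε iid N(0, noise_sd²)
  and class templates μ, ν iid N(0, 1) drawn once per cohort.

A single master seed is split (numpy `SeedSequence.spawn`) into pattern,
label and noise substreams, so enlarging `n_records` does not change the
planted templates, and identical configs are bit-identical.

**What this emulates and what it does not.** The generator reproduces the
features that drive the audit's behaviour: a severely imbalanced protected
attribute, a many-class imbalanced outcome, and embedding dimensions that
are outcome-informative, demographic-informative, jointly informative or
pure noise, with controllable effect sizes. It does *not* emulate anything
about real attention-network embeddings — their geometry, correlation
structure, or how diffusely demographic signal spreads across dimensions.
Passing tests therefore demonstrate that the audit machinery measures what
it claims (planted leaks are found; pruning removes exactly the planted
pathway), not that any real embedding is or is not biased.

## Numerical and design choices

- **Split**: hand-rolled stratified allocation with largest-remainder
  rounding (floor each class's quota, distribute the remaining slots by
  fractional part, ties by class order; every class keeps ≥1 record on each
  side). Deterministic given the seed. Both models share one split
  stratified by site so fairness metrics are computed on a single test set.
- **GBDT defaults**: depth 6, 200 trees, learning rate 0.1, histogram tree
  method, single thread. Single-threaded training plus a fixed seed makes
  runs reproducible to the byte (report CSVs compare equal across reruns).
  Tests and the acceptance script use 30–60 trees: with planted Gaussian
  signal the importance rankings stabilize long before 200 trees.
- **Tie-breaks**: top-k ranking and sweep prefix ranking break importance
  ties by ascending feature index.
- **Flag rule**: strict inequality (CFI > threshold), so a CFI exactly at
  the threshold is not flagged.
- **Degenerate fits**: a model whose booster never splits (no learnable
  signal at all) has zero total gain; its importance is defined as uniform
  so the sum-to-1 invariant holds.
- **Booster persistence** stores the native booster JSON plus a metadata
  sidecar (classes, feature names, importance); the sklearn wrapper is
  rebuilt on load.

## Problem sizes for the shipped experiments

The reference study this protocol is designed for operates on millions of
reports and 400-dimensional embeddings; the shipped experiments are desk
scale, chosen once:

- Acceptance-script primary cohort: n = 20,000, D = 400, 10 sites, site
  signal in dims 0–23, race signal in dims 12–23 (a 12-dimension planted
  overlap), β_site = β_race = 2, noise 1.
- Planted-recovery check: n = 20,000, D = 100, 12 race dims disjoint from
  12 site dims, β_race = 2, noise 1, 10 seeds; recovery = fraction of
  planted race dims inside the race model's top 50.
- Pruning stress test: n = 10,000, D = 100, 6 sites, 24 site dims of which
  12 are shared with race — the shared block is the only race pathway,
  while the disjoint site block provides redundant outcome signal. Pruning
  the planted overlap should leave site macro-F1 nearly unchanged
  (redundancy) while collapsing race accuracy to the majority-class rate.
- Unit-test cohorts: n = 800–2,000, D = 15–30.

## Known limitations

- Gain importance is the only importance notion implemented (no SHAP or
  permutation importance); gain is known to favour high-cardinality
  continuous splits and its top-k set is noisy at small n.
- The audit probes one bias pathway — concentrated, jointly important
  dimensions. Diffusely encoded demographic signal passes the audit
  undetected by construction; the race model's own accuracy is the better
  indicator there.
- With D close to k, the top-k intersection is dominated by chance overlap
  (top-50 of 100 dims covers half the space); audits should keep k ≪ D.
- Fairness gaps for groups with a handful of records are noise; use
  `min_support` and read the exclusion log rather than the raw gaps.
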