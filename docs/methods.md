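# Methods

## Fusion model

All soft strategies produce a convex combination of the per-model class
probabilities, `EP(x) = Σ_i w_i(x) p_i(x)`, and predict its argmax (lowest
index on exact ties).  Because the combination is convex, the fused vector is
automatically a probability vector, and the fused confidence can never exceed
the largest single-model mass on the chosen class — a structural sanity bound
the tests enforce.

Majority voting is the one hard strategy: the modal predicted label wins;
ties are broken by the highest single-model confidence among tied labels,
then by lowest class index (deterministic and order-stable — the tie rules
elsewhere in the package follow the same principle).  Its reported
"probability" vector is the vote-share vector (votes / M), which is the
natural probability-shaped summary of a hard vote.

## The fuzzy inference system

Weights come from a Mamdani FIS over model confidences:

* **Fuzzification.**  Each confidence variable lives on [0, 1] with three
  triangular terms: low (0, 0, 0.5), medium (0.25, 0.5, 0.75), high
  (0.5, 1, 1).  Shoulders at the ends give complete cover: every point of the
  universe has a positive-degree term, so some rule always fires.
* **Rules.**  One rule per (model, term): IF `conf_i` IS *t* THEN `weight_i`
  IS *t*.  Rule strength is the min over antecedent degrees (here a single
  clause); per-output aggregation is max over clipped consequents.
* **Defuzzification.**  Centroid on a discretised output universe with grid
  step 0.001.  At that step the centroid agrees with a 10× finer brute-force
  grid to better than 1e-3 (tested), at negligible cost.
* **Normalisation.**  Raw centroids are normalised to sum to 1 afterwards;
  a degenerate all-zero raw vector (unreachable with the default system,
  possible with user-supplied ones) falls back to uniform weights.  The
  normalise-afterwards choice guarantees the fusion stays convex regardless
  of the rule base.

This is deliberately the *minimal* monotone-by-construction system: rules
never cross models, so each model's raw weight depends only on its own
confidence, which makes the mapping symmetric under model permutation and
non-decreasing in each confidence (both property-tested on a 0.05 grid; the
measured response has no jump larger than 0.024 per 0.01 confidence step).
Cross-model rules are expressible in the `fis/1` serialization format but are
not generated by default.

Two application modes exist because either is defensible: `per_sample`
(default) infers one weight vector per sample from that sample's confidences
— this is what makes the combiner *dynamic*; `panel_average` feeds the
panel-mean confidences through the FIS once and applies one weight vector to
every sample, which reduces to a data-derived fixed-weight ensemble.

## Evaluation metrics

Accuracy, precision, recall, F1 and average confidence score (ACS) are
computed from a K×K confusion matrix via one-vs-rest class counts.
Aggregation is **macro** by default (unweighted mean over classes) with
**weighted** (support-weighted) selectable; macro is the default because it
is the only mode consistent with reference results whose precision sits far
below accuracy on imbalanced per-class performance.  Zero-denominator
classes contribute 0 and are listed in the report rather than dropped.  The
report-level F1 is the harmonic mean of the aggregated P and R; ACS is the
mean probability assigned to the predicted class.  Percentages are rounded
to 2 decimals in text output only.

## Statistical validation

Run series (typically five runs per approach) are summarised as mean and
sample SD (n − 1).  The 95% CI half width is **1.96·SD/√n** — the normal
approximation — because that is the convention the reference protocol's
printed intervals follow (0.44 for the ensemble standard-accuracy series,
which only the z form reproduces; Student-t with t(0.975, 4) = 2.776 would
give 0.62).  The orthodox small-n interval remains available via
`student_t=True` / `--student-t`.  Group comparison is classical
equal-variance one-way ANOVA; the p-value is the F upper tail.

**Known discrepancy.**  The reference table's occluded-image F statistics
(5.42 and 5.35) are not recoverable from its own printed run values: the
definitional ANOVA (confirmed against `scipy.stats.f_oneway`) gives 2.70 and
3.02.  The package asserts the recomputed values and reports them as
`*_recomputed`; no attempt is made to guess the source of the printed ones.
The standard-image statistics reproduce exactly at printed rounding.

## Challenge-set generators

All randomized operations are pure functions of (input, spec, seed) and
never change image dimensions or channel count.

* **Augmentation.**  Rotation, horizontal/vertical flip, vertical shift,
  per-axis scale, shear; each parameter drawn uniformly from its spec range,
  with a preset matching the validation protocol's ranges (rotation 10–20°,
  flip probability 0.1–0.5, shift 0–0.1, scale 0.01–0.1).  "Horizontal flip
  0.1–0.5" is read as a per-image flip *probability* drawn from that
  interval — flips have no magnitude, so no other reading is coherent.
  Operations with zero-valued parameters are skipped, making the all-zero
  spec a strict no-op and seeded outputs bit-identical.
* **Noise (TD1/TD2).**  "x% noise" is interpreted as salt-and-pepper
  corruption of exactly `round(f·N_pixels)` distinct pixels (f drawn from
  the preset range: TD1 0.25–0.40, TD2 0.40–0.50), each set to black or
  white with equal probability; a pixel already at the drawn extreme is set
  to the other, so the changed-pixel count is exact.  Pixel-fraction is the
  only interpretation under which a noise *percentage* is well defined; an
  additive-Gaussian mode (σ = f·127.5) is provided as an alternative.
* **Occluders (TD3).**  Leaves are filled ellipses in a green-brown palette,
  branches thick two-segment polylines, shadows semi-transparent dark
  polygons (opacity configurable, default 0.5).  Shapes are added until the
  boolean mask reaches the coverage target, each capped at 20% of the target
  area, which bounds the rendered coverage within ±20% relative of the
  target (tested at target 0.15 → [0.12, 0.18]).  Occluder geometry and
  palette are this package's own parametric designs.  The whole frame is
  eligible for occlusion (no foreground detection).  Approximately 10–15% of
  each class is replaced by occluded variants when building an occluded
  subset, with a per-class uniform draw of the fraction.
* **Fixtures.**  The procedural generator paints bird-like images (body
  ellipse, beak triangle, eye, textured background) with per-class palettes
  kept at pairwise colour distance ≥ 60; it stands in for real photographs
  so the pipeline is testable offline.  It reproduces byte-identical files
  per seed.

What the generators do *not* emulate: real textures, pose variation,
class-dependent difficulty, lighting.  Passing tests demonstrate the
correctness and determinism of the machinery, not field performance on real
photographs.

## Simulator

Classifier outputs are modelled as Dirichlet draws peaked on an intended
class: correct with probability `a` (the model's accuracy), otherwise a
uniformly chosen wrong class.  The peak concentration is calibrated by
seeded Monte-Carlo bisection so the expected top probability matches the
model's confidence target; calibration is deterministic (its RNG is derived
from the arguments, not the caller's seed) and cached.  The Dirichlet family
is the minimal generative model giving controllable accuracy, confidence and
normalisation by construction.  The attainable confidence floor is the mean
top probability of the flat Dirichlet (above 1/K); targets below it are
rejected with the measured floor.

Correct predictions use a higher confidence target than incorrect ones
(default: incorrect target halfway between chance and the correct target),
which is what makes confidence informative and gives the fuzzy combiner its
advantage; setting the two equal produces a deliberately uninformative model
under which fuzzy fusion degenerates to mean voting.

The argmax of each draw is forced onto the intended class by swapping the
maximal entry into that slot — a measure-preserving relabelling that keeps
accuracy exactly Bernoulli(a) and the confidence (max-entry) distribution
untouched, unlike rejection sampling, which would bias both.

Error correlation ρ uses a shared per-sample "hard-sample" uniform: each
model's correctness draw is replaced by the shared uniform with probability
ρ.  ρ = 0 gives independent errors, ρ = 1 with equal accuracies identical
error sets.  ρ is an ordinal knob, not calibrated to any real error-overlap
statistic.

## Problem sizes

The validation suite simulates panels of 20 000 samples (10 classes, 3
models) for the ensemble-lift check — large enough for a 4σ binomial margin
around the expected accuracies — and 10 × 4 000 samples for the
degraded-model comparison, where the decision criterion is a seed-majority
rather than a per-seed significance test.  Image-based checks use 96×96
procedural fixtures, the size at which pixel-count assertions (noise
fractions, occluder coverage) are already exact.

## Limitations

* The default FIS parameters are this package's own design; the dynamic
  weighting idea constrains the shape (monotone, symmetric) but not the
  exact breakpoints.  Alternative systems can be supplied as `fis/1` files.
* No probability calibration (e.g. temperature scaling) is applied to
  inputs; over-confident upstream models will be over-weighted.
* Only Mamdani min/max inference with centroid defuzzification is
  implemented; no Sugeno/TSK, no rule learning.
* No ROC/AUC or top-k metrics; no multiple-testing correction or effect
  sizes in the validation protocol.
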