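# Methods

This note records the model, the conventions the implementation commits to
where the method leaves room, and what the tests do and do not establish.

## The information system and preprocessing

A dataset is an information system *I* = (*U*, *A* ∪ *D*): objects *U*,
categorical condition attributes *A*, one decision attribute *D* with no
missing values (rows with a missing decision are dropped at read time).
Numeric attributes are discretized against ordered cut points declared in the
schema: a value maps to the label of the greatest cut point ≤ value, and
values below the range clamp to the first label. This left-edge convention is
monotone, total, idempotent, and reproduces binned domain alphabets such as
{0.39, 0.80, 1.20, 2.00, 3.00, 4.00} for serum bilirubin. Cut points may be
written as strings in the schema, in which case their exact spelling becomes
the label ("0.80" stays "0.80"). Missing cells use the sentinel "?" on disk
(the UCI convention; configurable).

Missing-value handling has three passes with a single threshold (default
0.25, rejection at ≥ threshold; a strict-> flag is provided because prose
descriptions of such rules vary between "greater than" and "at least"):

1. drop condition attributes whose missing fraction over the original
   objects reaches the threshold;
2. drop objects whose missing fraction over the *retained* attributes
   reaches it (a flag switches the denominator to the original attribute
   set — with per-attribute and per-object missingness both near the
   threshold the two modes can disagree, and real provenances rarely say
   which was used);
3. impute every remaining missing cell with the class-conditional mode: the
   most frequent value of that attribute among retained objects with the
   same decision label, ties broken by first occurrence in data order. A
   class×attribute stratum that is entirely missing is an error, not a
   silent guess.

A caveat worth knowing: object rejection under the default retained-attribute
denominator is **not** monotone in the threshold. Raising the threshold can
retain a heavily missing attribute, which raises some object's missing
fraction and can push it over the (also higher) line. The property holds
unconditionally for attributes, and for objects under the original-attribute
denominator; the test suite asserts exactly that.

## Rough-set feature selection

For *P* ⊆ *A*, IND(*P*) is the equivalence relation "equal on every attribute
of *P*"; IND(∅) is the single-block partition. Lower/upper approximations
and the boundary follow the standard per-class definitions; the positive
region Pos_*A*(*D*) is the union of all classes' lower approximations under
IND(*A*).

**Reduct acceptance.** All 2^|A| − 2 proper nonempty subsets are enumerated
(size-ascending; candidates at each size are counted by C(n, k), and an
exhaustive-search cap of 20 attributes guards against accidental blow-ups —
a size range restricts the search when more attributes are present). Two
acceptance semantics are implemented:

- `restricted` (default): IND(*P*) restricted to Pos_*A*(*D*) equals
  IND(*A*) restricted to the same universe. On the bundled six-object
  worked example this accepts exactly {Chp, Vessel} and {ECG, Vessel} —
  note {ECG, Vessel} does *not* preserve the positive region over *U*, so
  this reading is strictly weaker than the classical criterion and is the
  one that matches the worked example.
- `pos_preserving`: the classical decision-relative criterion
  Pos_*P*(*D*) = Pos_*A*(*D*).

No minimality filter is applied: acceptance in exact mode is superset-closed,
so reduct lists deliberately include proper supersets of minimal reducts.
The core is the intersection of all accepted subsets (empty when nothing is
accepted).

Because IND(*A*) refines IND(*P*) for *P* ⊆ *A*, equality on the reference
universe reduces to an equal block count — the implementation exploits this,
while the test oracle recomputes acceptance from explicit partition objects
and an all-pairs union-find, independently of the fast path.

**Approximate reducts.** The similarity between IND(*P*) and IND(*A*) is the
fraction of unordered object pairs (restricted to the reference universe) on
which the two partitions agree — both together or both apart. It is
symmetric, lies in [0, 1], and equals 1 exactly at partition equality, so
approximate mode converges to exact mode as the threshold approaches 1.
Acceptance is strict (> threshold). The dependency-degree ratio
γ_*P*/γ_*A* = |Pos_*P*|/|Pos_*A*| is available behind a flag as an
alternative measure.

**A structural consequence of the equality semantics.** Attributes that are
pure noise still *discern* objects, so when noise refines IND(*A*), every
exact reduct must reproduce that refinement and noise attributes end up
inside every accepted subset. Recovering only the truly informative
attributes from noisy tables is what the `pos_preserving` flag is for; the
synthetic-recovery tests exercise both regimes (partition equality on tables
without noise attributes, positive-region preservation with noise present).

## The classifier

One hidden layer of tanh units (default 25), one linear output unit, trained
by full-batch gradient descent on the mean squared error against 0/1 targets;
prediction thresholds the linear output at 0.5. Defaults where the method
itself pins only the topology and activations: learning rate 0.05, at most
1000 epochs, MSE goal 10⁻³, no momentum (a momentum coefficient is exposed),
weights initialized uniform(−0.5, 0.5) from a seeded generator. Inputs are
min-max scaled to [0, 1] with bounds learned on the training fold only
(integer-coded categories at raw scale saturate the tanh layer); constant
features map to 0 and out-of-range test values clip. The analytic gradients
are verified against central finite differences to 10⁻⁵ relative error —
the module's primary oracle. Training is deterministic given (data, config,
seed), and full-batch updates make it invariant to row permutation.

## Evaluation

Confusion counts use an explicit positive label (for the clinical benchmarks
the disease outcome; the pipeline defaults to the minority class when not
told). Accuracy/sensitivity/specificity are percentages, TPR/FPR fractions;
a zero denominator yields an undefined metric (`None`), never 0. Report
rounding mirrors common practice (percent 2 dp, TPR 2 dp, FPR 3 dp, AUC
4 dp); raw fractions are always retained. Note that applying the formulas
literally to a published confusion matrix can expose transcription slips in
secondary sources — e.g. counts TP=26, FN=2, TN=117, FP=2 give sensitivity
92.86% and specificity 98.32%, and an accuracy of 97.28% rather than a
rounded 97.30 — this package always reports the recomputed values.

The ROC curve sweeps the decision threshold across distinct scores (ties
step simultaneously); the trapezoidal AUC equals the Mann–Whitney
pair-counting statistic, which the tests verify against both an explicit
pair-enumeration oracle and scikit-learn.

Train/test splits are seeded simple random draws with training size
round-half-up(fraction·N) (e.g. 147 objects at 0.8 → 118/29); stratified
splitting is available but off by default. k-fold partitioning deals a
seeded shuffle into folds of ⌊N/k⌋ or one more. The pipeline runs 10-fold
cross-validation *within* the training portion as a validation signal, then
retrains on the full training portion before the single held-out evaluation.

## The synthetic generator

`SynthSpec` plants ground truth: informative attributes drawn uniformly over
a small alphabet (default cardinality 3), a decision given by a seeded
lookup table over the informative value-tuples (forced non-constant),
redundant attributes that are bijective recodings of informative ones (hence
partition-identical and interchangeable inside reducts), independent noise
attributes, label flips for a stated fraction of objects (creating a
nonempty boundary region wherever a flipped object shares its full profile),
and MCAR masking of condition cells at a stated rate. Defaults (100 objects,
2 informative + 1 redundant + 2 noise attributes) mirror the scale of the
clinical tables after discretization.

What the generator does *not* emulate: the real UCI marginal distributions,
correlated (non-MCAR) missingness of the kind that lets a handful of
patients carry most missing labs, and ordinal structure among categories.
Passing the recovery tests therefore shows the machinery is correct, not
that any particular clinical reduct list is.

## Problem sizes and limitations

The bundled tests run on tables of up to a few hundred objects and at most
13 attributes, where exhaustive enumeration is instant; the 18-attribute
(262 142-subset) hepatitis search runs in about a minute on one core.
Exact reproduction of published reduct totals and accuracies for the UCI
benchmarks additionally requires the original data (not redistributed here)
plus choices their provenance does not fully specify — the discretization of
the continuous heart-disease attributes, the denominator convention for
tuple rejection, and the network's learning rate and stopping rule — so
those figures are stretch targets, not guarantees of this implementation.
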