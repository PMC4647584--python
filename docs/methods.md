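# Methods

## The problem

Grid searches over classifier hyper-parameters are embarrassingly
parallel batches of small, independent jobs, yet they are usually run as
one monolithic process: a crash after hours of computation loses
everything, and the batch's definition lives in either a script or a
GUI-generated configuration too verbose to edit by hand.  `gridrun`
treats the batch as the unit of specification and the experiment as the
unit of execution: a short declarative XML document is expanded into a
Cartesian grid of fully-concrete experiment configurations, each of
which runs independently, writes its own verifiable result file, and can
be skipped on a re-run.

## Specification and grid semantics

A ranged hyper-parameter is either an explicit ordered value set or a
numeric interval `(start, step, end)`.  Interval values are materialised
by index, `v_i = start + i·step`, never by accumulation, with the end
point included when it lies on the lattice within a relative tolerance
of `1e-9·|step|`.  Numbers are carried as exact decimals from the XML to
the point of consumption, so `0.05 … 0.5 step 0.05` has exactly ten
values on every platform.  Parsing is strict — any unknown element or
attribute is an error — because a silently ignored typo in a parameter
name would change the scientific content of the grid.

The grid is ordered deterministically: algorithms in declaration order,
the last-declared parameter varying fastest.  Each grid point's
identifier is a readable slug plus an 8-hex-digit SHA-256 content digest
of (dataset, algorithm, parameter assignment, evaluation strategy).
Content addressing is what makes resume safe: if the specification is
edited, the identifiers change, and stale result files can no longer
satisfy the new grid.

Each experiment also receives a derived seed,
`sha256(master_seed ∥ experiment_id) mod 2³¹`.  This seed is reserved
for learners that are intrinsically stochastic (e.g. adapter-wrapped
estimators).  Fold assignment and train/test splits are instead seeded
by the specification-level evaluation seed, shared across the whole
grid, so every configuration is scored on the *same* partitions —
differences between grid points then reflect the hyper-parameters, not
partition luck.  Both seeds are pure functions of the specification, so
results are independent of scheduling.

## Evaluation

Three strategies are supported: leave-one-out cross-validation, k-fold
cross-validation (stratified by default) and a single percentage split
(shuffled before splitting; an unshuffled split would be order-biased
for sorted files).  Stratified folding shuffles within each class and
deals round-robin, carrying the dealing pointer across classes, which
bounds both per-class and overall fold-size imbalance at one.
Cross-validated predictions are pooled into a single confusion matrix
(micro aggregation) rather than averaged per fold: every reported number
is then an exact, reproducible function of the individual predictions.

Rows with a missing class label are excluded from evaluation entirely.
A training fold that happens to lack a class is legal: the learner never
predicts that level and its held-out instances score as errors.

Metrics follow the standard definitions — accuracy, per-class
precision/recall/F1, Cohen's kappa from the confusion marginals — with
explicit zero-denominator conventions: precision/recall are 0 when
undefined, F1 is 0 when precision + recall is 0, and kappa is 0 when the
expected agreement is 1 (single-class degenerate matrix).

## Built-in learners

The framework ships three deterministic reference learners so it is
testable end to end with no ML dependency; heavier schemes (C4.5-style
trees, rule lists, anything sklearn-shaped) plug in through the registry
adapter.

* **zeror** — majority class; ties to the first-declared level.
* **knn** — Euclidean distance on standardised numeric attributes
  (training mean/sd, population sd; zero-sd attributes ignored), nominal
  attributes contribute 0/1, any missing cell contributes 1 to the
  squared distance; distance ties break by lower training-row index,
  vote ties by first-declared level.
* **stump** — one-level tree maximising information gain over all
  single binary splits (numeric midpoint thresholds, nominal
  one-vs-rest), with both leaves required to hold at least `min_leaf`
  training rows; `min_leaf` is the tunable knob that gives the grid
  something real to optimise.  Rows missing the split attribute follow
  the "else" branch.  Gain ties prefer the lowest attribute index, then
  the lowest threshold or level code.

A caution that the deterministic tie rules make visible: under LOOCV,
any learner whose decision flips on a one-instance tie is scored *against*
the held-out class.  The majority baseline on a perfectly balanced
two-class dataset scores 0, not 0.5; a stump whose leaf is split evenly
between two classes misclassifies both.  These are properties of
leave-one-out itself, not artefacts, and they are why the worked
example's stump accuracies can sit below chance on a balanced
three-class dataset while its k-NN accuracies behave normally.

## Execution, checkpointing, resume

Result files are committed atomically (write to a temporary name, then
rename) and end with a completion footer — a SHA-256 digest of
everything above the provenance section.  "Successfully complete" is
defined as "the footer digest matches the payload": a crash at any point
leaves no file, an ignorable temp file, or a complete valid file, never
a plausible-looking partial.  The wall-clock duration lives in the
provenance section *outside* the digested payload, so re-running an
experiment reproduces its file byte-for-byte apart from that one line.

Resume is a set difference against the expanded grid, not a linear
cursor: under parallel execution the completion order is
nondeterministic, so "the most recent success" is not well defined, but
the set of valid result files is.  Failed experiments are re-run on
resume by default (failures are often transient); `--no-retry-failed`
keeps them.  A manifest records the specification digest; resuming
against a directory produced by a different specification is refused.

Parallelism uses a process pool of `workers` processes (`auto` = logical
cores − 1, floor 1).  Since each experiment's randomness is fixed by the
specification, result files are bit-identical across worker counts; the
test suite asserts this for worker counts {1, 2, 4} and the crash/resume
property for interruptions after 0, 1 and 7 commits.  Crashes are
injected through the executor's `stop_after` hook, which abandons the
run after K atomic commits — exercising exactly the code paths a real
kill would, deterministically.

## Dataset handling

ARFF (dense and sparse) and headered CSV are supported.  Sparse ARFF
follows the format's conventions: omitted positions are the attribute's
zero element — 0 for numerics, the **first declared level** for nominals
— and `?` is an explicit missing marker in both dialects.  String, date
and relational attributes are rejected loudly.  CSV columns are numeric
iff every non-missing cell parses as a number; the class column is
always treated as nominal, since class labels are labels even when they
look like integers.

## The synthetic generator

`make_synthetic` emulates the shape and difficulty of classification
data, not any particular biology: numeric attributes are
class-conditional unit-variance Gaussians with class `c ≥ 1` displaced
by `class_sep` along axis `c−1` (so all pairwise mean distances are at
least `class_sep`); nominal attributes are uniform three-level noise;
cells go missing independently at `missing_rate`; labels are
near-balanced.  Everything is a pure function of the seed.

Defaults used by the tests: the worked-example dataset is 40–120 samples
with a handful of attributes, `class_sep` 2.5–3 (learnable but not
trivial) and 2–5 % missingness; the wide-data stability check uses
150 samples × 50,000 numeric attributes, a scaled-down stand-in chosen
so the whole generate → sparse-ARFF round trip → evaluate cycle runs in
about a minute on one CPU.  What passing these tests shows is
stability and reproducibility of the machinery on realistic shapes; it
says nothing about any particular real dataset's signal, which the
generator does not attempt to imitate.

## Known limitations

* Classification only; regression targets and probabilistic outputs are
  out of scope.
* Grid search only — no random or adaptive search.
* Single-machine parallelism; no distributed execution.
* The summary CSV is this package's own documented dialect, not a
  byte-compatible import for any external analysis GUI.
* Learners receive the whole dataset plus row indices, which assumes the
  data fits in memory; out-of-core learning is out of scope.
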