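# Methods

This note documents the modelling choices behind `hepatox`: what each
stage assumes, the parameters that matter, what the synthetic generators
do and do not emulate, and the numerical conventions used throughout.

## Problem setting

The endpoint is binary hepatotoxicity: a compound either has documented
evidence of liver injury (label 1) or no reported hepatotoxic effect
(label 0). Real compilations of this endpoint are assembled by hand from
literature sources and toxicant databases; they are heterogeneous,
moderately imbalanced toward positives (roughly 60/40), and carry the
usual artifacts of merged registries — duplicate entries, salts and
mixtures, inorganics and compounds with conflicting activity calls. The
pipeline is built around that reality: curation is an explicit, ordered,
logged stage rather than a preprocessing afterthought.

## Curation rules

Rules fire in a fixed order so exclusion counts are reproducible:
parseable → single fragment → contains carbon → duplicate collapse →
explicit ambiguous flags. Design points that were genuinely open:

- **Mixture** is operationalized as more than one disconnected fragment
  in the canonical SMILES. This also removes salt forms; we deliberately
  do not strip salts to parent structures, which may make curated counts
  differ from compilations that do.
- **Organic** is operationalized as "contains at least one carbon atom".
- **Conflicting duplicate labels drop all copies** (treated as ambiguous
  activity) rather than voting or keeping the first; a conflict is
  evidence the underlying call is unreliable.
- The train/test split is stratified by label. Plain random splitting
  would wander a few points from the global class balance on desk-scale
  data; stratification guarantees the balanced representation the split
  exists to provide.

## Feature representations

- `physchem_descriptors`: RDKit's full 2D descriptor set (~210 columns,
  alphabetical order). Counts are toolkit-version-dependent, so code and
  tests assert properties (finite, 2D-only, deterministic) rather than
  exact counts.
- `extended_descriptors`: a larger all-2D set assembled from RDKit's
  descriptor blocks — the physchem set plus 2D autocorrelations (192),
  molecular quantum numbers (42) and BCUT2D eigenvalues (8). BCUT2D is
  undefined for atoms without Gasteiger parameters; such columns carry
  NaN and are removed by cleaning, mirroring how any large descriptor
  collection sheds incomputable columns.
- `circular_fingerprints`: hashed Morgan fingerprints. Radius 2 with
  2048 bits is the default; both are flags, since 1024-bit variants are
  common in the literature.

Cleaning drops every column containing at least one missing or
non-finite value (column-wise, never imputation). Min–max scaling is
fitted on training rows only and applied with clipping to test rows;
constant training columns map to 0. Fitting the scaler before the split
would leak test-range information for no benefit. Fingerprint matrices
pass through cleaning and scaling unchanged (bits are already in [0, 1]
— note the one corner: a bit constant at 1 across training rows is a
constant column and maps to 0, which carries no information either way).

## Feature selection

Ranking and step-scoring are deliberately decoupled. A literal
leave-one-descriptor-out over 2048 bits would require thousands of model
refits; instead features are ranked once — impurity importances of a
200-tree seeded random forest (`embedded_forest`, default), or
|per-feature AUC − 0.5| (`univariate_auc`) — and the relative AUC
contribution score

    contribution = (AUC_w − AUC_i) / AUC_w

is used to score *removal steps* of the sequential search. Positive
contribution means the removed block was informative. Conventions:

- Step size defaults to 5 % of the features (minimum 1); the full trace
  is always recorded so other operating points can be read off.
- Steps are scored by refitting the evaluator (default: 100-tree random
  forest) on an internal stratified 80/20 split of the *training* rows.
  The held-out test set never participates in selection.
- A step that removes every feature scores the chance AUC 0.5.
- The optimal subset is the argmax-AUC step including the all-features
  baseline; ties break toward fewer features.
- Ranking ties break lexicographically by feature name, so degenerate
  inputs (all-constant matrices) still order deterministically.

## Base learners

| member | implementation | key settings |
|---|---|---|
| knn | scikit-learn | k = 5 |
| svc | scikit-learn | RBF, C = 1, probability calibration on |
| rf, et | scikit-learn | 500 trees default; optional validation-AUC grid over {100, 300, 500, 700} |
| rnn | in-package numpy LSTM | 2 layers × 64 units, dropout 0.2, Adam lr 0.001, 10 epochs, batch 128 |
| mlp | scikit-learn | hidden (100, 50), max 500 iterations |

The recurrent member is a from-scratch numpy implementation: two stacked
LSTM layers, inverted dropout after each recurrent layer, a dense
sigmoid head, binary cross-entropy, Adam. Backpropagation-through-time
is exact and verified against central differences in the test suite.
The SVC's unstated kernel/C default to RBF/1; the optimizer family for
the recurrent net defaults to Adam; dropout defaults to 0.2 — all
exposed as configuration.

**Input shaping.** A fingerprint has no natural time axis. The default
reading reshapes the length-f vector into 32 timesteps of ⌈f/32⌉
channels (`chunked`), which preserves the sequence treatment at a cost
that scales with the timestep count rather than with f; `per_feature`
(one scalar per timestep, the literal reading) and `single` (one
timestep) are available. Pure-python BPTT over 2048 scalar timesteps is
two orders of magnitude more work for no accuracy gain on these data,
which is why chunked is the default.

No class weighting is applied anywhere: the imbalance is part of the
endpoint, and its signature (high sensitivity, weaker specificity) is
something the evaluation stage should expose, not mask.

## Ensembles

All members receive equal weight. Soft voting (default) averages the
member probability streams — this uses the full calibration information
and is robust to one poorly calibrated member. Hard voting takes the
majority label with exact ties resolved toward the toxic class:
in a screening context a false alarm is cheaper than a miss. Bagging
refits every member on `n_bootstrap` (default 5) with-replacement
resamples of full training size and soft-votes all member × replicate
streams; a test hook (`resample=False`) makes it degenerate exactly to
voting. Stacking builds out-of-fold meta-features (stratified
`k_oof`=5), so every training row is scored by a model that never saw
it, fits a logistic meta-learner on those probabilities, and refits
members on the full training set for prediction time.

## Evaluation conventions

All metrics are computed as fractions in [0, 1] and rendered to 4
decimals (or as percentages) in reports. Any 0/0 ratio surfaces as NaN —
an explicit undefined marker — never as a silent 0. AUC is the
rank-statistic form (ties counted ½), equivalent to trapezoidal ROC
integration. Cross-validation is stratified and re-runs the *entire*
pipeline (cleaning, scaling, selection, member fitting) inside each
training fold. Repeated-holdout summaries redraw the stratified split
and reseed the pipeline from one master seed per repeat, so both split
and training stochasticity contribute to the reported SD. One-way ANOVA
handles the degenerate zero-within-variance cases explicitly (equal
means → F=0, p=1; unequal → F=∞, p=0); post-hoc letter displays are out
of scope, reports simply rank groups by mean.

## Synthetic generators

**Planted fingerprints.** Informative bits fire Bernoulli(0.7) in
positives vs Bernoulli(0.3) in negatives; background bits fire
Bernoulli(0.1) everywhere; 40 informative bits among 2048; 600 samples;
62.5 % positives (matching the ~1618:970 imbalance of curated
hepatotoxicity compilations). These defaults are the package's study
conditions for the quantitative tests. The generator emulates the
*shape* of a fingerprint learning problem (sparse binary features, weak
individually / strong jointly signal, class imbalance), not chemistry:
real fingerprint bits are correlated through substructure hierarchies,
and real structure–toxicity signal is far noisier. Passing tests
demonstrate the machinery recovers a known signal under realistic
geometry — not that hepatotoxicity itself is this learnable.

**Rule-labeled molecules.** Valid organic molecules are enumerated by
decorating eight scaffolds (benzene, pyridine, phenol, naphthalene,
cyclohexane, chains/esters) with substituents; the label is a decidable
structural alert (nitro group present), optionally noised, with planted
duplicate rows to exercise curation. Nitro is a genuine toxicophore,
but a single-alert label is a deliberately easy target: it validates
the chemistry path (parsing, curation, fingerprint encoding, end-to-end
learning), not predictive performance on real liver injury.

## Problem sizes used in tests

The quantitative suite runs at the planted-generator defaults (n = 600,
2048 bits, 3–5 seeds per stochastic check), 10-fold CV at n = 250–400,
and the chemistry path at 500 molecules — sizes chosen so the full
pipeline, including the numpy LSTM, exercises every code path in
minutes on a single CPU while keeping sampling noise well inside the
asserted tolerances. The permuted-label negative control evaluates on a
50 % holdout so that chance AUC concentrates tightly around 0.5.

## Known limitations

- Real hepatotoxicity datasets are not included; absolute performance on
  the synthetic benchmarks says nothing about real-world accuracy.
- Curation does not strip salts to parents or standardize tautomers;
  multi-fragment entries are removed outright.
- The extended descriptor set is smaller than dedicated descriptor
  packages (~450 vs >1000 columns); it preserves the role of a wide,
  cleanable 2D block rather than any specific census.
- The LSTM is CPU-bound numpy: adequate at desk scale, not for
  datasets in the tens of thousands.
- Probability calibration of the recurrent member after 10 epochs can
  lag its ranking quality (see the README example); thresholded metrics
  for that member should be read with its AUC alongside.
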