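# hepatox

Hybrid machine-learning / deep-learning ensemble QSAR pipeline for binary
**hepatotoxicity** (drug-induced liver injury) prediction from molecular
structure.

Chemicals and drugs are labeled 1 (hepatotoxic) or 0 (non-hepatotoxic).
The package takes a raw compound table (SMILES + label), curates it,
computes molecular representations, selects informative features by their
AUC contribution, trains a heterogeneous set of base classifiers, and
combines them into voting, bagging or stacking ensembles with full
cross-validated metric reporting. It is aimed at computational
toxicologists and cheminformaticians who want a reproducible,
desk-runnable implementation of this ensemble strategy.

## The method

1. **Curation** — canonicalize SMILES (RDKit); drop unparseable entries,
   mixtures (multi-fragment), inorganics (no carbon), duplicates
   (conflicting labels count as ambiguous) and explicitly ambiguous rows;
   stratified 80/20 train/test split.
2. **Featurization** — three representations: the RDKit physico-chemical
   descriptor set (~210 attributes), an extended all-2D descriptor set
   (~450 attributes), and hashed Morgan/circular fingerprints (default
   radius 2, 2048 bits). Descriptor columns with missing values are
   dropped; descriptors are min–max scaled to [0, 1] on training rows.
3. **Feature selection** — features are ranked (embedded random-forest
   importances by default), then blocks of the lowest-ranked features are
   sequentially removed. Each removal step is scored on an internal
   validation split by its relative AUC contribution

   ```
   contribution_i = (AUC_w − AUC_i) / AUC_w
   ```

   where `AUC_w` uses all features and `AUC_i` the reduced set. The subset
   with maximal AUC (ties toward fewer features) is retained.
4. **Base models** — k-nearest neighbors (k = 5), RBF SVC with probability
   calibration, random forest and extra trees (500 trees, optional grid
   over {100, 300, 500, 700}), a two-layer LSTM recurrent network
   (64 units/layer, dropout 0.2, Adam lr 0.001, 10 epochs, batch 128;
   implemented in numpy, gradient-checked) and an MLP (hidden layers
   100→50, ≤500 iterations). All expose `P(toxic)` per compound.
5. **Ensembles** — equal-weight soft voting (mean probability; default),
   hard majority voting (ties → toxic), bagging (bootstrap-refit every
   member, soft-vote all replicates) and stacking (out-of-fold member
   probabilities → logistic meta-learner).
6. **Evaluation** — accuracy Q, sensitivity SE, specificity SP, precision
   PRE, F1, balanced accuracy BA = (SE+SP)/2 and ROC-AUC; stratified
   10-fold cross-validation and repeated-holdout mean ± SD summaries;
   one-way ANOVA for group comparisons.

Because curated hepatotoxicity compilations are assembled by hand and not
redistributable, the package ships two synthetic generators with known
ground truth: planted-signal binary fingerprints (class-dependent bit
rates, 62.5 % positives by default) and rule-labeled molecules (valid
organic SMILES labeled by a nitro-group structural alert).

## Worked example

```python
from hepatox import (HepatotoxicityClassifier, RuleLabeledSmilesSpec,
                     generate_rule_labeled_smiles)

df = generate_rule_labeled_smiles(RuleLabeledSmilesSpec(n_molecules=300, seed=4))
model = HepatotoxicityClassifier.from_dataframe(df, n_bits=1024, seed=4)
results = model.fit()          # stratified 80/20 holdout
print(results.summary())
```

```
Hepatotoxicity ensemble classifier
======================================================================
strategy: voting (soft vote)
members:  knn, svc, rf, et, rnn
features: circular_fingerprints (1024/1024 retained)
samples:  240 train / 60 test (seed 4)
----------------------------------------------------------------------
          accuracy     auc   f1  sensitivity  specificity  precision  balanced_accuracy
knn         0.9667  0.9981  0.9       0.8182          1.0        1.0             0.9091
svc         1.0000  1.0000  1.0       1.0000          1.0        1.0             1.0000
rf          1.0000  1.0000  1.0       1.0000          1.0        1.0             1.0000
et          1.0000  1.0000  1.0       1.0000          1.0        1.0             1.0000
rnn         0.8167  0.9351  0.0       0.0000          1.0        NaN             0.5000
ensemble    1.0000  1.0000  1.0       1.0000          1.0        1.0             1.0000
======================================================================
```

Read the table as fractions: the ensemble ranks every held-out toxic
molecule above every non-toxic one (AUC 1.0) and, at the default 0.5
threshold, recovers the whole toxic class. A `NaN` precision marks a 0/0
ratio (no positive predictions) rather than a silent zero — here the
recurrent member has learned the ranking (AUC 0.935) but after 10 epochs
on 240 molecules its probabilities still sit below 0.5, a calibration gap
the probability-averaging ensemble absorbs.

The same pipeline is scriptable from the shell:

```bash
hepatox synth smiles --n-molecules 300 -o compounds.csv
hepatox featurize compounds.csv --n-bits 1024 -o features.csv
hepatox train features.csv --members knn,svc,rf,et,rnn -o ensemble/
hepatox evaluate features.csv ensemble/ -o metrics.json
hepatox predict query.smi ensemble/ -o predictions.csv
```

or driven end to end from a YAML config with `hepatox run config.yaml`,
which writes a self-describing run directory (resolved config, curation
log, selected features, persisted ensemble, metrics, ROC points, log).

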