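# roughnet

Rough-set feature selection chained to a backpropagation neural network, for
binary classification of small tabular clinical datasets.

Clinical tables (hepatitis outcomes, breast tumour cytology, heart-disease
work-ups) are short and wide: a few hundred patients, a dozen-odd mostly
categorical attributes, missing cells, and a binary outcome. `roughnet`
implements a two-stage mining pipeline for exactly this regime:

1. **Feature selection by rough sets.** After threshold-based missing-value
   handling and cut-point discretization, the table is an information system
   *I* = (*U*, *A* ∪ *D*). For an attribute subset *P* ⊆ *A* the
   indiscernibility relation IND(*P*) groups objects equal on every attribute
   of *P*. The positive region Pos_*A*(*D*) — the union over decision classes
   *X* of the lower approximations ⋃{[x] : [x] ⊆ X} — contains the objects
   classifiable with certainty. All 2^|A| − 2 proper nonempty subsets are
   enumerated; *P* is accepted as a **reduct** when IND(*P*) restricted to
   Pos_*A*(*D*) equals IND(*A*) restricted to the same universe (exact mode),
   or when the pairwise partition similarity exceeds a threshold such as 0.90
   (approximate mode). The **core** is the intersection of all reducts.
2. **Classification by backpropagation.** Each selected reduct projects the
   table onto a few integer-coded features, min-max scaled to [0, 1], feeding
   a one-hidden-layer perceptron (25 tanh units, linear output) trained by
   full-batch gradient descent on the squared error against 0/1 targets.
   Evaluation uses held-out splits (80–20, 70–30, 60–40), 10-fold
   cross-validation inside the training portion, and confusion-matrix metrics
   (accuracy, sensitivity, specificity, TPR, FPR) plus ROC/AUC.

A synthetic-data generator with planted minimal reducts, controllable
inconsistency and MCAR missingness makes the whole pipeline testable without
any downloads.

## Worked example

The package bundles the classic six-patient heart-disease teaching table
(attributes Chp = chest-pain type, ECG, Vessel; decision Yes/No):

```python
import roughnet as rn
from roughnet.datasets import load_heart_sample

table = load_heart_sample()
print("IND(Chp):", sorted(sorted(b) for b in rn.ind_partition(table, ["Chp"]).blocks))
print("positive region:", sorted(rn.positive_region(table, table.condition_names).ids))
report = rn.find_reducts(table, mode="exact")
print("reducts:", [sorted(r.attributes) for r in report.reducts])
print("core:", sorted(report.core))
print("candidates examined:", report.counts.total)
```

prints

```
IND(Chp): [['P1', 'P4'], ['P2'], ['P3', 'P5', 'P6']]
positive region: ['P1', 'P2', 'P3', 'P4']
reducts: [['Chp', 'Vessel'], ['ECG', 'Vessel']]
core: ['Vessel']
candidates examined: 6
```

Patients P5 and P6 share every attribute value but disagree on the outcome,
so they fall outside the positive region (the table is inconsistent there).
Of the 2³ − 2 = 6 candidate subsets, exactly two reproduce the full
indiscernibility structure on the certain objects; every reduct must contain
Vessel, which is therefore the core. Metrics work the same way from counts:

```python
m = rn.metrics(rn.ConfusionMatrix(tp=26, fn=2, fp=2, tn=117))
print(m.rounded())
# {'accuracy': 97.28, 'sensitivity': 92.86, 'specificity': 98.32,
#  'tpr': 0.93, 'fpr': 0.017, 'auc': None}
```

## Command line

```sh
roughnet synth --objects 100 --informative 2 --noise 2 --missing-rate 0.05 \
    --seed 3 --out data.csv --schema-out schema.yaml --truth truth.json
roughnet preprocess --in data.csv --schema schema.yaml --out clean.csv --report report.json
roughnet reducts --in clean.csv --schema schema.yaml --mode exact --out reducts.json
roughnet train --in clean.csv --schema schema.yaml --reduct r.json \
    --split 0.8 --seed 42 --out model.json --metrics metrics.json
roughnet pipeline --config run.yaml --out-dir results/
```

Schemas for the three UCI clinical benchmarks (hepatitis, Wisconsin breast
cancer, Statlog heart disease) are bundled under `roughnet/data/`; the
datasets themselves are not redistributed — download them from the UCI
machine learning repository and point the CLI at the CSV.

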