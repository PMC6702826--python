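# mr2dnm

Hybrid tabular classification for biomedical-style datasets: a
mutual-information **maximum-relevance / minimum-redundancy (mRMR)** feature
ranking feeds a single **dendritic neuron model (DNM)** trained by
back-propagation. After training, the neuron's synapses are classified into
four connection regimes, pruned, and the surviving structure is exported as
a Boolean comparator circuit — so the learned rule is both a classifier and
a human-readable logic expression.

The package is aimed at practitioners who want an interpretable nonlinear
classifier for small/medium binary tables (clinical measurements, survey
records, sensor returns) and at researchers studying single-neuron
computation: the dendritic product structure lets one plastic neuron solve
nonlinearly separable tasks (XOR included) that a classical
McCulloch–Pitts unit cannot.

## The model

**Feature ranking.** Features are scored against the class label `c` by the
mRMR criterion on discrete mutual information
`I(x;y) = Σ p(x,y) log[p(x,y)/(p(x)p(y))]`:

```
Φ(S) = D(S) − R(S),   D = (1/|S|) Σ_{i∈S} I(x_i; c),
                      R = (1/|S|²) Σ_{i,r∈S} I(x_i; x_r)
```

ranked incrementally — the n-th feature maximizes
`I(x_r;c) − (1/(n−1)) Σ_{x_i∈S_{n−1}} I(x_r;x_i)` over the remaining
features. Continuous columns are discretized (3-bin mean±σ by default).

**The neuron.** With inputs `x_i ∈ [0,1]` and `M` dendritic branches:

```
Y_ij = σ(k (ω_ij x_i − q_ij))        synapse (sigmoid)
Z_j  = Π_i Y_ij                      dendrite (soft AND)
V    = Σ_j Z_j                       membrane (soft OR)
O    = σ(k_soma (V − θ_soma))        soma
```

Training minimizes `E = ½(T − O)²` per sample by gradient descent on
`(ω, q)` with the exact chain-rule gradients; one iteration is a full
shuffled pass over the training set.

**Pruning and circuit export.** Each trained synapse falls into one of four
regimes by the signs of `(ω, q)`: *direct* (passes `[x > θ]`, `θ = q/ω`),
*inverse* (logical NOT), *constant-1* (removable: multiplicative identity),
*constant-0* (its whole branch is removable: annihilator). What survives
compiles to comparators + NOT + per-branch AND + a root OR.

The feature-subset size is chosen by a wrapper sweep: train/evaluate the
neuron on every prefix of the mRMR order over repeated random 70/30 splits
and keep the size with the best mean test accuracy.

## Worked example

Rank a planted-redundancy table (2 informative features, 2 corrupted
duplicates, 2 noise coins), sweep the prefix size, train, prune, export:

```python
from mr2dnm import gen_redundant, MRMRSelector, DendriticNeuronClassifier, split_train_test
from mr2dnm.evaluation import feature_size_sweep
from mr2dnm.pruning import prune, to_logic_circuit, circuit_expression

ds = gen_redundant(n=300, n_informative=2, n_duplicates=2, n_noise=2,
                   flip_prob=0.25, label_flip_prob=0.1, seed=9)
sel = MRMRSelector(nominal_columns=tuple(range(6))).fit(ds.X, ds.y)
print([f"F{i+1}" for i in sel.order_])
# ['F2', 'F1', 'F6', 'F4', 'F3', 'F5']   <- both informative features first

res = feature_size_sweep(ds, sel.ranking_, n_runs=3, base_seed=2,
                         n_branches=3, k=5.0, eta=0.1, iterations=60)
print(res.to_frame())
#  size          features  mean_acc   sd_acc  mean_auc  mean_final_mse
#     1                F2  0.807407 0.227800  0.916192        0.100953
#     2             F2 F1  0.937037 0.006415  0.986830        0.035734
#     3          F2 F1 F6  0.929630 0.016973  0.987965        0.030875
#     ...
print(res.best_size)   # 2  <- the sweep recovers the planted structure
```

Training on the chosen prefix and exporting the circuit:

```python
idx = list(sel.order_[:res.best_size])
train_ds, test_ds = split_train_test(ds, 0.7, seed=0)
clf = DendriticNeuronClassifier(n_branches=3, k=5.0, eta=0.1, iterations=60, seed=1)
clf.fit(train_ds.X[:, idx], train_ds.y)
print(clf.score(test_ds.X[:, idx], test_ds.y))        # 0.9333
m = prune(clf.arch_, clf.params_)
print(m.counts)                                        # (2, 2) of the initial (6, 3)
print(circuit_expression(to_logic_circuit(m, clf.arch_.n_features)))
# x1>0.7792 OR x2>0.4878
```

The printed circuit *is* the learned rule: predict class 1 when either
selected (binary) feature fires, which is exactly the planted OR of the
two informative features.

The same pipeline is available from the shell:

```bash
mr2dnm synth redundant --n 300 --seed 9 --out data.csv
mr2dnm rank  --input data.csv --out ranking.json
mr2dnm sweep --input data.csv --runs 5 --seed 0 --out sweep.csv
mr2dnm train --input data.csv --seed 1 --out model.json --trace trace.csv
mr2dnm prune --model model.json --out morphology.json
mr2dnm export-circuit --model model.json --out netlist.json
```

Presets `wbcd`, `bupa`, `iono`, `pima`, `vote` (`--preset bupa`) carry the
published per-dataset hyperparameters for full-scale runs on the UCI files.

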