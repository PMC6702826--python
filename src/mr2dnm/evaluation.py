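"""Classification metrics, multi-run aggregation, and the wrapper sweep.

The headline protocol is: rank features by mRMR once, then for every prefix
size s of the ranking train the dendritic neuron on the top-s features over
several independent runs (each re-randomizing the 70/30 split, the weight
initialization and the shuffle order) and pick the size s* maximizing mean
test accuracy, smallest s on ties.  AUC is computed rank-based (the
Mann-Whitney statistic with midranks for tied scores), which equals the
trapezoidal area under the ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data import Dataset, split_train_test
from .dnm import forward_batch, predict_label
from .training import DendriticNeuronClassifier

__all__ = [
    "accuracy",
    "roc_auc",
    "RunAggregate",
    "repeated_runs",
    "SweepRecord",
    "SweepResult",
    "feature_size_sweep",
]


def accuracy(labels_true, labels_pred) -> float:
    """Fraction of matching labels."""
    t = np.asarray(labels_true)
    p = np.asarray(labels_pred)
    if t.shape != p.shape:
        raise ValueError("label vectors must have identical shape")
    if t.size == 0:
        raise ValueError("empty label vectors")
    return float(np.mean(t == p))


def roc_auc(labels_true, scores) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    Midranks handle tied scores, matching the trapezoidal ROC area.
    Raises on degenerate single-class input, where the area is undefined.
    """
    y = np.asarray(labels_true).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have identical shape")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: only one class present")
    ranks = rankdata(s)  # midranks
    rank_sum_pos = ranks[y == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class RunAggregate:
    """Summary over independent runs of split + train + test."""

    mean_accuracy: float
    sd_accuracy: float
    mean_auc: float
    mean_final_mse: float
    per_run_accuracy: tuple[float, ...]
    per_run_auc: tuple[float, ...]


def repeated_runs(
    dataset: Dataset,
    n_runs: int = 30,
    base_seed: int = 0,
    train_fraction: float = 0.7,
    **clf_params,
) -> RunAggregate:
    """Average accuracy/AUC over independent runs.

    Run r derives its seed from ``base_seed`` and re-randomizes the
    train/test split, the parameter initialization and the sample shuffle.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    accs, aucs, mses = [], [], []
    for r in range(n_runs):
        seed = (base_seed * 100003 + r) % (2**31 - 1)
        train_ds, test_ds = split_train_test(dataset, train_fraction, seed=seed)
        clf = DendriticNeuronClassifier(seed=seed, **clf_params)
        clf.fit(train_ds.X, train_ds.y)
        scores = forward_batch(clf.arch_, clf.params_, test_ds.X)
        pred = predict_label(scores)
        accs.append(accuracy(test_ds.y, pred))
        try:
            aucs.append(roc_auc(test_ds.y, scores))
        except ValueError:  # degenerate test split
            aucs.append(np.nan)
        mses.append(float(clf.trace_.mse_per_iteration[-1]))
    accs = np.array(accs)
    return RunAggregate(
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std(ddof=1)) if n_runs > 1 else 0.0,
        mean_auc=float(np.nanmean(aucs)),
        mean_final_mse=float(np.mean(mses)),
        per_run_accuracy=tuple(accs.tolist()),
        per_run_auc=tuple(float(a) for a in aucs),
    )


@dataclass(frozen=True)
class SweepRecord:
    size: int
    feature_indices: tuple[int, ...]
    feature_names: tuple[str, ...]
    mean_accuracy: float
    sd_accuracy: float
    mean_auc: float
    mean_final_mse: float


@dataclass(frozen=True)
class SweepResult:
    """One record per evaluated prefix size, plus the chosen size s*."""

    records: tuple[SweepRecord, ...]
    best_size: int

    def record_for(self, size: int) -> SweepRecord:
        for rec in self.records:
            if rec.size == size:
                return rec
        raise KeyError(size)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "size": r.size,
                    "features": " ".join(r.feature_names),
                    "mean_acc": r.mean_accuracy,
                    "sd_acc": r.sd_accuracy,
                    "mean_auc": r.mean_auc,
                    "mean_final_mse": r.mean_final_mse,
                }
                for r in self.records
            ]
        )


def feature_size_sweep(
    dataset: Dataset,
    ranking,
    n_runs: int = 30,
    base_seed: int = 0,
    sizes=None,
    train_fraction: float = 0.7,
    **clf_params,
) -> SweepResult:
    """Wrapper selection of the mRMR prefix size.

    For each prefix size s, the dataset restricted to the top-s ranked
    features is evaluated by `repeated_runs`; the chosen s* is the argmax of
    mean accuracy, smallest size on ties.
    """
    order = list(ranking.order)
    if len(order) != dataset.n_features or set(order) != set(range(dataset.n_features)):
        raise ValueError("ranking does not match the dataset's features")
    if sizes is None:
        sizes = range(1, dataset.n_features + 1)

    records = []
    for s in sizes:
        idx = tuple(order[:s])
        sub = Dataset(
            X=dataset.X[:, idx],
            y=dataset.y,
            feature_names=tuple(dataset.feature_names[i] for i in idx),
        )
        agg = repeated_runs(
            sub, n_runs=n_runs, base_seed=base_seed, train_fraction=train_fraction, **clf_params
        )
        records.append(
            SweepRecord(
                size=int(s),
                feature_indices=idx,
                feature_names=tuple(dataset.feature_names[i] for i in idx),
                mean_accuracy=agg.mean_accuracy,
                sd_accuracy=agg.sd_accuracy,
                mean_auc=agg.mean_auc,
                mean_final_mse=agg.mean_final_mse,
            )
        )
    best = max(records, key=lambda r: (r.mean_accuracy, -r.size))
    return SweepResult(records=tuple(records), best_size=best.size)
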