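"""Dataset ingestion, cleaning, normalization, splitting and fixtures.

The pipeline mirrors the standard tabular-classification preparation:
rows with missing values are deleted, nominal columns are ordinally coded,
every feature is min-max normalized to [0, 1] over the full cleaned table,
and the samples are split 70/30 at random into training and testing sets.

Three seed-deterministic generators provide synthetic benchmarks:
an XOR cloud (nonlinear separability), a planted-redundancy table
(informative features, corrupted duplicates, pure noise), and tables
labeled by a random ground-truth comparator circuit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pruning import Comparator, LogicCircuit, evaluate_circuit_batch

__all__ = [
    "Dataset",
    "load_table",
    "drop_missing",
    "normalize_minmax",
    "split_train_test",
    "gen_xor",
    "gen_redundant",
    "gen_circuit_labeled",
]


@dataclass
class Dataset:
    """In-memory feature table with binary labels.

    ``X`` is samples x features; after `normalize_minmax` every column
    lies in [0, 1].  ``missing_mask`` flags cells that were missing in the
    source file (all False after `drop_missing`).
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]
    nominal_columns: tuple[int, ...] = ()
    missing_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on sample count")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("one name per feature column")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_frame(self, label_column: str = "class") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df[label_column] = self.y
        return df


def load_table(
    path,
    label_column: str,
    missing_token: str = "?",
    positive_class=None,
    sep: str = ",",
) -> Dataset:
    """Read a delimited text table into a raw Dataset.

    Non-numeric columns are ordinally coded (sorted category order) and
    recorded as nominal; cells equal to ``missing_token`` are flagged in
    ``missing_mask`` (use `drop_missing` to delete those rows).  The label
    becomes 1 for ``positive_class`` (default: the lexicographically
    largest label value).
    """
    df = pd.read_csv(path, sep=sep, na_values=[missing_token], keep_default_na=False)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {list(df.columns)}")
    y_raw = df[label_column]
    feats = df.drop(columns=[label_column])

    missing_mask = feats.isna().to_numpy()
    nominal, coding = [], {}
    X = np.empty(feats.shape, dtype=float)
    for j, col in enumerate(feats.columns):
        series = feats[col]
        numeric = pd.to_numeric(series, errors="coerce")
        if numeric.notna().equals(series.notna()):
            X[:, j] = numeric.to_numpy(dtype=float)
        else:
            cats = sorted(series.dropna().astype(str).unique())
            codes = {c: i for i, c in enumerate(cats)}
            coding[str(col)] = codes
            X[:, j] = [codes.get(str(v), np.nan) if pd.notna(v) else np.nan for v in series]
            nominal.append(j)
    missing_mask |= np.isnan(X)

    if positive_class is None:
        positive_class = sorted(y_raw.astype(str).unique())[-1]
    y = (y_raw.astype(str) == str(positive_class)).astype(int).to_numpy()

    return Dataset(
        X=np.nan_to_num(X, nan=0.0),
        y=y,
        feature_names=tuple(str(c) for c in feats.columns),
        nominal_columns=tuple(nominal),
        missing_mask=missing_mask,
        meta={"positive_class": str(positive_class), "nominal_coding": coding},
    )


def drop_missing(dataset: Dataset) -> Dataset:
    """Delete every row with at least one missing cell, preserving order."""
    if dataset.missing_mask is None or not dataset.missing_mask.any():
        return replace(dataset, missing_mask=np.zeros_like(dataset.X, dtype=bool))
    keep = ~dataset.missing_mask.any(axis=1)
    if not keep.any():
        warnings.warn("every row contains a missing value; dataset is empty")
    return replace(
        dataset,
        X=dataset.X[keep],
        y=dataset.y[keep],
        missing_mask=dataset.missing_mask[keep],
    )


def normalize_minmax(dataset: Dataset) -> Dataset:
    """Per-column (x - min) / (max - min) over the full cleaned table.

    A constant column maps to all zeros (with a warning).  Applied before
    splitting, so train and test share one scale.
    """
    X = dataset.X.copy()
    mins = X.min(axis=0)
    maxs = X.max(axis=0)
    span = maxs - mins
    const = span == 0
    if const.any():
        names = [dataset.feature_names[j] for j in np.nonzero(const)[0]]
        warnings.warn(f"constant column(s) {names} normalized to 0")
    span = np.where(const, 1.0, span)
    X = (X - mins) / span
    X[:, const] = 0.0
    meta = dict(dataset.meta, norm_min=mins.tolist(), norm_max=maxs.tolist())
    return replace(dataset, X=X, meta=meta)


def split_train_test(
    dataset: Dataset, train_fraction: float = 0.7, seed: int = 0
) -> tuple[Dataset, Dataset]:
    """Seeded random split; train size is round-half-up(fraction * n).

    Round-half-up is the unique rule reproducing the canonical 70/30
    counts for n = 683 (478/205), 345 (242/103) and 768 (538/230).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n = dataset.n_samples
    # round product to 9 decimals first: 0.7 * 345 is 241.4999... in binary
    n_train = int(np.floor(np.round(train_fraction * n, 9) + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    tr, te = perm[:n_train], perm[n_train:]

    def take(idx):
        return replace(
            dataset,
            X=dataset.X[idx],
            y=dataset.y[idx],
            missing_mask=None if dataset.missing_mask is None else dataset.missing_mask[idx],
        )

    return take(tr), take(te)


def gen_xor(n_per_corner: int = 50, noise_sd: float = 0.1, seed: int = 0) -> Dataset:
    """Gaussian clouds at the corners of [0, 1]^2, labels = XOR of corners.

    The minimal nonlinearly separable benchmark: no single linear boundary
    (and no single AND term) separates the classes.  Points are clipped to
    [0, 1]; noise_sd=0 gives the bare 4-point truth table.
    """
    rng = np.random.default_rng(seed)
    corners = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    labels = np.array([0, 1, 1, 0])
    X = np.repeat(corners, n_per_corner, axis=0)
    X = X + rng.normal(0.0, noise_sd, size=X.shape)
    X = np.clip(X, 0.0, 1.0)
    y = np.repeat(labels, n_per_corner)
    return Dataset(
        X=X, y=y, feature_names=("F1", "F2"), meta={"generator": "xor", "seed": seed}
    )


def gen_redundant(
    n: int = 300,
    n_informative: int = 2,
    n_duplicates: int = 2,
    n_noise: int = 2,
    flip_prob: float = 0.0,
    label_flip_prob: float = 0.1,
    seed: int = 0,
) -> Dataset:
    """Planted-structure binary table: informative, duplicate and noise features.

    Informative features equal the label with ``label_flip_prob`` corruption
    (so their MI with the class is high but not degenerate); each duplicate
    copies one informative feature with ``flip_prob`` bit flips; noise
    features are independent fair coins.  Ground-truth roles are recorded
    in ``meta['roles']`` in column order.
    """
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    cols, roles = [], []
    informative_idx = []
    for i in range(n_informative):
        flips = rng.random(n) < label_flip_prob
        col = np.where(flips, 1 - y, y)
        informative_idx.append(len(cols))
        cols.append(col)
        roles.append("informative")
    for d in range(n_duplicates):
        src = informative_idx[d % max(n_informative, 1)]
        flips = rng.random(n) < flip_prob
        cols.append(np.where(flips, 1 - cols[src], cols[src]))
        roles.append(f"duplicate_of_{src}")
    for _ in range(n_noise):
        cols.append(rng.integers(0, 2, size=n))
        roles.append("noise")
    X = np.column_stack(cols).astype(float)
    names = tuple(f"F{j + 1}" for j in range(X.shape[1]))
    return Dataset(
        X=X,
        y=y,
        feature_names=names,
        nominal_columns=tuple(range(X.shape[1])),
        meta={"generator": "redundant", "roles": roles, "seed": seed},
    )


def random_circuit(
    n_features: int,
    n_branches: int = 2,
    max_comparators_per_branch: int = 2,
    seed: int = 0,
) -> LogicCircuit:
    """A random ground-truth comparator circuit over [0, 1]^N inputs."""
    rng = np.random.default_rng(seed)
    branches = []
    for _ in range(n_branches):
        n_comp = int(rng.integers(1, max_comparators_per_branch + 1))
        feats = rng.choice(n_features, size=min(n_comp, n_features), replace=False)
        comps = tuple(
            Comparator(
                feature=int(f),
                theta=float(rng.uniform(0.2, 0.8)),
                polarity=str(rng.choice(["direct", "inverse"])),
            )
            for f in feats
        )
        branches.append(comps)
    return LogicCircuit(n_features=n_features, branches=tuple(branches))


def gen_circuit_labeled(
    n_features: int,
    n: int = 200,
    circuit: LogicCircuit | None = None,
    seed: int = 0,
    **circuit_kwargs,
) -> Dataset:
    """Uniform inputs on [0, 1]^N labeled by a comparator circuit.

    If no circuit is supplied, a random one is generated from the seed and
    stored in ``meta['circuit']`` as ground truth for recovery tests.
    """
    rng = np.random.default_rng(seed)
    if circuit is None:
        circuit = random_circuit(n_features, seed=seed, **circuit_kwargs)
    if circuit.n_features != n_features:
        raise ValueError("circuit arity disagrees with n_features")
    X = rng.uniform(0.0, 1.0, size=(n, n_features))
    y = evaluate_circuit_batch(circuit, X)
    names = tuple(f"F{j + 1}" for j in range(n_features))
    return Dataset(
        X=X,
        y=y,
        feature_names=names,
        meta={"generator": "circuit", "circuit": circuit, "seed": seed},
    )
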