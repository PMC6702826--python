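"""Back-propagation training of the dendritic neuron model.

The per-sample squared error E = (1/2)(T - O)^2 is minimized by plain
gradient descent on the synaptic parameters (omega, q).  The analytic
gradient follows the chain through soma, membrane, branch product and
synaptic sigmoid:

    dE/dw_ij = (O - T) * k_soma O (1 - O) * prod_{L != i} Y_Lj * k x_i Y_ij (1 - Y_ij)
    dE/dq_ij = (O - T) * k_soma O (1 - O) * prod_{L != i} Y_Lj * (-k) Y_ij (1 - Y_ij)

Updates are applied per sample (online) in a seeded shuffled order; one
"iteration" is one full pass over the training set, after which the mean
of E over the set is recorded.  Parameters are initialized uniformly on
[-1.5, 1.5].

`DendriticNeuronClassifier` packages the whole procedure as a
scikit-learn classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_is_fitted, validate_data

from .dnm import (
    DNMArchitecture,
    DNMParameters,
    forward_batch,
    predict_label,
    sigmoid,
)

__all__ = [
    "TrainingConfig",
    "TrainingTrace",
    "init_params",
    "sample_error",
    "gradients",
    "update_step",
    "train",
    "DendriticNeuronClassifier",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Gradient-descent knobs: learning rate eta, epoch count, seed, init range."""

    eta: float
    iterations: int
    seed: int = 0
    init_low: float = -1.5
    init_high: float = 1.5

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.init_low >= self.init_high:
            raise ValueError("init_low must be below init_high")


@dataclass
class TrainingTrace:
    """Per-epoch mean squared error and the final parameters."""

    mse_per_iteration: np.ndarray
    final_params: DNMParameters
    initial_params: DNMParameters | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.mse_per_iteration = np.asarray(self.mse_per_iteration, dtype=float)
        if (self.mse_per_iteration < 0).any():
            raise ValueError("MSE cannot be negative")


def init_params(arch: DNMArchitecture, config: TrainingConfig) -> DNMParameters:
    """Uniform random init of omega and q on [init_low, init_high], seeded."""
    rng = np.random.default_rng(config.seed)
    shape = (arch.n_features, arch.n_branches)
    omega = rng.uniform(config.init_low, config.init_high, size=shape)
    q = rng.uniform(config.init_low, config.init_high, size=shape)
    return DNMParameters(omega, q)


def sample_error(O: float, T: int) -> float:
    """Half squared error E = (1/2)(T - O)^2 of one sample."""
    return 0.5 * (T - O) ** 2


def gradients(
    arch: DNMArchitecture, params: DNMParameters, x, T: int
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic dE/domega and dE/dq (each N x M) for one sample."""
    x = np.asarray(x, dtype=float)
    if x.shape != (arch.n_features,):
        raise ValueError(f"expected {arch.n_features} features, got shape {x.shape}")
    Y = sigmoid(arch.k * (params.omega * x[:, None] - params.q))  # N x M
    Z = np.prod(Y, axis=0)  # M
    V = float(Z.sum())
    O = float(sigmoid(arch.k_soma * (V - arch.theta_soma)))

    dE_dO = O - T
    dO_dV = arch.k_soma * O * (1.0 - O)
    # product over the other synapses of the branch; Y is bounded away from
    # 0 only in exact arithmetic, so use a masked quotient-free form
    with np.errstate(divide="ignore", invalid="ignore"):
        dZ_dY = np.where(Y > 0, Z[None, :] / Y, 0.0)
    zero_rows = Y == 0.0
    if zero_rows.any():
        # recompute affected entries by explicit leave-one-out product
        for i, j in zip(*np.nonzero(zero_rows)):
            dZ_dY[i, j] = np.prod(np.delete(Y[:, j], i))
    dY_dw = arch.k * x[:, None] * Y * (1.0 - Y)
    dY_dq = -arch.k * Y * (1.0 - Y)

    common = dE_dO * dO_dV * dZ_dY
    return common * dY_dw, common * dY_dq


def update_step(
    params: DNMParameters, grads: tuple[np.ndarray, np.ndarray], eta: float
) -> DNMParameters:
    """Gradient-descent step: new = old - eta * grad, elementwise."""
    g_omega, g_q = grads
    return DNMParameters(params.omega - eta * g_omega, params.q - eta * g_q)


def train(
    arch: DNMArchitecture,
    X,
    y,
    config: TrainingConfig,
    params: DNMParameters | None = None,
) -> TrainingTrace:
    """Online BP training: seeded shuffle each epoch, per-sample updates.

    Records the training-set mean of E after every epoch.  Fully
    deterministic given (seed, data, config).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("training set must be a nonempty 2-D matrix")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on sample count")

    rng = np.random.default_rng(config.seed)
    if params is None:
        params = init_params(arch, config)
    else:
        params = params.copy()
    initial = params.copy()

    n = X.shape[0]
    mse = np.empty(config.iterations)
    for epoch in range(config.iterations):
        for idx in rng.permutation(n):
            g = gradients(arch, params, X[idx], int(y[idx]))
            params = update_step(params, g, config.eta)
        O = forward_batch(arch, params, X)
        mse[epoch] = float(np.mean(0.5 * (y - O) ** 2))
    return TrainingTrace(mse_per_iteration=mse, final_params=params, initial_params=initial)


class DendriticNeuronClassifier(ClassifierMixin, BaseEstimator):
    """Single dendritic neuron binary classifier trained by back-propagation.

    Parameters mirror the model architecture and training loop: ``M``
    dendritic branches, synaptic steepness ``k``, soma steepness ``k_soma``
    and threshold ``theta_soma``, learning rate ``eta``, epoch count
    ``iterations`` and the RNG ``seed`` governing initialization and the
    per-epoch shuffle.  Features are expected in [0, 1]; labels binary.

    Attributes
    ----------
    arch_ : DNMArchitecture
    params_ : DNMParameters
        Trained synaptic weights (omega, q), each ``(n_features, M)``.
    trace_ : TrainingTrace
        Per-epoch training MSE.
    classes_ : ndarray
        The two class labels, mapped to soma targets 0 and 1 in sorted order.
    """

    def __init__(
        self,
        n_branches: int = 10,
        k: float = 3.0,
        k_soma: float = 10.0,
        theta_soma: float = 0.5,
        eta: float = 0.01,
        iterations: int = 1000,
        seed: int = 0,
        init_low: float = -1.5,
        init_high: float = 1.5,
        cutoff: float = 0.5,
    ):
        self.n_branches = n_branches
        self.k = k
        self.k_soma = k_soma
        self.theta_soma = theta_soma
        self.eta = eta
        self.iterations = iterations
        self.seed = seed
        self.init_low = init_low
        self.init_high = init_high
        self.cutoff = cutoff

    def fit(self, X, y):
        X, y = validate_data(self, X, y, dtype=float)
        self.classes_ = unique_labels(y)
        if self.classes_.shape[0] > 2:
            raise ValueError("binary classification only")
        y01 = (y == self.classes_[-1]).astype(int)
        self.arch_ = DNMArchitecture(
            n_features=X.shape[1],
            n_branches=self.n_branches,
            k=self.k,
            k_soma=self.k_soma,
            theta_soma=self.theta_soma,
        )
        config = TrainingConfig(
            eta=self.eta,
            iterations=self.iterations,
            seed=self.seed,
            init_low=self.init_low,
            init_high=self.init_high,
        )
        self.trace_ = train(self.arch_, X, y01, config)
        self.params_ = self.trace_.final_params
        return self

    def decision_function(self, X):
        """Soma outputs in (0, 1) for each sample."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=float)
        return forward_batch(self.arch_, self.params_, X)

    def predict_proba(self, X):
        O = self.decision_function(X)
        return np.column_stack([1.0 - O, O])

    def predict(self, X):
        O = self.decision_function(X)
        return self.classes_[predict_label(O, cutoff=self.cutoff)]
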