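"""Dendritic neuron model (DNM) forward computation.

A single neuron with N inputs and M dendritic branches.  Each input i feeds
every branch j through a synaptic sigmoid

    Y_ij = 1 / (1 + exp(-k (w_ij x_i - q_ij))),

branch outputs are the product of their synapse outputs (soft AND),
the membrane sums the branches (soft OR), and the soma applies a final
sigmoid with steepness k_soma and threshold theta_soma.

The trained (w, q) pair of every synapse places it in one of four regimes —
direct, inverse, constant-0, constant-1 — which is what makes the model
prunable and exportable as a Boolean comparator circuit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "DNMArchitecture",
    "DNMParameters",
    "ConnectionType",
    "sigmoid",
    "synapse_output",
    "synapse_threshold",
    "classify_connection",
    "dendrite_output",
    "membrane_output",
    "soma_output",
    "forward",
    "forward_batch",
    "predict_label",
    "save_model",
    "load_model",
]


def sigmoid(z):
    """Overflow-safe logistic function, valid for any finite argument."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DNMArchitecture:
    """Fixed structural constants of the neuron.

    n_features : N, inputs per branch.
    n_branches : M, dendritic branches.
    k : synaptic sigmoid steepness (> 0).
    k_soma : soma sigmoid steepness (> 0).
    theta_soma : soma threshold in [0, 1].
    """

    n_features: int
    n_branches: int
    k: float = 3.0
    k_soma: float = 10.0
    theta_soma: float = 0.5

    def __post_init__(self) -> None:
        if self.n_features < 1 or self.n_branches < 1:
            raise ValueError("need at least one feature and one branch")
        if self.k <= 0 or self.k_soma <= 0:
            raise ValueError("steepness parameters must be positive")
        if not 0.0 <= self.theta_soma <= 1.0:
            raise ValueError("theta_soma must lie in [0, 1]")


@dataclass
class DNMParameters:
    """Trainable synaptic weights: omega and q, both N x M."""

    omega: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.omega.shape != self.q.shape or self.omega.ndim != 2:
            raise ValueError("omega and q must be 2-D with identical shape")
        if not (np.all(np.isfinite(self.omega)) and np.all(np.isfinite(self.q))):
            raise ValueError("parameters must be finite")

    def copy(self) -> "DNMParameters":
        return DNMParameters(self.omega.copy(), self.q.copy())


class ConnectionType(str, Enum):
    DIRECT = "direct"
    INVERSE = "inverse"
    CONSTANT_0 = "constant_0"
    CONSTANT_1 = "constant_1"


def synapse_output(x, omega, q, k):
    """Synaptic sigmoid Y = sigma(k (omega x - q)); strictly inside (0, 1)."""
    if k <= 0:
        raise ValueError("k must be positive")
    return sigmoid(k * (np.asarray(omega) * x - np.asarray(q)))


def synapse_threshold(omega: float, q: float) -> float:
    """theta = q / omega, where the synaptic sigmoid crosses 0.5."""
    if omega == 0:
        raise ZeroDivisionError("undefined threshold: omega is zero (constant connection)")
    return q / omega


def classify_connection(omega: float, q: float) -> ConnectionType:
    """Assign a synapse to one of the four connection regimes.

    For omega > 0: q < 0 -> constant-1; 0 < q < omega -> direct;
    q > omega -> constant-0.  For omega < 0: q < omega -> constant-1;
    omega < q < 0 -> inverse; q > 0 -> constant-0.  Boundaries (which have
    measure zero under random initialization) go to the adjacent constant
    type, and omega == 0 is constant by construction: constant-0 for q > 0,
    constant-1 otherwise.
    """
    if omega > 0:
        if q <= 0:
            return ConnectionType.CONSTANT_1
        if q < omega:
            return ConnectionType.DIRECT
        return ConnectionType.CONSTANT_0
    if omega < 0:
        if q <= omega:
            return ConnectionType.CONSTANT_1
        if q < 0:
            return ConnectionType.INVERSE
        return ConnectionType.CONSTANT_0
    return ConnectionType.CONSTANT_0 if q > 0 else ConnectionType.CONSTANT_1


def dendrite_output(synapse_outputs) -> float:
    """Branch output Z_j: product of the branch's synapse outputs."""
    y = np.asarray(synapse_outputs, dtype=float)
    if y.size == 0:
        raise ValueError("a dendritic branch cannot be evaluated empty")
    return float(np.prod(y))


def membrane_output(branch_outputs) -> float:
    """Membrane potential V: sum over branches; empty sum is 0."""
    return float(np.sum(branch_outputs))


def soma_output(V: float, k_soma: float, theta_soma: float) -> float:
    """Soma sigmoid O = sigma(k_soma (V - theta_soma)); 0.5 at V = theta."""
    return float(sigmoid(k_soma * (V - theta_soma)))


def forward(arch: DNMArchitecture, params: DNMParameters, x) -> float:
    """Full forward pass for a single sample: soma(membrane(dendrites))."""
    x = np.asarray(x, dtype=float)
    if x.shape != (arch.n_features,):
        raise ValueError(f"expected {arch.n_features} features, got shape {x.shape}")
    Y = synapse_output(x[:, None], params.omega, params.q, arch.k)  # N x M
    Z = np.prod(Y, axis=0)
    V = float(Z.sum())
    return soma_output(V, arch.k_soma, arch.theta_soma)


def forward_batch(arch: DNMArchitecture, params: DNMParameters, X) -> np.ndarray:
    """Vectorized forward pass over rows of X (n_samples x N)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != arch.n_features:
        raise ValueError(f"expected {arch.n_features} features, got {X.shape[1]}")
    # Y: samples x N x M
    Y = sigmoid(arch.k * (params.omega[None] * X[:, :, None] - params.q[None]))
    V = np.prod(Y, axis=1).sum(axis=1)
    return sigmoid(arch.k_soma * (V - arch.theta_soma))


def predict_label(O, cutoff: float = 0.5) -> np.ndarray | int:
    """Hard class decision: 1 iff the soma output reaches the cutoff."""
    O = np.asarray(O)
    labels = (O >= cutoff).astype(int)
    return labels if labels.ndim else int(labels)


def save_model(path, arch: DNMArchitecture, params: DNMParameters, extra: dict | None = None) -> None:
    """Serialize {arch, omega, q} as JSON; round-trips bit-exactly via repr floats."""
    payload = {
        "arch": {
            "n_features": arch.n_features,
            "n_branches": arch.n_branches,
            "k": arch.k,
            "k_soma": arch.k_soma,
            "theta_soma": arch.theta_soma,
        },
        "omega": params.omega.tolist(),
        "q": params.q.tolist(),
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> tuple[DNMArchitecture, DNMParameters]:
    with open(path) as fh:
        payload = json.load(fh)
    arch = DNMArchitecture(**payload["arch"])
    params = DNMParameters(np.array(payload["omega"]), np.array(payload["q"]))
    return arch, params
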