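"""Neuron pruning and Boolean logic-circuit export.

After training, each synapse falls into one of four regimes.  Two of them
are structurally removable:

* constant-1 synapses multiply their branch by ~1 and are dropped
  (synaptic pruning, the multiplicative identity);
* a branch containing any constant-0 synapse always outputs ~0 and is
  removed whole (dendritic pruning, the annihilator).

What survives — direct and inverse synapses grouped by branch — maps onto a
comparator circuit: each direct synapse becomes the predicate [x_i > theta],
each inverse synapse its negation, each branch an AND over its predicates,
and the membrane an OR over branches.  The mapping is exact in the
saturated (large-k) limit of the sigmoids and approximate otherwise; the
agreement fraction is reported by `pruning_fidelity`, never assumed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .dnm import (
    ConnectionType,
    DNMArchitecture,
    DNMParameters,
    classify_connection,
    forward_batch,
    predict_label,
    synapse_threshold,
)

__all__ = [
    "SurvivingSynapse",
    "PrunedMorphology",
    "Comparator",
    "LogicCircuit",
    "prune",
    "count_initial_nodes",
    "to_logic_circuit",
    "evaluate_circuit",
    "pruning_fidelity",
    "circuit_expression",
    "save_circuit",
    "load_circuit",
]


@dataclass(frozen=True)
class SurvivingSynapse:
    feature: int  # 0-based input index
    connection: ConnectionType  # direct or inverse only
    theta: float


@dataclass(frozen=True)
class PrunedMorphology:
    """Simplified neuron after synaptic and dendritic pruning.

    ``branches`` maps surviving branch id -> surviving synapses (possibly
    an empty list for an always-true branch whose synapses were all
    constant-1).  ``counts`` is (surviving synapses, surviving branches).
    """

    branches: dict[int, tuple[SurvivingSynapse, ...]]

    @property
    def surviving_branches(self) -> tuple[int, ...]:
        return tuple(sorted(self.branches))

    @property
    def counts(self) -> tuple[int, int]:
        n_syn = sum(len(s) for s in self.branches.values())
        return n_syn, len(self.branches)


def count_initial_nodes(arch: DNMArchitecture) -> tuple[int, int]:
    """Node budget before pruning: (N*M synaptic points, M dendritic points)."""
    return arch.n_features * arch.n_branches, arch.n_branches


def prune(arch: DNMArchitecture, params: DNMParameters) -> PrunedMorphology:
    """Apply both pruning rules to trained parameters.

    Constant-1 synapses are dropped; any branch holding a constant-0
    synapse is dropped whole.  A branch whose synapses were all constant-1
    survives with zero comparators (always-true term, contributing +1 to
    the membrane sum).
    """
    branches: dict[int, tuple[SurvivingSynapse, ...]] = {}
    for j in range(arch.n_branches):
        kept: list[SurvivingSynapse] = []
        dead = False
        for i in range(arch.n_features):
            ctype = classify_connection(params.omega[i, j], params.q[i, j])
            if ctype is ConnectionType.CONSTANT_0:
                dead = True
                break
            if ctype is ConnectionType.CONSTANT_1:
                continue
            kept.append(
                SurvivingSynapse(
                    feature=i,
                    connection=ctype,
                    theta=synapse_threshold(params.omega[i, j], params.q[i, j]),
                )
            )
        if not dead:
            branches[j] = tuple(kept)
    return PrunedMorphology(branches=branches)


@dataclass(frozen=True)
class Comparator:
    """Predicate [x_feature > theta], negated when polarity is inverse."""

    feature: int
    theta: float
    polarity: str  # "direct" or "inverse"

    def evaluate(self, x: np.ndarray) -> bool:
        fires = bool(x[self.feature] > self.theta)  # strict >
        return fires if self.polarity == "direct" else not fires


@dataclass(frozen=True)
class LogicCircuit:
    """OR of per-branch ANDs of comparators; an empty OR is constant false.

    A branch with zero comparators is an AND over nothing, i.e. constant
    true, which makes the whole circuit constant true.
    """

    n_features: int
    branches: tuple[tuple[Comparator, ...], ...]

    @property
    def n_comparators(self) -> int:
        return sum(len(b) for b in self.branches)


def to_logic_circuit(morphology: PrunedMorphology, n_features: int) -> LogicCircuit:
    """Compile the pruned morphology into a comparator circuit.

    Thresholds outside [0, 1] make the comparator constant on the input
    domain; that is reported as a warning but kept, mirroring the trained
    parameters faithfully.
    """
    import warnings

    branches = []
    for j in sorted(morphology.branches):
        comps = []
        for syn in morphology.branches[j]:
            if not 0.0 <= syn.theta <= 1.0:
                warnings.warn(
                    f"comparator threshold {syn.theta:.3f} outside [0, 1]: "
                    f"constant on the input domain (feature F{syn.feature + 1})",
                    stacklevel=2,
                )
            comps.append(
                Comparator(feature=syn.feature, theta=syn.theta, polarity=syn.connection.value)
            )
        branches.append(tuple(comps))
    return LogicCircuit(n_features=n_features, branches=tuple(branches))


def evaluate_circuit(circuit: LogicCircuit, x) -> int:
    """Boolean evaluation: OR over branches of AND over comparators."""
    x = np.asarray(x, dtype=float)
    for branch in circuit.branches:
        if all(c.evaluate(x) for c in branch):
            return 1
    return 0


def evaluate_circuit_batch(circuit: LogicCircuit, X) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.array([evaluate_circuit(circuit, row) for row in X], dtype=int)


def pruning_fidelity(arch: DNMArchitecture, params: DNMParameters, X) -> float:
    """Fraction of inputs where full-model prediction equals circuit output.

    Equals 1.0 when every synapse is saturated over the inputs; reported as
    a diagnostic, never asserted, for soft parameters.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    full = predict_label(forward_batch(arch, params, X))
    circuit = to_logic_circuit(prune(arch, params), n_features=arch.n_features)
    pruned = evaluate_circuit_batch(circuit, X)
    return float(np.mean(full == pruned))


def circuit_expression(circuit: LogicCircuit) -> str:
    """Human-readable Boolean expression, e.g. '(x1>0.50 AND NOT x3>0.20) OR ...'."""
    if not circuit.branches:
        return "FALSE"
    terms = []
    for branch in circuit.branches:
        if not branch:
            terms.append("TRUE")
            continue
        lits = [
            (f"x{c.feature + 1}>{c.theta:.4g}" if c.polarity == "direct"
             else f"NOT x{c.feature + 1}>{c.theta:.4g}")
            for c in branch
        ]
        terms.append("(" + " AND ".join(lits) + ")" if len(lits) > 1 else lits[0])
    return " OR ".join(terms)


def save_circuit(path, circuit: LogicCircuit, extra: dict | None = None) -> None:
    payload = {
        "n_features": circuit.n_features,
        "branches": [
            [{"feature": c.feature, "theta": c.theta, "polarity": c.polarity} for c in branch]
            for branch in circuit.branches
        ],
        "expression": circuit_expression(circuit),
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_circuit(path) -> LogicCircuit:
    with open(path) as fh:
        payload = json.load(fh)
    branches = tuple(
        tuple(Comparator(c["feature"], c["theta"], c["polarity"]) for c in branch)
        for branch in payload["branches"]
    )
    return LogicCircuit(n_features=payload["n_features"], branches=branches)
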