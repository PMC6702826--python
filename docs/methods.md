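# Methods

## Model and procedure

The classifier is a single neuron with explicit dendritic structure. Every
input feature `x_i ∈ [0,1]` contacts every dendritic branch `j` through its
own synaptic sigmoid `Y_ij = σ(k(ω_ij x_i − q_ij))`; a branch multiplies its
synapse outputs (`Z_j = Π_i Y_ij`, a soft AND), the membrane sums the
branches (`V = Σ_j Z_j`, a soft OR), and the soma thresholds the sum
(`O = σ(k_soma(V − θ_soma))`). The two trainable matrices `ω` and `q` (each
N×M) are fit by stochastic gradient descent on the per-sample half squared
error `E = ½(T − O)²` using the exact analytic chain-rule gradients; one
"iteration" is one full pass over the training set in a freshly shuffled
(seeded) order, after which the training MSE is recorded. Parameters start
uniform on [−1.5, 1.5].

A trained synapse is typed by the signs of `(ω, q)`:

| regime | condition | behaviour on [0,1] |
|---|---|---|
| direct | `0 < q < ω` | crosses 0.5 upward at `θ = q/ω ∈ (0,1)` |
| inverse | `ω < q < 0` | crosses 0.5 downward at `θ ∈ (0,1)` |
| constant-1 | `q < 0 < ω`, or `q < ω < 0` | output above 0.5 everywhere |
| constant-0 | `0 < ω < q`, or `ω < 0 < q` | output below 0.5 everywhere |

Constant-1 synapses are the branch's multiplicative identity and are
pruned; a constant-0 synapse annihilates its branch, which is removed
whole. The remainder maps to a logic circuit — direct synapse → comparator
`[x_i > θ]` (strict inequality), inverse → comparator + NOT, branch → AND,
membrane → OR. The mapping is exact only in the saturated (large `k`)
limit; on soft models the circuit/model agreement is *reported* as a
fidelity fraction, never assumed.

Feature selection is mRMR on discrete mutual information. Relevance of a
subset is the mean `I(x_i; c)`; redundancy is the mean pairwise `I(x_i; x_r)`
over **all ordered pairs including self-pairs**, exactly as the criterion's
double sum is written — with the documented consequence that a singleton's
redundancy equals its entropy. The practical search is the first-order
incremental rule (step 1: max relevance; step n: relevance minus mean MI
with the already-selected set), with ties broken toward the lowest original
feature index for reproducibility. An exhaustive Φ-maximizing search over
all C(N,k) subsets is included as an oracle for small instances (N ≤ 12,
k ≤ 4). The subset *size* is chosen by a wrapper: every prefix of the
ranking is trained and evaluated over repeated independent runs and the
accuracy-argmax size wins, smallest size on ties.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `k` | synaptic sigmoid steepness | 3 | 1 for the WBCD preset; larger k → harder gates, better circuit fidelity, slower gradients |
| `k_soma` | soma steepness | 10 | all presets use 10 |
| `theta_soma` | soma threshold on V | 0.5 | in [0,1]; 0.5 in all presets |
| `M` (`n_branches`) | dendritic branches | 10 | presets: 45/10/34/25/30; upper bound on the OR-of-ANDs terms |
| `eta` | learning rate | 0.01 | presets: 0.01/0.005/0.001/0.001/0.001 |
| `iterations` | full training passes | 1000 | 2000 for the BUPA preset |
| `init_low/high` | init range for ω, q | ±1.5 | uniform |
| discretizer | MI binning for continuous columns | mean±σ, 3 bins | `equal_width(k)` selectable; nominal columns used as codes |
| MI log base | scale of all MI values | natural log | rankings are provably invariant to it (uniform rescaling); tested |
| decision cutoff | class-1 threshold on O | 0.5 | ties go to class 1 |

The per-dataset presets reproduce the published benchmark protocol
(WBCD/BUPA/IONO/PIMA/VOTE); cleaned sample counts and the 70/30 split
sizes they imply are encoded alongside.

## Data pipeline

Rows containing missing values (token `?` by default) are deleted, nominal
columns are ordinally coded in sorted category order, and each column is
min-max normalized over the **full cleaned table before splitting**. That
ordering mirrors the benchmark protocol but leaks test-set extrema into the
scale; for the bounded, rank-preserving min-max map the effect on accuracy
is negligible, and it is documented rather than silently changed. The
train/test split draws `round-half-up(0.7·n)` training rows from a seeded
permutation — the unique rounding consistent with all five published
train/test count pairs (the product is pre-rounded to 9 decimals because
0.7·345 is 241.4999… in binary floating point).

## Synthetic generators

Three seeded generators make every stage testable without downloads:

* **XOR clouds** — Gaussian blobs at the corners of [0,1]², labels the XOR
  of the corner bits; the minimal nonlinearly separable task. With
  `noise_sd=0` it degenerates to the 4-point truth table.
* **Planted redundancy** — informative features equal to the label with a
  corruption probability, duplicates that copy an informative column with
  independent bit flips, and fair-coin noise columns; ground-truth roles
  travel in metadata so ranking claims are checkable.
* **Circuit-labeled tables** — uniform inputs labeled by a random (or
  supplied) comparator circuit, stored as ground truth for
  structure-recovery tests; label rates are validated against the
  circuit's geometric acceptance volume.

These fixtures exercise the mechanisms (redundancy penalties, nonlinear
separability, circuit semantics) but are cleaner than real tables: features
are conditionally independent given the label, noise is symmetric, and
class balance is near 1:1. Passing on them demonstrates correctness of the
machinery, not expected accuracy on skewed, correlated clinical data.

## Numerical choices and degenerate cases

* Sigmoids are evaluated in the two-branch overflow-safe form; gradients
  use the `Y(1−Y)`/`O(1−O)` identities, so saturation never overflows.
* `∂Z_j/∂Y_ij` is computed as `Z_j / Y_ij` with an explicit leave-one-out
  product fallback when a synapse output underflows to exactly 0.
* Zero-probability contingency cells contribute exactly 0 to MI (limit
  convention); tiny negative round-off is clipped at 0.
* Boundary parameter sets (`q = 0`, `q = ω`, `ω = 0`) have measure zero
  under the random initializer; they are assigned deterministically to the
  adjacent constant regime (`ω>0, q≤0` → constant-1; `ω>0, q≥ω` →
  constant-0; `ω<0, q≤ω` → constant-1; `ω<0, q≥0` → constant-0; `ω=0` →
  constant-0 iff `q>0`), so typing is a total function.
* A branch whose synapses were all constant-1 survives pruning as an
  always-true AND term (it genuinely contributes +1 to V), making the
  exported circuit constant-true — faithfully mirroring the model.
* An empty morphology exports a constant-false circuit; an empty membrane
  sums to 0.
* AUC uses midranks for tied scores (equals the trapezoidal ROC area) and
  raises on single-class inputs.
* Ranking tie-breaks go to the lowest original feature index; sweep
  tie-breaks to the smallest subset size.

## Design choices where the design was open

* **Update granularity** — per-sample (online) updates, matching the
  single-sample error the gradient formulas differentiate; "iterations"
  count epochs, not samples. No momentum, decay, or early stopping: exactly
  the configured number of passes.
* **Redundancy self-pairs** — kept, as the double sum is written. The
  exhaustive-Φ oracle consequently disagrees with the incremental rule at
  subset size 1 whenever feature entropies differ (Φ({i}) = I − H vs pure
  relevance); the size-1 equivalence is therefore tested on equal-entropy
  fixtures, and the incremental rule is the production path.
* **Per-run re-randomization** — each of the repeated runs redraws the
  70/30 split, the initialization and the shuffle order from an
  independently derived seed; aggregates report mean ± sd.
* **"Optimal subset"** — operationalized as the accuracy-argmax prefix of
  the mRMR total order; nothing beyond the two pruning rules minimizes the
  exported circuit.

## Problem sizes

The test suite and the acceptance script run on deliberately small
instances chosen to exercise every code path quickly: 6-feature ranking
oracles at n = 40, gradient checks over 100 random architectures up to
4×5, the 4-point XOR truth table at 2000 epochs × 10 seeds, a 625-point
fidelity grid, and a 300-sample 6-feature sweep at 3 runs × 60 epochs.
Full-scale benchmark runs (30 runs × 1000–2000 epochs on the UCI tables)
use the same code via the CLI presets.

## Known limitations

* Binary classification only; one soma, no multi-class extension.
* MI is estimated by plug-in counts after discretization; no KNN/kernel
  continuous estimators, so rankings on continuous data depend on the
  binning choice (both mean±σ and equal-width are selectable).
* BP on this architecture has seed-dependent local minima (e.g. basins
  where every synapse goes constant); single runs can fail to converge,
  which is precisely why the evaluation protocol averages independent
  runs.
* Circuit fidelity below saturation is dataset- and parameter-dependent;
  it is measured and reported, not guaranteed.
* No imputation, stratified splitting, or class weighting.
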