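"""Discrete mutual-information estimation.

Both halves of the mRMR criterion — relevance of a feature to the class and
redundancy between features — reduce to the discrete mutual information

    I(x; y) = sum_{x,y} p(x, y) log[ p(x, y) / (p(x) p(y)) ]

computed from a contingency table of category codes.  Continuous features
are discretized first; nominal features are used as category codes directly.

The log base defaults to the natural log.  Because a change of base rescales
every MI value by the same constant, mRMR rankings are invariant to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiscretizedVariable",
    "JointDistribution",
    "discretize",
    "as_nominal",
    "mutual_information",
    "entropy",
]


@dataclass(frozen=True)
class DiscretizedVariable:
    """A variable reduced to integer category codes.

    Parameters
    ----------
    codes : ndarray of int
        0-based category id per sample; every code lies in
        ``[0, n_categories)``.
    n_categories : int
        Number of categories (>= 1).
    origin : {"nominal", "binned"}
        Whether the codes are native category ids or the result of binning
        a continuous variable.
    bin_edges : ndarray or None
        Strictly increasing interior bin edges; present iff ``origin ==
        "binned"``.
    """

    codes: np.ndarray
    n_categories: int
    origin: str = "nominal"
    bin_edges: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int64)
        object.__setattr__(self, "codes", codes)
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")
        if codes.size and (codes.min() < 0 or codes.max() >= self.n_categories):
            raise ValueError("codes must lie in [0, n_categories)")
        if self.origin not in ("nominal", "binned"):
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.bin_edges is not None:
            edges = np.asarray(self.bin_edges, dtype=float)
            if edges.size > 1 and not np.all(np.diff(edges) > 0):
                raise ValueError("bin_edges must be strictly increasing")
            object.__setattr__(self, "bin_edges", edges)

    def __len__(self) -> int:
        return self.codes.size


@dataclass(frozen=True)
class JointDistribution:
    """Contingency table of two discretized variables."""

    counts: np.ndarray
    n: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or (counts < 0).any():
            raise ValueError("counts must be a nonnegative 2-D matrix")
        if counts.sum() != self.n:
            raise ValueError("counts must sum to n")

    @classmethod
    def from_codes(cls, x: DiscretizedVariable, y: DiscretizedVariable) -> "JointDistribution":
        if len(x) != len(y):
            raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
        counts = np.zeros((x.n_categories, y.n_categories), dtype=np.int64)
        np.add.at(counts, (x.codes, y.codes), 1)
        return cls(counts=counts, n=len(x))


def as_nominal(values) -> DiscretizedVariable:
    """Encode raw (possibly non-contiguous) category values as codes."""
    values = np.asarray(values)
    _, codes = np.unique(values, return_inverse=True)
    n_cat = int(codes.max()) + 1 if codes.size else 1
    return DiscretizedVariable(codes=codes, n_categories=n_cat, origin="nominal")


def discretize(values, n_bins: int = 3, strategy: str = "mean_std") -> DiscretizedVariable:
    """Bin a continuous variable into integer categories.

    ``equal_width`` splits the observed range into ``n_bins`` equal-width
    intervals.  ``mean_std`` always produces 3 bins: below ``mu - sigma``,
    within one standard deviation of the mean, and above ``mu + sigma`` —
    the customary discretizer of the mRMR literature.

    A constant column collapses to a single category.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")

    lo, hi = values.min(), values.max()
    if lo == hi:
        return DiscretizedVariable(
            codes=np.zeros(values.size, dtype=np.int64),
            n_categories=1,
            origin="binned",
            bin_edges=np.array([]),
        )

    if strategy == "equal_width":
        if n_bins < 2:
            raise ValueError("equal_width requires n_bins >= 2")
        edges = np.linspace(lo, hi, n_bins + 1)[1:-1]
    elif strategy == "mean_std":
        mu, sigma = values.mean(), values.std()
        edges = np.array([mu - sigma, mu + sigma])
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    codes = np.searchsorted(edges, values, side="right")
    # compress unused trailing/leading categories so codes stay contiguous
    used, codes = np.unique(codes, return_inverse=True)
    return DiscretizedVariable(
        codes=codes.astype(np.int64),
        n_categories=used.size,
        origin="binned",
        bin_edges=edges,
    )


def mutual_information(
    x: DiscretizedVariable, y: DiscretizedVariable, log_base: float | None = None
) -> float:
    """I(x; y) from the joint contingency table; always >= 0.

    Cells with zero probability contribute exactly 0 (the limit convention
    p log p -> 0).  ``log_base=None`` means natural log.
    """
    joint = JointDistribution.from_codes(x, y)
    return mutual_information_from_joint(joint, log_base=log_base)


def mutual_information_from_joint(
    joint: JointDistribution, log_base: float | None = None
) -> float:
    counts = joint.counts
    n = joint.n
    if n == 0:
        return 0.0
    pxy = counts / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    ratio = np.where(mask, pxy / np.where(mask, px * py, 1.0), 1.0)
    mi = float(np.sum(np.where(mask, pxy * np.log(ratio), 0.0)))
    if log_base is not None:
        if log_base <= 1:
            raise ValueError("log_base must be > 1")
        mi /= np.log(log_base)
    # clip tiny negative round-off; MI is nonnegative by Jensen
    return max(mi, 0.0)


def entropy(x: DiscretizedVariable, log_base: float | None = None) -> float:
    """Shannon entropy H(x) = -sum p log p; 0 for a constant variable."""
    if len(x) == 0:
        raise ValueError("empty input")
    counts = np.bincount(x.codes, minlength=x.n_categories)
    p = counts[counts > 0] / len(x)
    h = float(-np.sum(p * np.log(p)))
    if log_base is not None:
        if log_base <= 1:
            raise ValueError("log_base must be > 1")
        h /= np.log(log_base)
    return max(h, 0.0)
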