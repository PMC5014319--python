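"""Willshaw/Lernmatrix binary associative memory with familiarity discrimination.

The Lernmatrix stores associations between binary vectors by Hebbian clipping:
a synapse ``w_ij`` is set to 1 the first time the pre-synaptic bit ``x_j`` and
the post-synaptic bit ``y_i`` co-occur, and never reset.  One-step retrieval
thresholds each unit's dendritic sum at the maximum sum over all units, so only
the maximally correlated units fire.

Familiarity discrimination asks a weaker question than full recall: *was this
cue stored?*  For an auto-associative (symmetric) memory it is answered from
the quadratic form ``net = x^T W x`` — the negated Hopfield energy — or from
the cosine between the cue and its one-step retrieval, compared against a
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
import math
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "DegenerateRetrievalError",
    "RetrievalResult",
    "FamiliarityResult",
    "FamiliarityConfig",
    "Lernmatrix",
    "learn_pairs",
    "retrieve",
    "backward_project",
    "hamming_distance",
    "net_value",
    "energy",
    "familiarity",
    "familiarity_batch",
    "save_weights",
    "load_weights",
]


class DegenerateRetrievalError(ValueError):
    """Raised when the maximum dendritic sum is zero.

    The literal retrieval rule would then activate *every* unit (0 >= 0),
    returning an all-ones vector that carries no information; callers that
    only need a familiarity verdict may catch this and treat it as sim = 0.
    """


def as_binary_vector(x, dim: int | None = None) -> np.ndarray:
    """Validate and convert to a 1-D uint8 array of {0,1}."""
    a = np.asarray(x)
    if a.ndim != 1:
        raise ValueError(f"expected a 1-D binary vector, got shape {a.shape}")
    if a.size == 0:
        raise ValueError("empty binary vector")
    if not np.isin(a, (0, 1)).all():
        raise ValueError("binary vector entries must be 0 or 1")
    if dim is not None and a.size != dim:
        raise ValueError(f"dimension mismatch: expected {dim}, got {a.size}")
    return a.astype(np.uint8)


def _as_weight_matrix(W) -> np.ndarray:
    W = np.asarray(W)
    if W.ndim != 2:
        raise ValueError(f"weight matrix must be 2-D, got shape {W.shape}")
    if not np.isin(W, (0, 1)).all():
        raise ValueError("weight matrix entries must be 0 or 1")
    return W.astype(np.uint8)


@dataclass(frozen=True)
class RetrievalResult:
    """Outcome of one-step threshold retrieval.

    ``y[i] = 1`` iff ``sums[i] >= threshold_used`` with
    ``threshold_used = max(sums)`` (the unit threshold T).
    """

    y: np.ndarray
    threshold_used: int
    sums: np.ndarray


@dataclass(frozen=True)
class FamiliarityResult:
    """Familiarity verdict for a cue against an auto-associative memory.

    net
        quadratic form ``x^T W x`` (non-negative integer).
    energy
        Hopfield energy ``H = -net``.
    hamming
        Hamming distance between the cue and its one-step retrieval
        (None when retrieval was degenerate).
    cosine
        cosine between the cue and its one-step retrieval (None when
        degenerate).
    sim
        1 if the mode's statistic meets its threshold, else 0.
    threshold_t
        the threshold actually applied.
    mode
        "net" or "cosine".
    """

    net: int
    energy: int
    hamming: int | None
    cosine: float | None
    sim: int
    threshold_t: float
    mode: str


@dataclass(frozen=True)
class FamiliarityConfig:
    """Familiarity mode and threshold used by the search layers."""

    mode: str = "cosine"
    t: float | str = 0.87

    def __post_init__(self):
        if self.mode not in ("net", "cosine"):
            raise ValueError(f"unknown familiarity mode {self.mode!r}")


# ---------------------------------------------------------------------------
# functional core


def learn_pairs(pairs: Iterable[tuple[Sequence, Sequence]],
                auto_associative: bool = False) -> np.ndarray:
    """Learn address/retrieved pairs into a fresh binary weight matrix.

    Weights start at zero and ``w_ij`` is clipped to 1 whenever some pair has
    ``y_i * x_j = 1``; learning is monotone and order-independent.
    """
    W = None
    for x, y in pairs:
        x = as_binary_vector(x)
        y = as_binary_vector(y)
        if auto_associative and (x.size != y.size or not np.array_equal(x, y)):
            raise ValueError("auto-association requires address == retrieved")
        if W is None:
            W = np.zeros((y.size, x.size), dtype=np.uint8)
        elif W.shape != (y.size, x.size):
            raise ValueError(
                f"dimension mismatch across pairs: expected {W.shape}, "
                f"got {(y.size, x.size)}")
        np.logical_or(W, np.outer(y, x), out=W.view(bool))
    if W is None:
        raise ValueError("no pairs to learn")
    return W


def retrieve(W, x) -> RetrievalResult:
    """One-step retrieval with the maximum-sum threshold."""
    W = _as_weight_matrix(W)
    x = as_binary_vector(x, dim=W.shape[1])
    sums = W.astype(np.int64) @ x.astype(np.int64)
    T = int(sums.max())
    if T == 0:
        raise DegenerateRetrievalError(
            "maximum dendritic sum is 0 (empty memory or disjoint cue)")
    y = (sums >= T).astype(np.uint8)
    return RetrievalResult(y=y, threshold_used=T, sums=sums)


def backward_project(W, y) -> RetrievalResult:
    """Retrieve through the transposed matrix (BAM-style backward pass)."""
    W = _as_weight_matrix(W)
    return retrieve(W.T, y)


def hamming_distance(a, b) -> int:
    a = as_binary_vector(a)
    b = as_binary_vector(b, dim=a.size)
    return int(np.sum(a != b))


def net_value(W, x) -> int:
    """Quadratic form ``net = x^T W x`` of an auto-associative memory."""
    W = _as_weight_matrix(W)
    if W.shape[0] != W.shape[1]:
        raise ValueError("net_value requires a square (auto-associative) W")
    x = as_binary_vector(x, dim=W.shape[1]).astype(np.int64)
    return int(x @ W.astype(np.int64) @ x)


def energy(W, x) -> int:
    """Hopfield energy ``H = -x^T W x``."""
    return -net_value(W, x)


def _cosine(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = int(x.sum()), int(y.sum())
    if sx == 0 or sy == 0:
        return 0.0
    dot = int(x.astype(np.int64) @ y.astype(np.int64))
    if dot * dot == sx * sy:      # exact collinearity (e.g. x == y)
        return 1.0
    return dot / math.sqrt(sx * sy)


def familiarity(W, x, mode: str = "net", t: float | str = "auto") -> FamiliarityResult:
    """Decide whether the cue ``x`` was stored in the auto-associative memory.

    mode="net" compares ``net = x^T W x`` against ``t`` (``t="auto"`` means
    ``t := T/2`` with T the cue's maximum dendritic sum).  mode="cosine"
    compares the cosine between ``x`` and its one-step retrieval against
    ``t`` in [0, 1].
    """
    W = _as_weight_matrix(W)
    if W.shape[0] != W.shape[1]:
        raise ValueError("familiarity requires a square (auto-associative) W")
    n = W.shape[0]
    x = as_binary_vector(x, dim=n)
    net = net_value(W, x)

    try:
        res = retrieve(W, x)
        ham: int | None = hamming_distance(x, res.y)
        cos: float | None = _cosine(x, res.y)
        T = res.threshold_used
    except DegenerateRetrievalError:
        if mode == "cosine":
            raise
        res, ham, cos, T = None, None, None, 0

    if mode == "net":
        tt = T / 2 if t == "auto" else float(t)
        if not 0 <= tt <= n * n:
            raise ValueError(f"net-mode threshold must be in [0, {n * n}]")
        sim = 0 if res is None else int(net >= tt)
    elif mode == "cosine":
        if t == "auto":
            raise ValueError("cosine mode requires an explicit threshold")
        tt = float(t)
        if not 0 <= tt <= 1:
            raise ValueError("cosine-mode threshold must be in [0, 1]")
        sim = int(cos >= tt)
    else:
        raise ValueError(f"unknown familiarity mode {mode!r}")

    return FamiliarityResult(net=net, energy=-net, hamming=ham, cosine=cos,
                             sim=sim, threshold_t=tt, mode=mode)


def familiarity_batch(W, C, mode: str = "cosine", t: float | str = 0.87):
    """Vectorized familiarity over the rows of candidate matrix ``C``.

    Returns ``(sims, stats)`` where ``stats`` is the mode's statistic per row
    (net or cosine); degenerate rows (max dendritic sum 0) get sim = 0 and, in
    cosine mode, statistic 0.  Equivalent row-by-row to :func:`familiarity`
    with the degenerate case mapped to sim = 0.
    """
    W = _as_weight_matrix(W)
    if W.shape[0] != W.shape[1]:
        raise ValueError("familiarity requires a square (auto-associative) W")
    n = W.shape[0]
    C = np.asarray(C)
    if C.ndim != 2 or C.shape[1] != n:
        raise ValueError(f"candidate matrix must be (k, {n})")
    Cf = C.astype(np.float32)
    S = Cf @ W.astype(np.float32)           # dendritic sums, exact in f32
    T = S.max(axis=1)
    net = np.einsum("ij,ij->i", S, Cf)
    if mode == "net":
        tt = np.where(T > 0, T / 2.0, np.inf) if t == "auto" else float(t)
        sims = (net >= tt) & (T > 0)
        stats = net.astype(np.int64)
    elif mode == "cosine":
        tt = float(t)
        Y = (S >= np.maximum(T, 1)[:, None]).astype(np.float32)
        dot = np.einsum("ij,ij->i", Cf, Y)
        sx, sy = Cf.sum(axis=1), Y.sum(axis=1)
        norm = np.sqrt(sx) * np.sqrt(sy)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = np.where(norm > 0, dot / norm, 0.0)
        cos[dot * dot == sx * sy] = np.where(dot > 0, 1.0, 0.0)[dot * dot == sx * sy]
        sims = (cos >= tt) & (T > 0)
        stats = cos
    else:
        raise ValueError(f"unknown familiarity mode {mode!r}")
    return sims.astype(np.uint8), stats


# ---------------------------------------------------------------------------
# estimator


class Lernmatrix(BaseEstimator):
    """Binary Willshaw associative memory as a scikit-learn-style estimator.

    Parameters
    ----------
    auto_associative : bool, default True
        If True, ``fit(X)`` stores each row of X with itself and the weight
        matrix is square and symmetric; familiarity discrimination requires
        this mode.

    Attributes
    ----------
    weights_ : ndarray of shape (n_units, n_inputs), dtype uint8
        The clipped Hebbian weight matrix.
    n_features_in_ : int
        Address-vector dimension.

    Examples
    --------
    >>> m = Lernmatrix().fit([[1, 0, 1]])
    >>> m.retrieve([1, 0, 0]).y.tolist()   # fault-tolerant completion
    [1, 0, 1]
    >>> m.familiarity([1, 0, 1], mode="net", t="auto").sim
    1
    """

    def __init__(self, auto_associative: bool = True):
        self.auto_associative = auto_associative

    # -- learning -----------------------------------------------------------

    def fit(self, X, y=None):
        """Learn the rows of X (auto-association) or the pairs (X[i], y[i])."""
        self._reset()
        return self.partial_fit(X, y)

    def partial_fit(self, X, y=None):
        """Monotone incremental learning: weights only ever go 0 -> 1."""
        X = np.atleast_2d(np.asarray(X))
        if y is None:
            if not self.auto_associative:
                raise ValueError("hetero-associative fit requires y")
            Y = X
        else:
            Y = np.atleast_2d(np.asarray(y))
            if self.auto_associative and not np.array_equal(X, Y):
                raise ValueError("auto-association requires address == retrieved")
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and y must pair up row-wise")
        W_new = learn_pairs(zip(X, Y), auto_associative=self.auto_associative)
        if getattr(self, "weights_", None) is None:
            self.weights_ = W_new
        else:
            if self.weights_.shape != W_new.shape:
                raise ValueError("dimension mismatch with previously learned pairs")
            np.logical_or(self.weights_, W_new, out=self.weights_.view(bool))
        self.n_features_in_ = self.weights_.shape[1]
        return self

    def _reset(self):
        self.weights_ = None

    def _check_fitted(self) -> np.ndarray:
        if getattr(self, "weights_", None) is None:
            raise ValueError("this Lernmatrix instance is not fitted yet")
        return self.weights_

    # -- retrieval ----------------------------------------------------------

    def retrieve(self, x) -> RetrievalResult:
        return retrieve(self._check_fitted(), x)

    def backward_project(self, y) -> RetrievalResult:
        return backward_project(self._check_fitted(), y)

    def predict(self, X) -> np.ndarray:
        """Row-wise one-step retrieval."""
        W = self._check_fitted()
        X = np.atleast_2d(np.asarray(X))
        return np.vstack([retrieve(W, row).y for row in X])

    # -- familiarity --------------------------------------------------------

    def net_value(self, x) -> int:
        return net_value(self._check_fitted(), x)

    def energy(self, x) -> int:
        return energy(self._check_fitted(), x)

    def familiarity(self, x, mode: str = "net", t: float | str = "auto") -> FamiliarityResult:
        return familiarity(self._check_fitted(), x, mode=mode, t=t)

    def familiarity_batch(self, C, mode: str = "cosine", t: float | str = 0.87):
        return familiarity_batch(self._check_fitted(), C, mode=mode, t=t)


# ---------------------------------------------------------------------------
# text I/O: whitespace-delimited 0/1 matrix, first line "n m"


def save_weights(W, path) -> None:
    W = _as_weight_matrix(W)
    with open(path, "w") as fh:
        fh.write(f"{W.shape[0]} {W.shape[1]}\n")
        for row in W:
            fh.write(" ".join(map(str, row.tolist())) + "\n")


def load_weights(path) -> np.ndarray:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("weight file must start with a 'n m' header line")
        n, m = int(header[0]), int(header[1])
        W = np.loadtxt(fh, dtype=np.uint8, ndmin=2)
    if W.shape != (n, m):
        raise ValueError(f"weight file body {W.shape} does not match header ({n}, {m})")
    return _as_weight_matrix(W)
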