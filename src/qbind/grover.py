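"""Index-level simulation of the Grover search over address tuples.

The search space is the set of ordered M-tuples over nu = 2^ceil(log2 N)
addresses (P' = nu^M tuples); addresses above N are zero "waste objects".
Only the tuple index register is simulated with amplitudes: the oracle is a
basis-state permutation plus a flag, so phase-marking the set of familiar
tuples and inverting about the mean reproduces the full-circuit dynamics
exactly while keeping the state vector at P' real amplitudes.

After k = floor(pi/4 * sqrt(P'/r)) iterations the probability of measuring a
marked tuple is sin^2((2k+1) * arcsin(sqrt(r/P'))), near 1 for r << P'.  The
measured tuple is handed back to the classical memory, which recalls the
noise-free stored category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .binding_search import CombinationSpace, perm_count, perm_rep_count
from .lernmatrix import (DegenerateRetrievalError, FamiliarityConfig,
                         familiarity_batch, retrieve)
from .scene_coding import Scene

__all__ = [
    "IndexState",
    "GroverPlan",
    "CostReport",
    "SearchResult",
    "nu",
    "init_index_state",
    "mark_set",
    "grover_iterate",
    "optimal_iterations",
    "predicted_success",
    "make_plan",
    "run_search",
    "cost_report",
]


def nu(N: int) -> int:
    """Smallest power of two >= N; addresses N+1..nu are waste objects."""
    if N < 1:
        raise ValueError("N must be at least 1")
    return 1 << max(N - 1, 0).bit_length()


@dataclass
class IndexState:
    """Real amplitude vector over the nu^M address tuples.

    Tuples are 1-based ``(a_1, ..., a_M)`` with each ``a_m`` in 1..nu; the
    flat index is row-major: ``sum_m (a_m - 1) * nu^(M-m)``.
    """

    amplitudes: np.ndarray
    nu: int
    M: int

    @property
    def P_prime(self) -> int:
        return self.nu ** self.M

    def index_of(self, tup) -> int:
        if len(tup) != self.M:
            raise ValueError(f"expected an M={self.M} tuple")
        idx = 0
        for a in tup:
            if not 1 <= a <= self.nu:
                raise ValueError(f"address {a} outside 1..{self.nu}")
            idx = idx * self.nu + (a - 1)
        return idx

    def tuple_of(self, idx: int) -> tuple[int, ...]:
        out = []
        for _ in range(self.M):
            out.append(idx % self.nu + 1)
            idx //= self.nu
        return tuple(reversed(out))

    def probability(self, tup) -> float:
        return float(self.amplitudes[self.index_of(tup)] ** 2)


def init_index_state(nu_: int, M: int) -> IndexState:
    """Uniform superposition 1/sqrt(nu^M) over all tuples (Hadamard on every
    address bit, tensored M times)."""
    if nu_ < 1 or nu_ & (nu_ - 1):
        raise ValueError("nu must be a power of two")
    if M < 1:
        raise ValueError("M must be at least 1")
    P = nu_ ** M
    return IndexState(np.full(P, 1.0 / math.sqrt(P)), nu_, M)


def mark_set(scene: Scene, W, fam: FamiliarityConfig, M: int,
             nu_: int | None = None, batch: int = 4096) -> set[tuple[int, ...]]:
    """The set of address tuples whose oracle bit is 1.

    Precomputed with the vectorized classical familiarity (the oracle is a
    deterministic basis-state flag, so this is exact).  Tuples containing a
    waste address (> N) are never marked: waste entities are all-zero, and the
    partially-zero candidates they induce are masked out here (a permissive
    threshold could otherwise accept a zero-padded fragment of a category).
    """
    E = scene.entity_matrix()
    N, p = E.shape
    if nu_ is None:
        nu_ = nu(N)
    Epad = np.zeros((nu_, p), dtype=np.uint8)
    Epad[:N] = E
    W = np.asarray(W)
    if W.shape[0] != p * M:
        raise ValueError(f"weight matrix dimension {W.shape[0]} != M*p = {p * M}")

    marked: set[tuple[int, ...]] = set()
    P = nu_ ** M
    idx = np.arange(P)
    digits = np.empty((P, M), dtype=np.int64)
    rem = idx
    for m in range(M - 1, -1, -1):
        digits[:, m] = rem % nu_
        rem = rem // nu_
    for start in range(0, P, batch):
        d = digits[start:start + batch]
        C = Epad[d].reshape(d.shape[0], M * p)
        sims, _ = familiarity_batch(W, C, fam.mode, fam.t)
        sims = sims & (d < N).all(axis=1)
        for i in np.flatnonzero(sims):
            marked.add(tuple(int(a) + 1 for a in d[i]))
    return marked


def grover_iterate(state: IndexState, marked) -> IndexState:
    """One Grover iteration: phase-flip the marked tuples, then invert every
    amplitude about the mean.  Norm-preserving."""
    a = state.amplitudes
    if a.size == 0:
        raise ValueError("empty state")
    a = a.copy()
    if marked is not None and len(marked) > 0:
        if isinstance(marked, np.ndarray):
            idx = marked
        else:
            idx = [state.index_of(t) for t in marked]
        a[idx] = -a[idx]
    a = 2.0 * a.mean() - a
    return IndexState(a, state.nu, state.M)


def optimal_iterations(P_prime: int, r: int) -> int:
    """floor(pi/4 * sqrt(P'/r)) Grover iterations for r solutions in P'."""
    if r < 1:
        raise ValueError("r must be at least 1 (solution counting is assumed)")
    if r > P_prime:
        raise ValueError("r cannot exceed the search-space size")
    return int(math.floor(math.pi / 4.0 * math.sqrt(P_prime / r)))


def predicted_success(P_prime: int, r: int, k: int) -> float:
    """Closed-form probability sin^2((2k+1) * arcsin(sqrt(r/P'))) of measuring
    a marked tuple after k iterations from the uniform state."""
    theta = math.asin(math.sqrt(r / P_prime))
    return math.sin((2 * k + 1) * theta) ** 2


@dataclass(frozen=True)
class GroverPlan:
    P_prime: int
    r: int
    k: int
    theta: float
    predicted_success: float

    @classmethod
    def create(cls, P_prime: int, r: int) -> "GroverPlan":
        k = optimal_iterations(P_prime, r)
        return cls(P_prime=P_prime, r=r, k=k,
                   theta=math.asin(math.sqrt(r / P_prime)),
                   predicted_success=predicted_success(P_prime, r, k))


def make_plan(N: int, M: int, r: int = 1) -> GroverPlan:
    return GroverPlan.create(nu(N) ** M, r)


@dataclass
class SearchResult:
    found: list[tuple[int, ...]]
    recovered: list[np.ndarray]
    oracle_calls: int
    repeats_used: int
    plan: GroverPlan
    status: str                       # "ok" or "budget-exhausted"
    marked_count: int


def run_search(scene: Scene, W, M: int, r: int,
               fam: FamiliarityConfig = FamiliarityConfig(),
               seed: int | None = None, repeats: int = 100,
               rng: np.random.Generator | None = None) -> SearchResult:
    """Simulated hybrid search: amplify, measure, repeat until r distinct
    marked tuples are found (or the repeat budget runs out), then recall each
    found category from the classical memory.

    ``r`` is an input: counting the solutions is delegated to quantum
    counting, outside this simulator's scope.  ``oracle_calls`` accounts
    Grover-style: k oracle applications per repeat actually run.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    N = scene.N
    nu_ = nu(N)
    plan = GroverPlan.create(nu_ ** M, r)
    marked = mark_set(scene, W, fam, M, nu_=nu_)

    state = init_index_state(nu_, M)
    marked_idx = np.fromiter((state.index_of(t) for t in sorted(marked)),
                             dtype=np.int64, count=len(marked))
    for _ in range(plan.k):
        state = grover_iterate(state, marked_idx)
    probs = state.amplitudes ** 2
    probs = probs / probs.sum()

    found: list[tuple[int, ...]] = []
    repeats_used = 0
    for _ in range(repeats):
        repeats_used += 1
        idx = int(rng.choice(probs.size, p=probs))
        tup = state.tuple_of(idx)
        if tup in marked and tup not in found:
            found.append(tup)
            if len(found) >= r:
                break

    E = scene.entity_matrix()
    p = scene.p
    recovered = []
    for tup in found:
        cand = np.concatenate([E[a - 1] if a <= N else np.zeros(p, np.uint8)
                               for a in tup])
        try:
            recovered.append(retrieve(W, cand).y)
        except DegenerateRetrievalError:
            recovered.append(None)
    status = "ok" if len(found) >= r else "budget-exhausted"
    return SearchResult(found=found, recovered=recovered,
                        oracle_calls=plan.k * repeats_used,
                        repeats_used=repeats_used, plan=plan, status=status,
                        marked_count=len(marked))


@dataclass(frozen=True)
class CostReport:
    """The paper-style cost accounting for (N, M, p, r)."""

    N: int
    M: int
    p: int
    r: int
    L: int                      # Perm(N, M)
    P: int                      # N^M
    nu: int
    P_prime: int                # nu^M
    sqrt_P_prime: float
    classical_queries: int      # O(N^M) term: the full with-repetition sweep
    grover_iterations: int      # ~ sqrt(P'/r)
    preparation_cost: int       # O(N*M) superposition/load preparation
    load_gates: int             # N*(N-1)*p per load
    familiarity_gates: int      # 4*n^2 with n = p*M
    ordering_check: bool        # sqrt(P') < L < P (the M >= 2 regime)


def cost_report(N: int, M: int, p: int, r: int = 1) -> CostReport:
    if N < 1 or M < 1 or p < 1 or r < 1:
        raise ValueError("N, M, p, r must be positive")
    space = CombinationSpace.create(N, M, r)
    n = p * M
    sqrtP = math.sqrt(space.P_prime)
    return CostReport(
        N=N, M=M, p=p, r=r, L=space.L, P=space.P, nu=space.nu,
        P_prime=space.P_prime, sqrt_P_prime=sqrtP,
        classical_queries=space.P,
        grover_iterations=optimal_iterations(space.P_prime, r),
        preparation_cost=N * M,
        load_gates=N * (N - 1) * p,
        familiarity_gates=4 * n * n,
        ordering_check=bool(sqrtP < space.L < space.P),
    )
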