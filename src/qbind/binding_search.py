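"""Classical combinatorial search for stored categories in a scene.

A category of M objects hidden among N scene objects must be found by posing
ordered candidate tuples to the associative memory: ``L = Perm(N, M) =
N!/(N-M)!`` tuples without address repetition, or ``P = N^M`` with repetition
(the relaxation used by the quantum search, ``P > L`` for M >= 2).  Each
candidate is the concatenation of the addressed cognitive entities; the memory
answers with a familiarity verdict per candidate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .lernmatrix import (DegenerateRetrievalError, FamiliarityConfig,
                         familiarity_batch, retrieve)
from .scene_coding import Scene

__all__ = [
    "CombinationSpace",
    "BindResult",
    "perm_count",
    "perm_rep_count",
    "enumerate_candidates",
    "candidate_matrix",
    "classical_bind",
]


def perm_count(N: int, M: int) -> int:
    """Number of ordered M-tuples of distinct objects: ``N!/(N-M)!``."""
    if N < 1 or M < 1:
        raise ValueError("N and M must be positive")
    if M > N:
        raise ValueError(f"M={M} exceeds N={N}")
    return math.perm(N, M)


def perm_rep_count(N: int, M: int) -> int:
    """Number of ordered M-tuples with repetition: ``N**M`` (exact integer)."""
    if N < 1 or M < 1:
        raise ValueError("N and M must be positive")
    return N ** M


def _nu(N: int) -> int:
    return 1 << max(N - 1, 0).bit_length()


@dataclass(frozen=True)
class CombinationSpace:
    """The sizes of the combination search space for (N, M).

    L = Perm(N, M) ordered tuples without repetition, P = N^M with
    repetition, and P' = nu^M after padding the address space to the power
    of two nu = 2^ceil(log2 N); L <= P <= P'.
    """

    N: int
    M: int
    L: int
    P: int
    nu: int
    P_prime: int
    r: int = 1

    @classmethod
    def create(cls, N: int, M: int, r: int = 1) -> "CombinationSpace":
        nu = _nu(N)
        return cls(N=N, M=M, L=perm_count(N, M), P=perm_rep_count(N, M),
                   nu=nu, P_prime=nu ** M, r=r)


def enumerate_candidates(scene: Scene, M: int, mode: str = "perm",
                         ) -> Iterator[tuple[tuple[int, ...], np.ndarray]]:
    """Yield ``(address_tuple, candidate_vector)`` in lexicographic order.

    mode="perm" enumerates ordered tuples of distinct addresses (Perm(N, M)
    of them); mode="perm_rep" enumerates all N^M tuples.  The candidate is
    the concatenation of the addressed entities in tuple order.
    """
    if scene.N == 0:
        raise ValueError("empty scene")
    if M < 1:
        raise ValueError("M must be positive")
    addresses = scene.addresses
    if mode == "perm":
        if M > scene.N:
            raise ValueError(f"M={M} exceeds the scene size N={scene.N}")
        tuples = itertools.permutations(addresses, M)
    elif mode == "perm_rep":
        tuples = itertools.product(addresses, repeat=M)
    else:
        raise ValueError(f"unknown enumeration mode {mode!r}")
    E = scene.entity_matrix()
    for tup in tuples:
        yield tup, np.concatenate([E[a - 1] for a in tup])


def candidate_matrix(scene: Scene, M: int, mode: str = "perm"):
    """All candidates stacked into a matrix, plus the ordered tuple list."""
    tuples = []
    rows = []
    for tup, vec in enumerate_candidates(scene, M, mode):
        tuples.append(tup)
        rows.append(vec)
    return tuples, np.vstack(rows)


@dataclass
class BindResult:
    """Result of the classical binding loop."""

    matches: list[tuple[tuple[int, ...], float]]   # (tuple, statistic), sim=1
    best: tuple[int, ...] | None
    best_stat: float | None
    recovered: np.ndarray | None                   # noise-free category recall
    queries: int
    mode: str
    fam: FamiliarityConfig


def classical_bind(scene: Scene, W, M: int, mode: str = "perm",
                   fam: FamiliarityConfig = FamiliarityConfig(),
                   early_stop: bool = False) -> BindResult:
    """Evaluate familiarity for every candidate tuple of the scene.

    All candidates with sim = 1 are collected; the best (highest statistic,
    ties broken by lexicographically smallest tuple) is re-posed to the memory
    to recall the stored, noise-free category vector.  ``queries`` counts the
    familiarity evaluations (the full tuple count unless ``early_stop``).
    """
    W = np.asarray(W)
    if W.shape[0] != scene.p * M:
        raise ValueError(
            f"weight matrix dimension {W.shape[0]} != M*p = {scene.p * M}")

    tuples, C = candidate_matrix(scene, M, mode)
    if early_stop:
        matches: list[tuple[tuple[int, ...], float]] = []
        queries = 0
        for i, tup in enumerate(tuples):
            queries += 1
            sims, stats = familiarity_batch(W, C[i:i + 1], fam.mode, fam.t)
            if sims[0]:
                matches.append((tup, float(stats[0])))
                break
    else:
        sims, stats = familiarity_batch(W, C, fam.mode, fam.t)
        queries = len(tuples)
        matches = [(tuples[i], float(stats[i]))
                   for i in np.flatnonzero(sims)]

    best = best_stat = recovered = None
    if matches:
        # highest statistic; ties -> lexicographically smallest tuple
        best, best_stat = min(matches, key=lambda ms: (-ms[1], ms[0]))
        idx = tuples.index(best)
        try:
            recovered = retrieve(W, C[idx]).y
        except DegenerateRetrievalError:
            recovered = None
    return BindResult(matches=matches, best=best, best_stat=best_stat,
                      recovered=recovered, queries=queries, mode=mode, fam=fam)
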