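"""Reversible-logic model of the familiarity oracle, evaluable on basis states.

The oracle U_F marks, in a single flag bit, whether the candidate addressed by
the address registers is familiar to the associative memory.  It composes

* U_load — a multiplexer that copies the scene entity with the queried
  address into the input register (one per category slot),
* U_Sim — the familiarity circuit: ``net = sum_ij w_ij AND x_i AND x_j``
  accumulated with Peres full adders, then ``(t-1) - net`` with full
  subtractors so the final borrow bit is 1 exactly when ``net >= t``,
* U_CNOT — copies the borrow bit out into |sim>,
* the mirror inverses of U_Sim and U_load, which uncompute every
  intermediate (waste) bit back to 0.

Everything here is a permutation of classical bit strings; evaluating on a
basis state is exact, which is what lets the index-level Grover simulation be
exact as well.

Gate accounting follows the idealized formulas (each AND/OR one Toffoli, each
Peres adder or full subtractor one gate): ``N*(N-1)*p`` for the load and
``4*n^2`` for familiarity.  The emitted gate list of this concrete
construction differs (equality tests, carry chains, constant preparation);
its true length is ``len(circuit.gates)`` while ``reported_gate_count``
carries the formula value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .scene_coding import Scene

__all__ = [
    "Gate",
    "Circuit",
    "peres_full_adder",
    "full_subtractor",
    "build_load_circuit",
    "build_familiarity_circuit",
    "build_oracle_circuit",
    "evaluate_circuit",
    "inverse_circuit",
    "oracle_bit",
    "OracleEvaluator",
    "dump_circuit",
    "parse_circuit_text",
]

_KINDS = {"NOT": 1, "CNOT": 2, "TOFFOLI": 3,
          "PERES_ADD": 4, "PERES_ADD_INV": 4,
          "FULL_SUB": 4, "FULL_SUB_INV": 4}

_INVERSE = {"NOT": "NOT", "CNOT": "CNOT", "TOFFOLI": "TOFFOLI",
            "PERES_ADD": "PERES_ADD_INV", "PERES_ADD_INV": "PERES_ADD",
            "FULL_SUB": "FULL_SUB_INV", "FULL_SUB_INV": "FULL_SUB"}


class Gate(NamedTuple):
    kind: str
    wires: tuple[int, ...]


def make_gate(kind: str, *wires: int) -> Gate:
    if kind not in _KINDS:
        raise ValueError(f"unknown gate kind {kind!r}")
    if len(wires) != _KINDS[kind]:
        raise ValueError(f"{kind} takes {_KINDS[kind]} wires, got {len(wires)}")
    if len(set(wires)) != len(wires):
        raise ValueError(f"gate wires must be distinct: {wires}")
    return Gate(kind, tuple(int(w) for w in wires))


# ---------------------------------------------------------------------------
# primitive mappings


def _check_bits(*bits):
    for b in bits:
        if b not in (0, 1):
            raise ValueError(f"inputs must be bits, got {b!r}")


def peres_full_adder(x1: int, x2: int, x3: int, x4: int = 0):
    """Peres gate: with x4 = 0, output 3 is the sum and output 4 the carry
    of the full addition x1 + x2 + x3 (x1 passes through unchanged)."""
    _check_bits(x1, x2, x3, x4)
    return (x1, x1 ^ x2, x1 ^ x2 ^ x3,
            ((x1 ^ x2) & x3) ^ (x1 & x2) ^ x4)


def full_subtractor(x1: int, x2: int, x3: int, x4: int = 0):
    """Reversible full subtractor: with x4 = 0, output 3 is the difference and
    output 4 the borrow of x1 - x2 - x3 (minuend x1 passes through)."""
    _check_bits(x1, x2, x3, x4)
    borrow = ((1 ^ x1) & (x2 | x3)) | (x2 & x3)
    return (x1, x1 ^ x2, x1 ^ x2 ^ x3, x4 ^ borrow)


def _peres_inv(y1, y2, y3, y4):
    x1, x2, x3 = y1, y1 ^ y2, y2 ^ y3
    x4 = y4 ^ ((x1 ^ x2) & x3) ^ (x1 & x2)
    return x1, x2, x3, x4


def _full_sub_inv(y1, y2, y3, y4):
    x1, x2, x3 = y1, y1 ^ y2, y2 ^ y3
    x4 = y4 ^ (((1 ^ x1) & (x2 | x3)) | (x2 & x3))
    return x1, x2, x3, x4


# ---------------------------------------------------------------------------
# circuits


@dataclass
class Circuit:
    """An ordered reversible gate list over named, disjoint bit registers."""

    width: int
    registers: dict[str, tuple[int, int]]        # name -> (start, length)
    gates: list[Gate]
    reported_gate_count: int | None = None       # idealized accounting
    breakdown: dict[str, int] | None = None
    meta: dict = field(default_factory=dict)

    def wires(self, name: str) -> list[int]:
        start, length = self.registers[name]
        return list(range(start, start + length))

    def extract(self, state: np.ndarray, name: str) -> np.ndarray:
        start, length = self.registers[name]
        return state[start:start + length]

    def evaluate(self, init: dict[str, Sequence[int]] | np.ndarray) -> np.ndarray:
        return evaluate_circuit(self, init)

    def inverse(self) -> "Circuit":
        return inverse_circuit(self)


def evaluate_circuit(circuit: Circuit,
                     init: dict[str, Sequence[int]] | np.ndarray) -> np.ndarray:
    """Apply the gate list to a basis state; returns the output basis state.

    ``init`` is either a full-width bit array or a dict of register values
    (registers not mentioned start at 0).
    """
    if isinstance(init, dict):
        state = np.zeros(circuit.width, dtype=np.uint8)
        for name, bits in init.items():
            start, length = circuit.registers[name]
            bits = np.asarray(bits, dtype=np.uint8)
            if bits.size != length:
                raise ValueError(f"register {name!r} expects {length} bits")
            state[start:start + length] = bits
    else:
        state = np.array(init, dtype=np.uint8)
        if state.size != circuit.width:
            raise ValueError(f"state must cover all {circuit.width} wires")
    if not np.isin(state, (0, 1)).all():
        raise ValueError("basis state must be binary")

    s = state
    for kind, w in circuit.gates:
        if kind == "NOT":
            s[w[0]] ^= 1
        elif kind == "CNOT":
            s[w[1]] ^= s[w[0]]
        elif kind == "TOFFOLI":
            s[w[2]] ^= s[w[0]] & s[w[1]]
        elif kind == "PERES_ADD":
            s[list(w)] = peres_full_adder(*(int(b) for b in s[list(w)]))
        elif kind == "PERES_ADD_INV":
            s[list(w)] = _peres_inv(*(int(b) for b in s[list(w)]))
        elif kind == "FULL_SUB":
            s[list(w)] = full_subtractor(*(int(b) for b in s[list(w)]))
        elif kind == "FULL_SUB_INV":
            s[list(w)] = _full_sub_inv(*(int(b) for b in s[list(w)]))
        else:  # pragma: no cover
            raise ValueError(f"unknown gate kind {kind!r}")
    return s


def inverse_circuit(circuit: Circuit) -> Circuit:
    inv_gates = [Gate(_INVERSE[g.kind], g.wires) for g in reversed(circuit.gates)]
    return Circuit(width=circuit.width, registers=dict(circuit.registers),
                   gates=inv_gates, reported_gate_count=circuit.reported_gate_count,
                   breakdown=circuit.breakdown, meta=dict(circuit.meta))


class _Alloc:
    def __init__(self, start: int = 0):
        self.top = start

    def take(self, n: int) -> list[int]:
        ws = list(range(self.top, self.top + n))
        self.top += n
        return ws


# ---------------------------------------------------------------------------
# load multiplexer


def _scene_bits(scene) -> np.ndarray:
    if isinstance(scene, Scene):
        return scene.entity_matrix().astype(np.uint8)
    E = np.asarray(scene, dtype=np.uint8)
    if E.ndim != 2:
        raise ValueError("scene must be a Scene or an (N, p) bit matrix")
    return E


def _address_bits(value: int, width: int) -> list[int]:
    """address-1 in binary, LSB first."""
    return [(value - 1) >> k & 1 for k in range(width)]


def _emit_load(gates: list[Gate], alloc: _Alloc, alpha: list[int],
               x_wires: list[int], scene_wires: np.ndarray, N: int) -> None:
    """Multiplex entity z_a into ``x_wires`` for the address held in ``alpha``.

    For each address a in 1..N an equality test against the constant a-1 is
    computed (NOTs on the zero bits, a Toffoli AND-chain), used to control the
    copy of entity a's bits, and uncomputed, so every ancilla ends at 0.
    Addresses above N ("waste objects") match nothing and leave x at 0.
    """
    A = len(alpha)
    p = len(x_wires)
    chain = alloc.take(max(A - 1, 0))           # reused across addresses
    for a in range(1, N + 1):
        bits = _address_bits(a, A)
        flips = [alpha[k] for k in range(A) if bits[k] == 0]
        pre = [make_gate("NOT", wq) for wq in flips]
        build: list[Gate] = []
        if A == 0:
            controls: list[int] = []
        elif A == 1:
            controls = [alpha[0]]
        else:
            build.append(make_gate("TOFFOLI", alpha[0], alpha[1], chain[0]))
            for k in range(2, A):
                build.append(make_gate("TOFFOLI", chain[k - 2], alpha[k], chain[k - 1]))
            controls = [chain[A - 2]]
        gates.extend(pre)
        gates.extend(build)
        for j in range(p):
            sj = int(scene_wires[a - 1, j])
            if controls:
                gates.append(make_gate("TOFFOLI", controls[0], sj, x_wires[j]))
            else:
                gates.append(make_gate("CNOT", sj, x_wires[j]))
        gates.extend(Gate(_INVERSE[g.kind], g.wires) for g in reversed(build))
        gates.extend(pre)


def build_load_circuit(scene, nu: int | None = None) -> Circuit:
    """The multiplexer |0..0>|alpha>|scene> -> |z_alpha>|alpha>|scene>.

    ``reported_gate_count`` is the idealized N*(N-1)*p accounting.
    """
    E = _scene_bits(scene)
    N, p = E.shape
    if N < 1:
        raise ValueError("empty scene")
    if nu is None:
        nu = 1 << max(N - 1, 0).bit_length()
    A = max(nu - 1, 0).bit_length()

    alloc = _Alloc()
    x_wires = alloc.take(p)
    alpha = alloc.take(A)
    scene_flat = alloc.take(N * p)
    scene_wires = np.array(scene_flat, dtype=np.int64).reshape(N, p)
    gates: list[Gate] = []
    _emit_load(gates, alloc, alpha, x_wires, scene_wires, N)
    regs = {"x": (x_wires[0] if p else 0, p),
            "alpha": (alpha[0] if A else p, A),
            "scene": (scene_flat[0], N * p),
            "anc": (scene_flat[-1] + 1, alloc.top - (scene_flat[-1] + 1))}
    return Circuit(width=alloc.top, registers=regs, gates=gates,
                   reported_gate_count=N * (N - 1) * p,
                   meta={"N": N, "p": p, "nu": nu, "A": A,
                         "scene_bits": E.copy()})


# ---------------------------------------------------------------------------
# familiarity circuit


def _emit_familiarity(gates: list[Gate], alloc: _Alloc, x_wires: list[int],
                      w_wires: np.ndarray, t: int) -> int:
    """Emit U_Sim over the given input/weight wires; returns the borrow wire.

    net is accumulated bit-serially: each term w_ij AND x_i AND x_j is two
    Toffolis, then rippled into a fresh copy of the accumulator with Peres
    adders; finally (t-1) - net is formed with full subtractors so the final
    borrow reads ``net >= t``.
    """
    n = len(x_wires)
    b = (n * n).bit_length() + 1                # accumulator width
    acc = alloc.take(b)                          # fresh zeros
    for i in range(n):
        for j in range(n):
            (u,) = alloc.take(1)
            if i == j:
                gates.append(make_gate("CNOT", x_wires[i], u))
            else:
                gates.append(make_gate("TOFFOLI", x_wires[i], x_wires[j], u))
            (a,) = alloc.take(1)
            gates.append(make_gate("TOFFOLI", u, int(w_wires[i, j]), a))
            carry = a
            for k in range(b):
                s_w, c_w = alloc.take(2)
                gates.append(make_gate("PERES_ADD", acc[k], carry, s_w, c_w))
                acc[k] = s_w
                carry = c_w

    if t == 0:                                   # net >= 0 always holds
        (sim,) = alloc.take(1)
        gates.append(make_gate("NOT", sim))
        return sim
    mval = t - 1
    if mval >= 1 << b:
        raise ValueError(f"threshold t={t} exceeds the accumulator range")
    m_wires = alloc.take(b)
    for k in range(b):
        if (mval >> k) & 1:
            gates.append(make_gate("NOT", m_wires[k]))
    (borrow,) = alloc.take(1)
    for k in range(b):
        (b_out,) = alloc.take(1)
        gates.append(make_gate("FULL_SUB", m_wires[k], acc[k], borrow, b_out))
        borrow = b_out
    return borrow


def build_familiarity_circuit(W, t: int) -> Circuit:
    """U_Sim for an auto-associative memory W and integer threshold t.

    The borrow register (``meta['borrow_wire']``) holds sim = [net >= t].
    ``reported_gate_count`` is the idealized 4*n^2, itemized in ``breakdown``.
    """
    W = np.asarray(W, dtype=np.uint8)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be a square (auto-associative) bit matrix")
    if not isinstance(t, (int, np.integer)) or t < 0:
        raise ValueError("the circuit threshold must be a non-negative integer")
    n = W.shape[0]
    alloc = _Alloc()
    x_wires = alloc.take(n)
    w_flat = alloc.take(n * n)
    w_wires = np.array(w_flat, dtype=np.int64).reshape(n, n)
    gates: list[Gate] = []
    anc_start = alloc.top
    borrow = _emit_familiarity(gates, alloc, x_wires, w_wires, int(t))
    regs = {"x": (0, n), "w": (n, n * n), "result": (anc_start, alloc.top - anc_start)}
    return Circuit(width=alloc.top, registers=regs, gates=gates,
                   reported_gate_count=4 * n * n,
                   breakdown={"and": 2 * n * n, "adders": n * n,
                              "subtractors": n * n},
                   meta={"n": n, "t": int(t), "borrow_wire": borrow,
                         "w_bits": W.copy()})


# ---------------------------------------------------------------------------
# composed oracle U_F


def build_oracle_circuit(scene, W, t: int, M: int,
                         nu: int | None = None) -> Circuit:
    """U_F = U_load^M ; U_Sim ; U_CNOT ; U_Sim^-1 ; U_load^-M.

    Input: |0>|0..0>|alpha_1..alpha_M>|scene>|w>; output leaves |sim> holding
    the familiarity bit of the addressed candidate with every other
    non-constant register restored to 0.
    """
    E = _scene_bits(scene)
    N, p = E.shape
    n = M * p
    W = np.asarray(W, dtype=np.uint8)
    if W.shape != (n, n):
        raise ValueError(f"W must be {n}x{n} for M={M}, p={p}")
    if nu is None:
        nu = 1 << max(N - 1, 0).bit_length()
    A = max(nu - 1, 0).bit_length()

    alloc = _Alloc()
    (sim,) = alloc.take(1)
    alpha_slots = [alloc.take(A) for _ in range(M)]
    x_slots = [alloc.take(p) for _ in range(M)]
    scene_flat = alloc.take(N * p)
    scene_wires = np.array(scene_flat, dtype=np.int64).reshape(N, p)
    w_flat = alloc.take(n * n)
    w_wires = np.array(w_flat, dtype=np.int64).reshape(n, n)
    anc_start = alloc.top

    fwd: list[Gate] = []
    for m in range(M):
        _emit_load(fwd, alloc, alpha_slots[m], x_slots[m], scene_wires, N)
    x_all = [w for slot in x_slots for w in slot]
    borrow = _emit_familiarity(fwd, alloc, x_all, w_wires, int(t))

    gates = list(fwd)
    gates.append(make_gate("CNOT", borrow, sim))
    gates.extend(Gate(_INVERSE[g.kind], g.wires) for g in reversed(fwd))

    regs = {"sim": (sim, 1),
            "alpha": (alpha_slots[0][0] if A else 1, M * A),
            "x": (x_slots[0][0], n),
            "scene": (scene_flat[0], N * p),
            "w": (w_flat[0], n * n),
            "anc": (anc_start, alloc.top - anc_start)}
    return Circuit(width=alloc.top, registers=regs, gates=gates,
                   reported_gate_count=M * N * (N - 1) * p + 2 * 4 * n * n + 1,
                   meta={"N": N, "p": p, "M": M, "nu": nu, "A": A, "t": int(t),
                         "scene_bits": E.copy(), "w_bits": W.copy()})


class OracleEvaluator:
    """Builds U_F once and evaluates it per address tuple (1-based addresses,
    values N+1..nu are waste objects that never match)."""

    def __init__(self, scene, W, t: int, M: int, nu: int | None = None,
                 check_uncompute: bool = True):
        self.circuit = build_oracle_circuit(scene, W, t, M, nu=nu)
        self.check_uncompute = check_uncompute
        c = self.circuit
        self._base = np.zeros(c.width, dtype=np.uint8)
        start, length = c.registers["scene"]
        self._base[start:start + length] = c.meta["scene_bits"].ravel()
        wstart, wlength = c.registers["w"]
        self._base[wstart:wstart + wlength] = c.meta["w_bits"].ravel()

    def __call__(self, address_tuple: Sequence[int]) -> int:
        c = self.circuit
        M, A, nu = c.meta["M"], c.meta["A"], c.meta["nu"]
        if len(address_tuple) != M:
            raise ValueError(f"expected an M={M} address tuple")
        state = self._base.copy()
        astart, _ = c.registers["alpha"]
        for m, a in enumerate(address_tuple):
            if not 1 <= a <= nu:
                raise ValueError(f"address {a} outside 1..{nu}")
            for k, bit in enumerate(_address_bits(int(a), A)):
                state[astart + m * A + k] = bit
        out = evaluate_circuit(c, state)
        if self.check_uncompute:
            ref = state.copy()
            sim_wire = c.registers["sim"][0]
            ref[sim_wire] = out[sim_wire]
            if not np.array_equal(out, ref):
                raise AssertionError("oracle failed to uncompute its waste bits")
        return int(out[c.registers["sim"][0]])


def oracle_bit(scene, W, t: int, address_tuple: Sequence[int],
               evaluator: OracleEvaluator | None = None) -> int:
    """The sim bit of U_F for one candidate address tuple.

    Equals ``familiarity(W, candidate, mode="net", t=t).sim`` for the
    concatenation of the addressed entities.  Pass a prebuilt
    :class:`OracleEvaluator` to amortize circuit construction.
    """
    if evaluator is None:
        M = len(address_tuple)
        evaluator = OracleEvaluator(scene, W, t, M)
    return evaluator(address_tuple)


# ---------------------------------------------------------------------------
# text dump


def dump_circuit(circuit: Circuit, path) -> None:
    """One gate per line ``KIND w1 w2 ...`` with a register-map header."""
    with open(path, "w") as fh:
        fh.write(f"# width {circuit.width}\n")
        for name, (start, length) in circuit.registers.items():
            fh.write(f"# register {name} {start} {length}\n")
        if circuit.reported_gate_count is not None:
            fh.write(f"# reported_gate_count {circuit.reported_gate_count}\n")
        for g in circuit.gates:
            fh.write(g.kind + " " + " ".join(map(str, g.wires)) + "\n")


def parse_circuit_text(text: str) -> Circuit:
    width = 0
    registers: dict[str, tuple[int, int]] = {}
    reported = None
    gates: list[Gate] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if parts[0] == "width":
                width = int(parts[1])
            elif parts[0] == "register":
                registers[parts[1]] = (int(parts[2]), int(parts[3]))
            elif parts[0] == "reported_gate_count":
                reported = int(parts[1])
            continue
        parts = line.split()
        gates.append(make_gate(parts[0], *map(int, parts[1:])))
    return Circuit(width=width, registers=registers, gates=gates,
                   reported_gate_count=reported)
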