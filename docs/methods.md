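# Methods

This note records the model, the defaults, and the design decisions behind
`qbind`, in the spirit of a package methods appendix.  Every number quoted
here is computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted that the code does not reproduce.

## Associative memory

The memory is a binary Willshaw/Lernmatrix: clipped Hebbian learning
(`w_ij ← 1` on co-activation, monotone, order-independent) and one-step
retrieval that thresholds each unit's dendritic sum at the maximum sum T.
Only auto-association is exercised by the pipeline; the backward (BAM-style)
projection through Wᵀ is provided for hetero-associative use.

**Degenerate retrieval.**  When T = 0 (empty memory or a cue disjoint from
every stored pattern) the literal threshold rule would activate *every*
unit, an all-ones answer that carries no information and would poison any
similarity measure downstream.  We raise `DegenerateRetrievalError` instead;
the search layers catch it and score the candidate as unfamiliar.

**Familiarity modes.**  Two statistics are implemented:

* `net` — the quadratic form net = xᵀWx with threshold t (default
  `t = "auto"`, meaning T/2 with T the cue's maximum dendritic sum).  This
  is the statistic the reversible circuit computes; it is cheap but
  permissive for strongly overlapping codes, because net grows with *any*
  stored structure the cue touches.
* `cosine` — the cosine between the cue and its one-step retrieval, with a
  threshold in [0, 1].  This is the normalized statistic the demonstration
  uses (threshold 0.87).

The decision boundary is `statistic ≥ t` everywhere.  In the circuit the
comparison is realized as the borrow bit of the subtraction (t−1) − net over
a ⌈log₂(n²+1)⌉+1-bit register, which is 1 exactly when net ≥ t for integer
t; the exactness of this equivalence is tested exhaustively on small
memories.  An exact-collinearity shortcut returns cosine = 1.0 when
(x·y)² = |x|²|y|², so a cue identical to its retrieval is never lost to
floating-point rounding.

## Scene coding

An object is encoded as a cognitive entity of three associative fields:

* identity — the object's bitmap cropped at its bounding box and rescaled
  to 10×10 by nearest-neighbour sampling (row/column index
  ⌊(i+½)·h/10⌋), flattened row-major: 100 bits.  Orientation normalization
  is a no-op for the axis-aligned blockworld shapes.
* abscissa / ordinate bars — half-open runs [x0, x0+w) and [y0, y0+h) over
  the canvas axes, 0-based, origin top-left: 100 + 100 bits on the default
  100×100 canvas.

Hence p = 300 per entity and n = M·p = 900 for the three-object category;
these dimensions, and the bar/bounding-box round trip, are asserted in the
tests.  Categories are concatenations in slot order, so tuple order matters
— candidates are ordered tuples (permutations), never sets.

## The blockworld generator

The generator emulates the standard demonstration conditions and doubles as
the package's ground-truth source:

| parameter | default | rationale |
| --- | --- | --- |
| canvas | 100×100 | the pictogram size of the demonstration |
| N (objects) | 10 | tower (3) + 7 distractor blocks |
| tower template | pyramid over two cubes, 20×20 blocks | a 60 px tower on a 100 px canvas, roughly the demonstration's proportions |
| learned positions | 10 distinct, uniform | "ten positions of the category are learned" |
| noise rate | 0.02 per pixel | visible corruption (≈ 5 identity bits per category) without overwhelming a 10×10 bitmap |
| placement | non-overlapping, ≤ 500 rejection retries | objects are segmented entities; overlap would corrupt identity crops |

Noise enters through the *pictogram*: the scene is rendered, every pixel is
flipped independently with the noise rate, and identity fields are then
extracted from the noisy image.  Position bars come from the scene
description itself, because segregation (detecting and localizing the
objects) is assumed solved — the package addresses the combination problem
only.  Consequences worth knowing: identity fields carry binomial noise
(≈ 2 % of 255 category identity bits), while bars are exact.  Real vision
would add localization error to the bars and correlated (non-i.i.d.) pixel
noise; passing tests therefore demonstrate the binding machinery, not
robustness of a vision front end.

The generator returns full ground truth (planted tuple, planted position,
learned positions), is bit-reproducible under its seed, and all pipeline
seeds fan out from one global seed through stable per-stage labels.

## Classical binding sweep

All candidate tuples are enumerated lexicographically — Perm(N, M) without
address repetition, or N^M with repetition (the relaxation the quantum
route uses; duplicates are not filtered, the familiarity test rejects
them).  Familiarity is evaluated for every candidate (vectorized as one
matrix product; the query count reported is the full tuple count unless the
optional early-stop flag is set).  The best match is the highest statistic,
ties broken by lexicographically smallest tuple for determinism, and is
re-posed to the memory to recall the stored noise-free category.

## Reversible oracle

The oracle U_F is built from five stages: M load multiplexers, the
familiarity circuit, a CNOT copying the verdict out, and the mirror
inverses of the familiarity circuit and the loads.  Everything is a
permutation of basis states, evaluated exactly on bit arrays.

* **Load.**  For each address a the multiplexer computes an equality flag
  against the address register (NOTs on the zero bits, a Toffoli AND-chain),
  copies entity a under that flag (one Toffoli per bit), and uncomputes the
  flag.  Addresses above N match nothing: waste objects are all-zero.
* **Familiarity.**  net is accumulated bit-serially: each term
  w_ij ∧ x_i ∧ x_j costs two Toffolis; each accumulation ripples through a
  fresh copy of the accumulator with Peres full adders (the old accumulator
  wires become waste, restored later by uncomputation).  The threshold
  constant t−1 is prepared with NOT gates and subtracted with full
  subtractors; the final borrow is the verdict.
* **Accounting.**  Gate counts are reported with the idealized accounting
  (each AND one Toffoli, each adder/subtractor one gate): N(N−1)p for a
  load and 4n² for familiarity (2n² ANDs + n² adders + n² subtractors).
  The emitted gate list of this concrete construction differs (equality
  chains, carries, constants); its true length is `len(circuit.gates)`,
  kept separate from `reported_gate_count` so the formula surface stays
  exact.

The uncompute contract — every wire outside the verdict, address, scene and
weight registers returns to its initial value — is asserted on every oracle
evaluation, and oracle-vs-classical equivalence is tested exhaustively for
all address tuples of small scenes, including tuples containing waste
addresses (which score the zero-padded candidate).

## Grover simulation

The full oracle register (≥ 900 object bits plus ancillas) is far beyond
state-vector simulation, but the oracle is a basis-state permutation plus a
flag: conditioned on the index register it acts as the identity on
everything it uncomputes.  The simulation therefore keeps amplitudes only
over the ν^M tuple indices and applies the textbook update — phase flip on
the marked set, inversion about the mean — which is *exact*, not an
approximation.  Marked tuples are precomputed once with the vectorized
classical familiarity (a simulation device; the per-iteration oracle-call
count is still accounted Grover-style as k per repeat).  Tuples containing
waste addresses are never marked: their entities are all-zero and the
zero-padded fragments they induce are masked.

Iteration count k = ⌊(π/4)√(P′/r)⌋ with r the (assumed known) number of
solutions; counting r is delegated to quantum counting and is out of scope.
Norm conservation, the closed-form success probability
sin²((2k+1)·arcsin√(r/P′)) (to 1e−9 across P′ up to 4096), and sampling
fidelity of the measurement step are all property-tested.

## Verification thresholds of the demonstration

The classical sweep uses the cosine statistic at t = 0.87 and identifies the
planted tuple as the best match (score ≈ 0.99) in every seeded run tested.
That threshold is deliberately permissive: a tuple sharing two of the three
tower entities, whose third entity has the right shape but bars missing the
learned bar coordinates, scores about (255+80)/375 ≈ 0.89 — above 0.87 —
so several near-aliases also pass, which is harmless for best-match
recovery.

The Grover fixture, however, is defined by the premise of exactly one
solution (r = 1), so its oracle threshold must separate the planted tuple
from every alias.  The separation is derivable from the coding geometry:
with non-overlapping placement, the closest possible alias shares the full
identity fields, two complete bar fields and at most one coinciding bar of
the third slot, bounding its cosine by (255+100)/375 ≈ 0.947, while the
noisy planted tuple scores at least ≈ 0.98 (identity flips are
Binomial(255, 0.02)).  The oracle threshold 0.96 sits between these two
analytic bounds; with it the marked set is exactly the planted tuple, the
r = 1 plan (k = 50 on P′ = 4096) predicts success 0.99995, and the planted
tuple is measured in 100 of 100 seeded runs.

## Known limitations

* The index-level simulation proves nothing about physical feasibility; the
  gate counts are the idealized accounting, not a transpiled depth.
* The cosine statistic degrades when stored categories overlap heavily in
  bar space; the alias analysis above assumes the default geometry (20×20
  blocks, distinct learned positions, non-overlapping placement).
* The pictogram pipeline assumes segregation: object identities and boxes
  are known, only category membership is searched.
* Solution counting (r) is an input everywhere; budget-exhausted searches
  return partial results with a warning status rather than an estimate.
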