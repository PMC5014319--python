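"""Unit and property tests for the Lernmatrix associative memory."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from qbind.lernmatrix import (DegenerateRetrievalError, Lernmatrix,
                              backward_project, energy, familiarity,
                              familiarity_batch, hamming_distance, learn_pairs,
                              load_weights, net_value, retrieve, save_weights)

SETTINGS = dict(derandomize=True, deadline=None, max_examples=60)


def bit_vectors(min_dim=1, max_dim=8):
    return st.integers(min_dim, max_dim).flatmap(
        lambda d: st.lists(st.integers(0, 1), min_size=d, max_size=d))


# ---------------------------------------------------------------------------
# learning


def test_learn_single_auto_pair_sets_outer_product():
    W = learn_pairs([((1, 0, 1), (1, 0, 1))])
    assert W.tolist() == [[1, 0, 1], [0, 0, 0], [1, 0, 1]]


def test_learn_zero_pair_gives_zero_matrix():
    W = learn_pairs([((0, 0, 0), (0, 0))])
    assert W.shape == (2, 3) and not W.any()


def test_learning_is_idempotent():
    once = learn_pairs([((1, 0, 1), (1, 0, 1))])
    twice = learn_pairs([((1, 0, 1), (1, 0, 1))] * 2)
    assert np.array_equal(once, twice)


@pytest.mark.parametrize("pairs", [
    [((1, 0), (1, 0)), ((1, 0, 1), (1, 0, 1))],        # address dims differ
    [((1, 0), (1,)), ((1, 0), (1, 1))],                # retrieved dims ok/mixed
])
def test_learn_dimension_mismatch_raises(pairs):
    with pytest.raises(ValueError):
        learn_pairs(pairs)


def test_learn_rejects_non_binary():
    with pytest.raises(ValueError):
        learn_pairs([((2, 0), (1, 0))])


@settings(**SETTINGS)
@given(st.lists(bit_vectors(3, 3), min_size=1, max_size=5), st.randoms())
def test_learning_monotone_or_of_outer_products_and_order_free(vecs, rnd):
    """W is the element-wise OR of the per-pair outer products, so permuting
    the pair order leaves it unchanged."""
    pairs = [(v, v) for v in vecs]
    W = learn_pairs(pairs)
    expected = np.zeros((3, 3), dtype=bool)
    for v in vecs:
        expected |= np.outer(v, v).astype(bool)
    assert np.array_equal(W.astype(bool), expected)
    shuffled = list(pairs)
    rnd.shuffle(shuffled)
    assert np.array_equal(learn_pairs(shuffled), W)


@settings(**SETTINGS)
@given(st.lists(bit_vectors(2, 8), min_size=1, max_size=4))
def test_auto_associative_learning_is_symmetric(vecs):
    dim = len(vecs[0])
    vecs = [v[:dim] + [0] * (dim - len(v)) for v in vecs]
    W = learn_pairs([(v, v) for v in vecs])
    assert np.array_equal(W, W.T)


# ---------------------------------------------------------------------------
# retrieval


def test_retrieve_stored_pattern():
    W = learn_pairs([((1, 0, 1), (1, 0, 1))])
    res = retrieve(W, (1, 0, 1))
    assert res.sums.tolist() == [2, 0, 2]
    assert res.threshold_used == 2
    assert res.y.tolist() == [1, 0, 1]


def test_retrieve_completes_partial_cue():
    W = learn_pairs([((1, 0, 1), (1, 0, 1))])
    res = retrieve(W, (1, 0, 0))
    assert res.sums.tolist() == [1, 0, 1]
    assert res.threshold_used == 1
    assert res.y.tolist() == [1, 0, 1]


def test_retrieve_empty_memory_is_degenerate():
    with pytest.raises(DegenerateRetrievalError):
        retrieve(np.zeros((3, 3), dtype=np.uint8), (1, 1, 1))


def test_backward_projection_of_hetero_pair():
    W = learn_pairs([((1, 1, 0), (0, 1))])
    res = backward_project(W, (0, 1))
    assert res.y.tolist() == [1, 1, 0]
    assert res.threshold_used == 1


def test_backward_equals_forward_for_symmetric_memory():
    W = learn_pairs([((1, 0, 1), (1, 0, 1)), ((0, 1, 1), (0, 1, 1))])
    fwd = retrieve(W, (1, 0, 1))
    bwd = backward_project(W, (1, 0, 1))
    assert np.array_equal(fwd.y, bwd.y) and fwd.threshold_used == bwd.threshold_used


def test_backward_zero_cue_is_degenerate():
    W = learn_pairs([((1, 1, 0), (0, 1))])
    with pytest.raises(DegenerateRetrievalError):
        backward_project(W, (0, 0))


@settings(**SETTINGS)
@given(st.lists(bit_vectors(4, 6), min_size=1, max_size=4))
def test_no_miss_retrieval_of_stored_patterns(vecs):
    """Every active bit of a stored pattern is active in its own retrieval:
    those units all reach the maximal sum |x|."""
    dim = len(vecs[0])
    vecs = [tuple(v[:dim] + [0] * (dim - len(v))) for v in vecs]
    vecs = [v for v in vecs if any(v)]
    if not vecs:
        return
    W = learn_pairs([(v, v) for v in vecs])
    for v in vecs:
        res = retrieve(W, v)
        assert res.threshold_used == sum(v)
        assert all(res.y[i] == 1 for i, b in enumerate(v) if b)


def test_single_stored_pattern_retrieved_exactly():
    v = (1, 0, 1, 1, 0, 1)
    W = learn_pairs([(v, v)])
    assert retrieve(W, v).y.tolist() == list(v)


# ---------------------------------------------------------------------------
# familiarity statistics


def test_hamming_distance_cases():
    assert hamming_distance((1, 0, 1), (1, 0, 1)) == 0
    assert hamming_distance((1, 0, 1), (0, 1, 0)) == 3
    assert hamming_distance((1, 0, 1), (1, 1, 1)) == 1
    with pytest.raises(ValueError):
        hamming_distance((1, 0), (1, 0, 1))


def test_net_value_and_energy():
    W = learn_pairs([((1, 0, 1), (1, 0, 1))])
    assert net_value(W, (1, 0, 1)) == 4
    assert energy(W, (1, 0, 1)) == -4
    assert net_value(W, (0, 0, 0)) == 0
    with pytest.raises(ValueError):
        net_value(np.zeros((2, 3), dtype=np.uint8), (1, 0, 1))


def test_net_value_double_loop_equals_matrix_form():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = int(rng.integers(2, 9))
        W = rng.integers(0, 2, size=(n, n), dtype=np.uint8)
        W = np.bitwise_or(W, W.T)
        x = rng.integers(0, 2, size=n, dtype=np.uint8)
        double = sum(int(W[i, j]) * int(x[i]) * int(x[j])
                     for i in range(n) for j in range(n))
        assert net_value(W, x) == double
        # scalar product of x with the un-thresholded W.x
        assert double == int(x @ (W.astype(int) @ x))


def test_energy_non_increasing_along_sub_patterns():
    """Adding bits of a stored pattern to a partial cue never raises H."""
    v = np.array([1, 1, 0, 1, 0, 1], dtype=np.uint8)
    W = learn_pairs([(v, v)])
    support = np.flatnonzero(v)
    for size in range(len(support)):
        for sub in itertools.combinations(support, size):
            x = np.zeros(6, dtype=np.uint8)
            x[list(sub)] = 1
            h = energy(W, x)
            for extra in set(support) - set(sub):
                x2 = x.copy()
                x2[extra] = 1
                assert energy(W, x2) <= h


def test_familiarity_net_auto_on_stored_pattern():
    W = learn_pairs([((1, 0, 1), (1, 0, 1))])
    f = familiarity(W, (1, 0, 1), mode="net", t="auto")
    assert (f.net, f.threshold_t, f.sim) == (4, 1.0, 1)
    assert f.energy == -4


def test_familiarity_zero_cue_not_familiar():
    W = learn_pairs([((1, 0, 1), (1, 0, 1))])
    assert familiarity(W, (0, 0, 0), mode="net", t=1).sim == 0
    # cosine mode raises on degenerate retrieval; callers treat as sim = 0
    with pytest.raises(DegenerateRetrievalError):
        familiarity(W, (0, 0, 0), mode="cosine", t=0.5)


def test_familiarity_cosine_of_stored_pattern_is_one():
    W = learn_pairs([((1, 0, 1), (1, 0, 1))])
    f = familiarity(W, (1, 0, 1), mode="cosine", t=1.0)
    assert f.cosine == pytest.approx(1.0)
    assert f.sim == 1


@pytest.mark.parametrize("mode,t", [("net", -1), ("net", 100), ("cosine", 1.5)])
def test_familiarity_threshold_range_validation(mode, t):
    W = learn_pairs([((1, 0, 1), (1, 0, 1))])
    with pytest.raises(ValueError):
        familiarity(W, (1, 0, 1), mode=mode, t=t)


def test_familiarity_of_disjoint_stored_patterns():
    """With mutually disjoint stored patterns there is no crosstalk: every
    stored pattern is recognized at t = T/2 (brute-force check)."""
    rng = np.random.default_rng(7)
    for trial in range(20):
        dim = int(rng.integers(8, 33))
        k = int(rng.integers(1, 6))
        perm = rng.permutation(dim)
        cuts = sorted(rng.choice(np.arange(1, dim), size=k - 1, replace=False)) if k > 1 else []
        groups = np.split(perm, cuts)
        pats = []
        for g in groups:
            v = np.zeros(dim, dtype=np.uint8)
            v[g] = 1
            pats.append(v)
        W = learn_pairs([(v, v) for v in pats])
        for v in pats:
            assert familiarity(W, v, mode="net", t="auto").sim == 1


def test_familiarity_batch_matches_scalar_path():
    rng = np.random.default_rng(3)
    pats = rng.integers(0, 2, size=(3, 12), dtype=np.uint8)
    W = learn_pairs([(v, v) for v in pats])
    C = rng.integers(0, 2, size=(20, 12), dtype=np.uint8)
    for mode, t in [("net", 5), ("net", "auto"), ("cosine", 0.8)]:
        sims, stats = familiarity_batch(W, C, mode, t)
        for i, row in enumerate(C):
            try:
                f = familiarity(W, row, mode=mode, t=t)
                assert sims[i] == f.sim
                ref = f.net if mode == "net" else f.cosine
                assert stats[i] == pytest.approx(ref)
            except DegenerateRetrievalError:
                assert sims[i] == 0


# ---------------------------------------------------------------------------
# estimator surface and I/O


def test_estimator_fit_predict_and_clone():
    m = Lernmatrix().fit([[1, 0, 1], [0, 1, 0]])
    assert m.weights_.shape == (3, 3)
    assert np.array_equal(m.predict([[1, 0, 1]]), [[1, 0, 1]])
    m2 = clone(m)
    assert m2.get_params() == m.get_params()
    with pytest.raises(ValueError):
        m2.retrieve([1, 0, 1])      # clone is unfitted


def test_estimator_partial_fit_is_monotone():
    m = Lernmatrix().fit([[1, 0, 0]])
    W0 = m.weights_.copy()
    m.partial_fit([[0, 0, 1]])
    assert (m.weights_ >= W0).all()
    assert m.weights_[2, 2] == 1


def test_estimator_rejects_mismatched_auto_pairs():
    with pytest.raises(ValueError):
        Lernmatrix().fit([[1, 0]], [[0, 1]])


def test_weight_matrix_text_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    W = rng.integers(0, 2, size=(5, 7), dtype=np.uint8)
    path = tmp_path / "W.txt"
    save_weights(W, path)
    first = path.read_text().splitlines()[0]
    assert first == "5 7"
    assert np.array_equal(load_weights(path), W)
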