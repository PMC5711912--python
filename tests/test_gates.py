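"""Gate evaluation, feedback updates, and gene decoding."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from markovbrains import (
    DeterministicGate,
    FeedbackGate,
    ProbabilisticGate,
    apply_feedback,
    check_feedback_inputs,
    decode_gate,
    eval_deterministic,
    eval_probabilistic,
)
from markovbrains.genome import GATE_KINDS, PAYLOAD_LENGTH, GeneSpan

FLOOR, CAP = 0.01, 0.99


def make_fb_gate(P, depth=1, delta=0.5):
    P = np.asarray(P, dtype=float)
    return FeedbackGate(
        input_nodes=list(range(int(np.log2(P.shape[0])) or 1))[: 4],
        output_nodes=[4],
        P=P,
        pos_node=1,
        neg_node=2,
        depth=depth,
        delta_pos=np.full(depth, delta),
        delta_neg=np.full(depth, delta),
    )


# -- deterministic ----------------------------------------------------

def test_deterministic_lookup():
    gate = DeterministicGate([0, 1], [4], np.array([3, 2, 1, 0]))
    assert [eval_deterministic(gate, i) for i in range(4)] == [3, 2, 1, 0]


def test_deterministic_rejects_out_of_range_pattern():
    gate = DeterministicGate([0], [4], np.array([0, 1]))
    with pytest.raises(ValueError):
        eval_deterministic(gate, 2)


# -- probabilistic ----------------------------------------------------

def test_probabilistic_sampling_matches_row(rng):
    gate = ProbabilisticGate([0], [4, 5], np.array([[0.7, 0.1, 0.1, 0.1],
                                                    [0.25] * 4]))
    draws = [eval_probabilistic(gate, 0, rng) for _ in range(4000)]
    freq = np.bincount(draws, minlength=4) / len(draws)
    assert np.allclose(freq, [0.7, 0.1, 0.1, 0.1], atol=0.03)


def test_probabilistic_rejects_unnormalized_row(rng):
    gate = ProbabilisticGate([0], [4], np.array([[0.7, 0.7], [0.5, 0.5]]))
    with pytest.raises(ValueError):
        eval_probabilistic(gate, 0, rng)


def test_feedback_gate_buffers_decisions_most_recent_first(rng):
    gate = make_fb_gate(np.full((4, 2), 0.5), depth=2)
    o1 = eval_probabilistic(gate, 3, rng)
    o2 = eval_probabilistic(gate, 1, rng)
    assert list(gate.history) == [(1, o2), (3, o1)]
    o3 = eval_probabilistic(gate, 2, rng)
    assert list(gate.history) == [(2, o3), (1, o2)]  # oldest evicted


# -- feedback updates -------------------------------------------------

def test_positive_feedback_raises_credited_entry(rng):
    gate = make_fb_gate(np.full((2, 2), 0.5))
    gate.history.appendleft((0, 1))
    before = gate.P[0, 1]
    apply_feedback(gate, "positive", rng)
    assert gate.P[0, 1] >= before
    assert np.isclose(gate.P[0].sum(), 1.0)


def test_negative_feedback_lowers_penalized_entry(rng):
    gate = make_fb_gate(np.full((2, 2), 0.5))
    gate.history.appendleft((0, 1))
    before = gate.P[0, 1]
    apply_feedback(gate, "negative", rng)
    assert gate.P[0, 1] <= before
    assert np.isclose(gate.P[0].sum(), 1.0)


def test_feedback_with_empty_buffer_is_noop(rng):
    gate = make_fb_gate(np.full((2, 2), 0.5))
    before = gate.P.copy()
    apply_feedback(gate, "positive", rng)
    assert np.array_equal(gate.P, before)


def test_feedback_rejects_unknown_sign(rng):
    gate = make_fb_gate(np.full((2, 2), 0.5))
    with pytest.raises(ValueError):
        apply_feedback(gate, "sideways", rng)


def test_feedback_credits_each_buffer_slot_with_its_own_delta(rng):
    gate = make_fb_gate(np.full((4, 4), 0.25), depth=2)
    gate.delta_pos = np.array([0.5, 0.0])  # slot 1 frozen
    gate.history.appendleft((0, 0))  # older -> slot 1
    gate.history.appendleft((1, 1))  # newest -> slot 0
    before = gate.P.copy()
    apply_feedback(gate, "positive", rng)
    assert np.array_equal(gate.P[0], before[0])  # delta 0: untouched
    assert gate.P[1, 1] >= before[1, 1]


def test_zero_shift_draw_leaves_row_unchanged(rng):
    gate = make_fb_gate(np.full((2, 2), 0.5), delta=0.0)
    gate.history.appendleft((0, 0))
    apply_feedback(gate, "positive", rng)
    assert np.array_equal(gate.P, np.full((2, 2), 0.5))


@given(st.integers(0, 2**32 - 1), st.integers(2, 4), st.integers(1, 4))
def test_feedback_keeps_rows_stochastic_and_bounded(seed, log_cols, depth):
    rng = np.random.default_rng(seed)
    n_cols = 2 ** log_cols
    # +1 keeps every starting entry above the 0.01 floor, so the bound
    # check below covers untouched rows too
    raw = rng.random((4, n_cols)) + 1.0
    P = raw / raw.sum(axis=1, keepdims=True)
    gate = make_fb_gate(P, depth=depth)
    for _ in range(200):
        gate.history.clear()
        for _ in range(int(rng.integers(1, depth + 1))):
            gate.history.appendleft(
                (int(rng.integers(4)), int(rng.integers(n_cols)))
            )
        gate.delta_pos = rng.random(depth)
        gate.delta_neg = rng.random(depth)
        sign = "positive" if rng.random() < 0.5 else "negative"
        apply_feedback(gate, sign, rng)
        assert np.allclose(gate.P.sum(axis=1), 1.0, atol=1e-9)
        assert (gate.P >= FLOOR - 1e-12).all()
        assert (gate.P <= CAP + 1e-12).all()


def test_repeated_positive_feedback_converges_to_cap(rng):
    gate = make_fb_gate(np.full((2, 2), 0.5))
    gate.history.appendleft((0, 0))
    for _ in range(2000):
        apply_feedback(gate, "positive", rng)
    assert np.isclose(gate.P[0, 0], CAP)
    assert np.isclose(gate.P[0, 1], FLOOR)


def test_cap_is_tighter_for_wide_rows(rng):
    # with 16 columns, the floor on 15 entries caps the target at 0.85
    gate = make_fb_gate(np.full((2, 16), 1 / 16))
    gate.history.appendleft((0, 0))
    for _ in range(5000):
        apply_feedback(gate, "positive", rng)
    assert gate.P[0, 0] <= 1 - FLOOR * 15 + 1e-12
    assert np.isclose(gate.P[0].sum(), 1.0)


def test_feedback_line_reader():
    gate = make_fb_gate(np.full((2, 2), 0.5))
    state = np.zeros(16, dtype=np.uint8)
    assert check_feedback_inputs(gate, state) == "none"
    state[gate.pos_node] = 1
    assert check_feedback_inputs(gate, state) == "positive"
    state[gate.neg_node] = 1
    assert check_feedback_inputs(gate, state) == "both"
    state[gate.pos_node] = 0
    assert check_feedback_inputs(gate, state) == "negative"


def test_birth_table_is_preserved_copy(rng):
    gate = make_fb_gate(np.full((2, 2), 0.5))
    gate.history.appendleft((0, 0))
    apply_feedback(gate, "positive", rng)
    assert np.array_equal(gate.P_birth, np.full((2, 2), 0.5))


# -- decoding ---------------------------------------------------------

@given(st.integers(0, 2**32 - 1), st.sampled_from(GATE_KINDS))
def test_decoding_is_total_and_valid(seed, kind):
    rng = np.random.default_rng(seed)
    payload = rng.integers(0, 256, size=PAYLOAD_LENGTH, dtype=np.uint8)
    gate = decode_gate(GeneSpan(kind, 0, payload))
    assert 1 <= gate.n_inputs <= 4
    assert 1 <= gate.n_outputs <= 4
    assert all(0 <= n < 16 for n in gate.input_nodes)
    assert all(4 <= n < 16 for n in gate.output_nodes)  # sensors protected
    if isinstance(gate, DeterministicGate):
        assert gate.table.shape == (2 ** gate.n_inputs,)
        assert (gate.table < 2 ** gate.n_outputs).all()
        assert (gate.table >= 0).all()
    else:
        assert gate.P.shape == (2 ** gate.n_inputs, 2 ** gate.n_outputs)
        assert np.allclose(gate.P.sum(axis=1), 1.0)
        assert (gate.P > 0).all()  # byte+1 encoding: no zero entries
    if isinstance(gate, FeedbackGate):
        assert 1 <= gate.depth <= 4
        assert 0 <= gate.pos_node < 16 and 0 <= gate.neg_node < 16
        assert gate.delta_pos.shape == (gate.depth,)
        assert ((0 <= gate.delta_pos) & (gate.delta_pos <= 1)).all()
        assert ((0 <= gate.delta_neg) & (gate.delta_neg <= 1)).all()


def test_decoding_known_payload():
    payload = np.zeros(PAYLOAD_LENGTH, dtype=np.uint8)
    payload[0] = 1   # 2 inputs
    payload[1] = 0   # 1 output
    payload[2], payload[3] = 3, 20  # inputs -> nodes 3, 4
    payload[6] = 13  # output -> 4 + 13 % 12 = 5
    payload[10:14] = [0, 1, 2, 3]
    gate = decode_gate(GeneSpan("deterministic", 0, payload))
    assert gate.input_nodes == [3, 4]
    assert gate.output_nodes == [5]
    assert list(gate.table) == [0, 1, 0, 1]
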