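"""Logic gates: deterministic, probabilistic, and feedback.

A Markov Brain wires binary nodes through small logic gates with 1-4
input and 1-4 output wires. Deterministic gates map each input pattern
to a fixed output pattern; probabilistic gates hold a row-stochastic
probability matrix ``P`` and sample an output pattern per update.
Feedback gates extend probabilistic gates with lifetime plasticity:
they buffer their recent (input, output) decisions and, when one of
two genetically wired feedback lines reads a 1, multiplicatively
reinforce (positive line) or weaken (negative line) the buffered table
entries, keeping rows normalized and every touched entry inside
[0.01, 0.99].

Gates are decoded from gene payloads; every byte string decodes to a
valid gate. Decoding layout (byte offsets into the payload)::

    0        number of input wires   (byte % 4 + 1)
    1        number of output wires  (byte % 4 + 1)
    2-5      input node addresses    (byte % n_nodes; any node readable)
    6-9      output node addresses   (4 + byte % (n_nodes - 4); sensors
             are write-protected)
    -- feedback gates only --
    10       positive feedback node  (byte % n_nodes)
    11       negative feedback node  (byte % n_nodes)
    12       buffer depth            (byte % 4 + 1)
    13-16    positive deltas         (byte / 255, one per buffer slot)
    17-20    negative deltas         (byte / 255)
    --
    then     the logic table, row-major: deterministic gates read one
             byte per input pattern (% 2**n_out); probabilistic and
             feedback gates read 2**n_in * 2**n_out bytes, add 1 to
             each (so no row is all-zero) and normalize per row.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .genome import GeneSpan

__all__ = [
    "N_NODES",
    "DeterministicGate",
    "ProbabilisticGate",
    "FeedbackGate",
    "eval_deterministic",
    "eval_probabilistic",
    "apply_feedback",
    "check_feedback_inputs",
    "decode_gate",
]

#: Total node count of a brain: 4 sensors, 2 outputs, 10 hidden.
N_NODES = 16
#: First node index gates may write to (sensors are read-only).
FIRST_WRITABLE_NODE = 4

_ROW_TOL = 1e-9


@dataclass
class DeterministicGate:
    input_nodes: list[int]
    output_nodes: list[int]
    table: np.ndarray  # (2**n_in,) ints in [0, 2**n_out)

    kind = "deterministic"

    @property
    def n_inputs(self) -> int:
        return len(self.input_nodes)

    @property
    def n_outputs(self) -> int:
        return len(self.output_nodes)


@dataclass
class ProbabilisticGate:
    input_nodes: list[int]
    output_nodes: list[int]
    P: np.ndarray  # (2**n_in, 2**n_out), row-stochastic

    kind = "probabilistic"

    @property
    def n_inputs(self) -> int:
        return len(self.input_nodes)

    @property
    def n_outputs(self) -> int:
        return len(self.output_nodes)


@dataclass
class FeedbackGate:
    input_nodes: list[int]
    output_nodes: list[int]
    P: np.ndarray
    pos_node: int
    neg_node: int
    depth: int
    delta_pos: np.ndarray  # (depth,), values in [0, 1]
    delta_neg: np.ndarray
    P_birth: np.ndarray = None
    #: recent (input, output) decisions, most recent first
    history: deque = field(default_factory=deque)

    kind = "feedback"

    def __post_init__(self) -> None:
        if self.P_birth is None:
            self.P_birth = self.P.copy()
        if not isinstance(self.history, deque) or self.history.maxlen != self.depth:
            self.history = deque(self.history, maxlen=self.depth)

    @property
    def n_inputs(self) -> int:
        return len(self.input_nodes)

    @property
    def n_outputs(self) -> int:
        return len(self.output_nodes)


def _check_row(row: np.ndarray) -> None:
    if abs(float(row.sum()) - 1.0) > 1e-6 or (row < 0).any():
        raise ValueError("probability row is not a normalized distribution")


def eval_deterministic(gate: DeterministicGate, input_pattern: int) -> int:
    """Look up the output pattern for ``input_pattern``."""
    if not 0 <= input_pattern < 2 ** gate.n_inputs:
        raise ValueError(
            f"input pattern {input_pattern} out of range for "
            f"{gate.n_inputs}-input gate"
        )
    return int(gate.table[input_pattern])


def eval_probabilistic(
    gate: ProbabilisticGate | FeedbackGate,
    input_pattern: int,
    rng: np.random.Generator,
) -> int:
    """Sample an output pattern from row ``input_pattern`` of ``P``.

    For a feedback gate the (input, output) decision is pushed onto the
    buffer, evicting the oldest entry when the buffer is full.
    """
    if not 0 <= input_pattern < 2 ** gate.n_inputs:
        raise ValueError(f"input pattern {input_pattern} out of range")
    row = gate.P[input_pattern]
    _check_row(row)
    o = int(_kernel.sample_row(row, row.size, rng.random()))
    if isinstance(gate, FeedbackGate):
        gate.history.appendleft((input_pattern, o))
    return o


def apply_feedback(
    gate: FeedbackGate, sign: str, rng: np.random.Generator
) -> FeedbackGate:
    """Reinforce or weaken every buffered decision of ``gate``.

    For the buffered decision at slot ``k`` (0 = most recent) a shift
    is drawn uniformly from [0, delta_pos[k]] (positive feedback) or
    [0, delta_neg[k]] (negative), applied to ``P[i, o]``, and the row
    is renormalized with entries clamped to [0.01, 0.99]. An empty
    buffer is a no-op. Mutates and returns ``gate``.
    """
    if sign not in ("positive", "negative"):
        raise ValueError(f"sign must be 'positive' or 'negative', got {sign!r}")
    positive = sign == "positive"
    deltas = gate.delta_pos if positive else gate.delta_neg
    n_cols = gate.P.shape[1]
    for k, (i, o) in enumerate(gate.history):
        u = rng.random() * float(deltas[k])
        _kernel.feedback_update_row(gate.P[i], n_cols, o, u, positive)
    return gate


def check_feedback_inputs(gate: FeedbackGate, node_states: np.ndarray) -> str:
    """Report which feedback lines read a 1: 'none', 'positive',
    'negative', or 'both'. A 0 on a line has no effect; a 1 triggers
    that feedback (positive is applied before negative when both fire).
    """
    pos = int(node_states[gate.pos_node]) == 1
    neg = int(node_states[gate.neg_node]) == 1
    if pos and neg:
        return "both"
    if pos:
        return "positive"
    if neg:
        return "negative"
    return "none"


def decode_gate(
    span: GeneSpan, n_nodes: int = N_NODES
) -> DeterministicGate | ProbabilisticGate | FeedbackGate:
    """Decode a gene payload into a gate (total: never fails)."""
    p = span.payload.astype(np.int64)
    n_in = int(p[0] % 4 + 1)
    n_out = int(p[1] % 4 + 1)
    input_nodes = [int(v % n_nodes) for v in p[2 : 2 + n_in]]
    output_nodes = [
        FIRST_WRITABLE_NODE + int(v % (n_nodes - FIRST_WRITABLE_NODE))
        for v in p[6 : 6 + n_out]
    ]
    n_rows = 2 ** n_in
    n_cols = 2 ** n_out

    if span.gate_kind == "deterministic":
        table = (p[10 : 10 + n_rows] % n_cols).astype(np.int64)
        return DeterministicGate(input_nodes, output_nodes, table)

    if span.gate_kind == "probabilistic":
        raw = p[10 : 10 + n_rows * n_cols].reshape(n_rows, n_cols) + 1.0
        P = raw / raw.sum(axis=1, keepdims=True)
        return ProbabilisticGate(input_nodes, output_nodes, P)

    if span.gate_kind == "feedback":
        pos_node = int(p[10] % n_nodes)
        neg_node = int(p[11] % n_nodes)
        depth = int(p[12] % 4 + 1)
        delta_pos = (p[13 : 13 + depth] / 255.0).astype(np.float64)
        delta_neg = (p[17 : 17 + depth] / 255.0).astype(np.float64)
        raw = p[21 : 21 + n_rows * n_cols].reshape(n_rows, n_cols) + 1.0
        P = raw / raw.sum(axis=1, keepdims=True)
        return FeedbackGate(
            input_nodes, output_nodes, P, pos_node, neg_node, depth,
            delta_pos, delta_neg,
        )

    raise ValueError(f"unknown gate kind: {span.gate_kind!r}")
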