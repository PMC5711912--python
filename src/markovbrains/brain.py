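"""Markov Brains: decoded gate networks over 16 binary nodes.

Node layout is fixed: nodes 0-3 are sensors (written by the world each
update, read-only for gates), nodes 4-5 are the motor outputs, and
nodes 6-15 are hidden. Updates are synchronous and double-buffered:
all gates read the pre-update state and OR their outputs into a fresh
zero next-state, so gate order is irrelevant to the result and any
information kept across updates must be actively rewritten into hidden
nodes. Output nodes are not latched between updates.

Feedback gates read their feedback lines from the pre-update state and
apply feedback *before* any gate samples, so feedback always refers to
the consequences of past decisions.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import _kernel
from .gates import (
    N_NODES,
    DeterministicGate,
    FeedbackGate,
    ProbabilisticGate,
    decode_gate,
)
from .genome import GATE_KINDS, Genome, find_genes

__all__ = [
    "MarkovBrain",
    "build_brain",
    "brain_step",
    "reset_brain",
    "set_feedback_enabled",
]

N_SENSORS = 4
N_OUTPUTS = 2

_KIND_CODE = {"deterministic": 0, "probabilistic": 1, "feedback": 2}

# a throwaway generator for purely deterministic brains, never drawn from
_NULL_RNG = np.random.default_rng(0)


class MarkovBrain:
    """A gate network plus its 16-node binary state vector.

    The brain compiles its gates into flat arrays consumed by the
    simulation kernel; probability matrices of the gate objects are
    views into those arrays, so lifetime learning performed during an
    evaluation is visible on the gates themselves.
    """

    def __init__(self, gates, feedback_enabled: bool = True):
        self.gates = list(gates)
        self.feedback_enabled = bool(feedback_enabled)
        self.state = np.zeros(N_NODES, dtype=np.uint8)
        self._compile()

    # -- construction ------------------------------------------------

    def _compile(self) -> None:
        G = len(self.gates)
        self._kind = np.zeros(G, dtype=np.int8)
        self._n_in = np.ones(G, dtype=np.int8)
        self._n_out = np.ones(G, dtype=np.int8)
        self._in_nodes = np.zeros((G, 4), dtype=np.int8)
        self._out_nodes = np.full((G, 4), 4, dtype=np.int8)
        self._det_table = np.zeros((G, 16), dtype=np.int16)
        self._P = np.zeros((G, 16, 16), dtype=np.float64)
        self._P_birth = np.zeros((G, 16, 16), dtype=np.float64)
        self._pos_node = np.zeros(G, dtype=np.int8)
        self._neg_node = np.zeros(G, dtype=np.int8)
        self._depth = np.ones(G, dtype=np.int8)
        self._dpos = np.zeros((G, 4), dtype=np.float64)
        self._dneg = np.zeros((G, 4), dtype=np.float64)
        self._hist_i = np.zeros((G, 4), dtype=np.int16)
        self._hist_o = np.zeros((G, 4), dtype=np.int16)
        self._hist_len = np.zeros(G, dtype=np.int8)

        for g, gate in enumerate(self.gates):
            self._kind[g] = _KIND_CODE[gate.kind]
            self._n_in[g] = gate.n_inputs
            self._n_out[g] = gate.n_outputs
            self._in_nodes[g, : gate.n_inputs] = gate.input_nodes
            self._out_nodes[g, : gate.n_outputs] = gate.output_nodes
            R, C = 2 ** gate.n_inputs, 2 ** gate.n_outputs
            if isinstance(gate, DeterministicGate):
                self._det_table[g, :R] = gate.table
            else:
                self._P[g, :R, :C] = gate.P
                # rebind so kernel updates are visible on the gate object
                gate.P = self._P[g, :R, :C]
                if isinstance(gate, FeedbackGate):
                    self._P_birth[g, :R, :C] = gate.P_birth
                    gate.P_birth = self._P_birth[g, :R, :C]
                    self._pos_node[g] = gate.pos_node
                    self._neg_node[g] = gate.neg_node
                    self._depth[g] = gate.depth
                    self._dpos[g, : gate.depth] = gate.delta_pos
                    self._dneg[g, : gate.depth] = gate.delta_neg

    @property
    def feedback_gates(self) -> list[FeedbackGate]:
        return [g for g in self.gates if isinstance(g, FeedbackGate)]

    def _kernel_args(self):
        return (
            self._kind, self._n_in, self._n_out, self._in_nodes,
            self._out_nodes, self._det_table, self._P,
            self._pos_node, self._neg_node, self._depth,
            self._dpos, self._dneg,
            self._hist_i, self._hist_o, self._hist_len,
        )

    # -- behaviour ---------------------------------------------------

    def step(self, sensor_bits, rng: np.random.Generator | None = None):
        """One synchronous update; returns the 2-bit motor output as
        (node4, node5). ``rng`` may be omitted for purely deterministic
        brains."""
        if rng is None:
            if (self._kind != 0).any():
                raise ValueError("rng required for brains with stochastic gates")
            rng = _NULL_RNG
        sensors = np.asarray(sensor_bits, dtype=np.uint8)
        if sensors.shape != (N_SENSORS,):
            raise ValueError(f"expected {N_SENSORS} sensor bits")
        _kernel.brain_step_arrays(
            *self._kernel_args(), self.state, sensors,
            self.feedback_enabled, rng, np.zeros(N_NODES, dtype=np.uint8),
        )
        return int(self.state[4]), int(self.state[5])

    def reset(self) -> "MarkovBrain":
        """Return the brain to its birth state: zero all nodes, restore
        every feedback table to its genome-decoded values, clear the
        decision buffers. Idempotent."""
        self.state[:] = 0
        self._hist_len[:] = 0
        self._hist_i[:] = 0
        self._hist_o[:] = 0
        for g, gate in enumerate(self.gates):
            if isinstance(gate, FeedbackGate):
                np.copyto(self._P[g], self._P_birth[g])
                gate.history.clear()
        return self

    def feedback_history(self, gate_index: int) -> list[tuple[int, int]]:
        """Buffered (input, output) decisions of gate ``gate_index`` as
        maintained during brain stepping, most recent first."""
        m = int(self._hist_len[gate_index])
        return [
            (int(self._hist_i[gate_index, k]), int(self._hist_o[gate_index, k]))
            for k in range(m)
        ]

    # -- serialization ----------------------------------------------

    def to_dict(self) -> dict:
        gates = []
        for gate in self.gates:
            d = {
                "kind": gate.kind,
                "input_nodes": [int(v) for v in gate.input_nodes],
                "output_nodes": [int(v) for v in gate.output_nodes],
            }
            if isinstance(gate, DeterministicGate):
                d["table"] = [int(v) for v in gate.table]
            else:
                d["P"] = np.asarray(gate.P).tolist()
            if isinstance(gate, FeedbackGate):
                d.update(
                    P_birth=np.asarray(gate.P_birth).tolist(),
                    pos_node=int(gate.pos_node),
                    neg_node=int(gate.neg_node),
                    depth=int(gate.depth),
                    delta_pos=[float(v) for v in gate.delta_pos],
                    delta_neg=[float(v) for v in gate.delta_neg],
                )
            gates.append(d)
        return {
            "state": self.state.tolist(),
            "feedback_enabled": self.feedback_enabled,
            "gates": gates,
        }

    def save_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)


def build_brain(
    genome: Genome, gate_kinds=GATE_KINDS, n_nodes: int = N_NODES
) -> MarkovBrain:
    """Decode every gene of ``genome`` into a gate and assemble the
    brain, all nodes zeroed and feedback enabled. ``gate_kinds``
    restricts which gene types are expressed (the single-gate-type
    experimental conditions)."""
    spans = find_genes(genome, kinds=gate_kinds)
    gates = [decode_gate(span, n_nodes=n_nodes) for span in spans]
    return MarkovBrain(gates)


def brain_step(brain: MarkovBrain, sensor_bits, rng=None):
    return brain.step(sensor_bits, rng)


def reset_brain(brain: MarkovBrain) -> MarkovBrain:
    return brain.reset()


def set_feedback_enabled(brain: MarkovBrain, flag: bool) -> MarkovBrain:
    """Enable or disable lifetime plasticity. When disabled, feedback
    gates still sample and buffer decisions but never alter their
    probability tables (the frozen-feedback control)."""
    brain.feedback_enabled = bool(flag)
    return brain
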